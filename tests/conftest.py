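"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately use naive explicit loops so they stay independent
of the vectorized implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from beatmatch import SynthParams, generate_record


def brute_force_ncc(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Per-lag Pearson correlation with an explicit O(N*L) loop."""
    L = len(t)
    t0 = t - t.mean()
    tn = np.sqrt(np.sum(t0**2))
    out = np.empty(len(x) - L + 1)
    for k in range(len(out)):
        w = x[k : k + L]
        w0 = w - w.mean()
        wn = np.sqrt(np.sum(w0**2))
        out[k] = 0.0 if wn == 0 else float(np.dot(t0, w0) / (tn * wn))
    return out


def brute_force_prominence(values: np.ndarray, peak: int) -> float:
    """Topographic prominence of a strict local maximum, by definition.

    Walk left and right until a strictly higher sample (or the signal end)
    is reached; the prominence is the peak height minus the higher of the
    two minima found on the way.
    """
    v = np.asarray(values, dtype=float)
    left_min = v[peak]
    i = peak - 1
    while i >= 0 and v[i] <= v[peak]:
        left_min = min(left_min, v[i])
        i -= 1
    if i < 0:
        left_min = v[: peak + 1].min()
    right_min = v[peak]
    i = peak + 1
    while i < len(v) and v[i] <= v[peak]:
        right_min = min(right_min, v[i])
        i += 1
    if i >= len(v):
        right_min = v[peak:].min()
    return float(v[peak] - max(left_min, right_min))


def brute_force_template_scores(candidates: np.ndarray) -> np.ndarray:
    """All-vs-all Pearson correlations and mean/SD scores via double loop."""
    n = len(candidates)
    scores = np.empty(n)
    for i in range(n):
        cors = []
        for j in range(n):
            if i == j:
                continue
            a = candidates[i] - candidates[i].mean()
            b = candidates[j] - candidates[j].mean()
            cors.append(float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b))))
        cors = np.asarray(cors)
        sd = cors.std(ddof=1) if len(cors) > 1 else 0.0
        scores[i] = cors.mean() / max(sd, 1e-12)
    return scores


def brute_force_classify(detected, reference):
    """Cycle-rule TP/FP/FN with explicit interval membership loops."""
    detected = list(detected)
    reference = list(reference)
    mids = [(reference[i] + reference[i + 1]) / 2 for i in range(len(reference) - 1)]
    bounds = [-np.inf] + mids + [np.inf]
    tp = fp = fn = 0
    for c in range(len(reference)):
        members = [d for d in detected if bounds[c] <= d < bounds[c + 1]]
        if not members:
            fn += 1
            continue
        tp += 1
        fp += len(members) - 1
    return tp, fp, fn


@pytest.fixture(scope="session")
def clean_synth():
    """60 s healthy record, 70 bpm, 20 dB in-band SNR, seed 1."""
    return generate_record(SynthParams(duration_s=60.0, seed=1))


@pytest.fixture(scope="session")
def quiet_synth():
    """Near-noiseless 60 s record for shape-recovery checks."""
    return generate_record(SynthParams(duration_s=60.0, snr_db=40.0, seed=3))
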