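"""Automatic heartbeat-template selection.

The detector needs one representative heartbeat segment before it can run
template matching. That segment is found without any ECG reference:

1. Scan consecutive non-overlapping 10 s windows of the preprocessed
   signal, starting at t = 0.
2. In each window, build an envelope — the 4th power of the signal,
   low-pass filtered at 3 Hz (2nd-order zero-lag Butterworth), clipped at
   zero and normalized to its own maximum — and pick envelope peaks with
   topographic prominence >= 0.25. Each peak is a putative heartbeat.
3. Gate the window: it is *reliable* only if at least ``min_beats`` (5)
   peaks were found and the mean absolute deviation of the inter-beat
   intervals is below ``mad_threshold_ms`` (335 ms, derived from the upper
   tail of inter-beat variability in atrial fibrillation — the most
   variable rhythm a genuine heart can produce; more variability than that
   indicates spurious peaks).
4. In the first reliable window, cut one candidate segment per peak, from
   200 ms before to 500 ms after the peak, and keep candidates fully
   inside the window.
5. Score each candidate by the ratio of the mean to the standard deviation
   of its Pearson correlations with every other candidate ("all vs. all");
   the highest-scoring candidate becomes the template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateCandidateError,
    DegenerateSegmentError,
    InsufficientCandidatesError,
    LengthError,
    NoReliableWindowError,
)
from .preprocess import FilterSpec, butterworth_zero_lag
from .records import DetectorConfig

_SD_FLOOR = 1e-12  # scores with SD below this are treated as SD = floor


@dataclass
class EnvelopeSeries:
    """Normalized non-negative envelope of one analysis window."""

    values: np.ndarray
    fs: float
    window_start_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class WindowReliability:
    """Outcome of the reliability gate for one 10 s window."""

    n_beats: int
    ibis_ms: np.ndarray
    mad_ms: float
    reliable: bool
    reasons: set[str] = field(default_factory=set)  # subset of {too_few_beats, high_mad}


@dataclass
class TemplateCandidateSet:
    """Equal-length beat segments cut around envelope peaks."""

    candidates: np.ndarray  # shape (n_candidates, segment_length)
    anchor_offset_samples: int
    beat_times_s: np.ndarray  # originating envelope-peak times (window-relative)
    fs: float


@dataclass
class HeartbeatTemplate:
    """The selected heartbeat segment.

    ``anchor_offset_samples`` marks the sample that was the envelope peak,
    so detections made with this template can be reported at a consistent
    within-beat landmark.
    """

    waveform: np.ndarray
    fs: float
    anchor_offset_samples: int
    source_window_index: int = -1
    score: float = float("nan")
    beat_time_s: float = float("nan")  # record-absolute time of the anchor

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if len(self.waveform) < 2:
            raise DegenerateCandidateError("template must have at least 2 samples")
        if not 0 <= self.anchor_offset_samples < len(self.waveform):
            raise DegenerateCandidateError("anchor outside template support")


def compute_envelope(
    segment: np.ndarray, fs: float, cfg: DetectorConfig | None = None, window_start_s: float = 0.0
) -> EnvelopeSeries:
    """Envelope = normalized low-passed 4th power of the segment.

    Raising the signal to an even power rectifies it and sharpens beats
    relative to baseline noise; the 3 Hz low-pass merges the intra-beat
    oscillations into one hump per heartbeat. Negative low-pass ripple is
    clipped at zero before normalizing to the maximum, so the configured
    prominence threshold lives on a fixed 0-1 scale.
    """
    cfg = cfg or DetectorConfig()
    segment = np.asarray(segment, dtype=float)
    if len(segment) < fs:
        raise LengthError("envelope needs at least 1 s of samples")
    powered = segment ** cfg.env_power
    spec = FilterSpec("lowpass", cfg.env_lp_order, (cfg.env_lp_hz,))
    smoothed = butterworth_zero_lag(powered, fs, spec)
    smoothed = np.clip(smoothed, 0.0, None)
    peak = smoothed.max()
    if peak <= 0:
        raise DegenerateSegmentError("flat segment: envelope maximum is zero")
    return EnvelopeSeries(values=smoothed / peak, fs=fs, window_start_s=window_start_s)


def detect_envelope_peaks(env: EnvelopeSeries, cfg: DetectorConfig | None = None) -> np.ndarray:
    """Envelope-peak times (seconds, window-relative) with prominence >= 0.25."""
    cfg = cfg or DetectorConfig()
    idx, _ = sps.find_peaks(env.values, prominence=cfg.env_min_prominence)
    return idx / env.fs


def assess_window_reliability(
    beat_times: np.ndarray, cfg: DetectorConfig | None = None
) -> WindowReliability:
    """Apply the two-criterion gate: enough beats, low IBI variability.

    The variability measure is the mean absolute deviation (MAD) of the
    inter-beat intervals about their mean, in milliseconds.
    """
    cfg = cfg or DetectorConfig()
    beat_times = np.asarray(beat_times, dtype=float)
    n = len(beat_times)
    ibis_ms = np.diff(beat_times) * 1000.0
    mad_ms = float(np.mean(np.abs(ibis_ms - ibis_ms.mean()))) if len(ibis_ms) else 0.0
    reasons: set[str] = set()
    if n < cfg.min_beats:
        reasons.add("too_few_beats")
    if mad_ms >= cfg.mad_threshold_ms:
        reasons.add("high_mad")
    return WindowReliability(
        n_beats=n, ibis_ms=ibis_ms, mad_ms=mad_ms, reliable=not reasons, reasons=reasons
    )


def segment_candidate_beats(
    segment: np.ndarray,
    fs: float,
    beat_times: np.ndarray,
    cfg: DetectorConfig | None = None,
) -> TemplateCandidateSet:
    """Cut a fixed window around each envelope peak.

    Each candidate spans ``seg_pre_ms`` before to ``seg_post_ms`` after the
    peak; beats whose window would cross either edge of the segment are
    dropped. All surviving candidates have identical length
    ``pre + post + 1`` samples with the peak at index ``pre``.
    """
    cfg = cfg or DetectorConfig()
    segment = np.asarray(segment, dtype=float)
    pre = int(round(cfg.seg_pre_ms * fs / 1000.0))
    post = int(round(cfg.seg_post_ms * fs / 1000.0))
    rows, kept_times = [], []
    for t in np.asarray(beat_times, dtype=float):
        c = int(round(t * fs))
        if c - pre < 0 or c + post > len(segment) - 1:
            continue
        rows.append(segment[c - pre : c + post + 1])
        kept_times.append(t)
    if len(rows) < 2:
        raise InsufficientCandidatesError(
            f"only {len(rows)} candidate beats survive edge trimming"
        )
    return TemplateCandidateSet(
        candidates=np.vstack(rows),
        anchor_offset_samples=pre,
        beat_times_s=np.asarray(kept_times),
        fs=fs,
    )


def score_and_select_template(cands: TemplateCandidateSet) -> HeartbeatTemplate:
    """Pick the candidate with the highest mean/SD of cross correlations.

    For candidate i the scores use the n-1 Pearson correlations with every
    other candidate; the SD is the sample standard deviation (it is taken
    as zero when only one correlation exists, and floored at 1e-12 so a
    perfectly consistent candidate gets a large finite score). Ties go to
    the earliest beat.
    """
    X = np.asarray(cands.candidates, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise InsufficientCandidatesError("need at least two candidates to score")
    if np.any(X.std(axis=1) == 0):
        raise DegenerateCandidateError("a candidate segment has zero variance")
    corr = np.corrcoef(X)
    scores = np.empty(n)
    for i in range(n):
        others = np.delete(corr[i], i)
        mean = others.mean()
        sd = others.std(ddof=1) if len(others) > 1 else 0.0
        scores[i] = mean / max(sd, _SD_FLOOR)
    best = int(np.argmax(scores))  # argmax returns the first maximum: earliest beat wins
    return HeartbeatTemplate(
        waveform=X[best].copy(),
        fs=cands.fs,
        anchor_offset_samples=cands.anchor_offset_samples,
        score=float(scores[best]),
        beat_time_s=float(cands.beat_times_s[best]),
    )


def auto_select_template(
    x: np.ndarray, fs: float, cfg: DetectorConfig | None = None
) -> HeartbeatTemplate:
    """Scan 10 s windows from t=0 and return the template of the first
    reliable one.

    Windows are consecutive and non-overlapping; a trailing partial window
    is not searched. A window that passes the reliability gate but cannot
    produce scorable candidates (all beats at the edges, or a flat
    candidate) is skipped like an unreliable one. Raises
    :class:`~beatmatch.errors.NoReliableWindowError` when the whole record
    is exhausted.
    """
    cfg = cfg or DetectorConfig()
    x = np.asarray(x, dtype=float)
    win = int(round(cfg.window_s * fs))
    if len(x) < win:
        raise LengthError(f"record of {len(x)} samples shorter than one {cfg.window_s} s window")
    n_windows = len(x) // win
    for w in range(n_windows):
        seg = x[w * win : (w + 1) * win]
        try:
            env = compute_envelope(seg, fs, cfg, window_start_s=w * win / fs)
        except DegenerateSegmentError:
            continue
        beat_times = detect_envelope_peaks(env, cfg)
        gate = assess_window_reliability(beat_times, cfg)
        if not gate.reliable:
            continue
        try:
            cands = segment_candidate_beats(seg, fs, beat_times, cfg)
            tpl = score_and_select_template(cands)
        except (InsufficientCandidatesError, DegenerateCandidateError):
            continue
        tpl.source_window_index = w
        tpl.beat_time_s = tpl.beat_time_s + w * win / fs  # record-absolute anchor time
        return tpl
    raise NoReliableWindowError("no reliable 10 s window found in the record")
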