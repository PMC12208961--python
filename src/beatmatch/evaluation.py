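"""Statistical assessment of beat detections against an ECG reference.

The ECG R peaks (found with the Pan-Tompkins algorithm) define the
ground-truth heartbeat times. Detections are scored per *cardiac cycle*:
cycles partition the time axis at the midpoints between consecutive
reference beats, each detection is assigned to the cycle containing it,
the detection nearest the cycle's reference beat is the true positive
(TP), any further detections in the cycle are false positives (FP), and
cycles with no detection are false negatives (FN). Sensitivity =
TP/(TP+FN); positive predictive value (PPV) = TP/(TP+FP).

Inter-beat-interval agreement uses only IBIs whose two bounding reference
beats were both TP-matched with no FP between the matched detections,
then ordinary least squares (with 95% confidence intervals) and a
Bland-Altman analysis. When the paired differences fail a Shapiro-Wilk
normality check the Bland-Altman bias falls back to the median and the
limits of agreement to the 2.5th/97.5th percentiles, with bootstrap
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import signal as sps
from scipy import stats

from .errors import ConfigError, LengthError, SampleSizeError, UndefinedMetricError

_NORMALITY_ALPHA = 0.05
_SHAPIRO_MAX_N = 5000
_BOOTSTRAP_RESAMPLES = 2000


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins)
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Locate ECG R peaks with the Pan-Tompkins chain.

    Steps: 5-15 Hz QRS-emphasis band-pass, derivative, squaring, 150 ms
    moving-window integration, adaptive dual thresholds (signal/noise
    running estimates) with a 200 ms refractory period and a search-back
    pass at half threshold when an expected beat is missed. Each detection
    is refined to the local absolute maximum of the band-passed ECG within
    +-50 ms. Thresholds track the signal scale, so the result is invariant
    to amplitude rescaling.

    ``ecg`` is expected to already be baseline/powerline conditioned (see
    :func:`beatmatch.preprocess.preprocess_channel` with role ``ecg``).
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 10 * fs:
        raise LengthError("R-peak detection needs at least 10 s of ECG")

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp) * fs
    squared = deriv**2
    mwi_len = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(mwi_len) / mwi_len, mode="same")

    refractory = int(round(0.200 * fs))
    search_back_window = int(round(1.66 * fs))  # ~missed-beat horizon

    # initialize running estimates from the first 2 s
    init = mwi[: int(2 * fs)]
    spki = 0.25 * init.max() if init.max() > 0 else 0.0
    npki = 0.5 * init.mean()
    threshold = npki + 0.25 * (spki - npki)

    candidates, _ = sps.find_peaks(mwi, distance=refractory)
    peaks: list[int] = []
    last_peak = -search_back_window
    rr_avg = None
    pending: list[int] = []  # sub-threshold candidates for search-back

    for c in candidates:
        if mwi[c] > threshold:
            if peaks and c - peaks[-1] < refractory:
                continue
            peaks.append(c)
            spki = 0.125 * mwi[c] + 0.875 * spki
            if len(peaks) > 1:
                rr = peaks[-1] - peaks[-2]
                rr_avg = rr if rr_avg is None else 0.875 * rr_avg + 0.125 * rr
            last_peak = c
            pending = []
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki
            pending.append(c)
            # search-back: no beat for > 1.66 RR -> take best pending at half threshold
            horizon = int(1.66 * rr_avg) if rr_avg else search_back_window
            if c - last_peak > horizon and pending:
                best = max(pending, key=lambda i: mwi[i])
                if mwi[best] > 0.5 * threshold and (not peaks or best - peaks[-1] >= refractory):
                    peaks.append(best)
                    spki = 0.25 * mwi[best] + 0.75 * spki
                    last_peak = best
                    pending = []
        threshold = npki + 0.25 * (spki - npki)

    # refine to the local extremum of the band-passed ECG
    half = int(round(0.050 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = sorted(set(refined))
    return np.asarray(refined, dtype=float) / fs


# ---------------------------------------------------------------------------
# TP/FP/FN classification and detection metrics
# ---------------------------------------------------------------------------

@dataclass
class BeatMatchResult:
    tp: int
    fp: int
    fn: int
    detection_labels: list[str]  # "TP"/"FP" per detection
    cycle_assignment: np.ndarray  # per reference cycle: detection index of the TP, or -1


@dataclass
class DetectionMetrics:
    sensitivity_pct: float
    ppv_pct: float

    @property
    def sensitivity_rounded(self) -> float:
        return round(self.sensitivity_pct, 1)

    @property
    def ppv_rounded(self) -> float:
        return round(self.ppv_pct, 1)


def classify_detections(detected: np.ndarray, reference: np.ndarray) -> BeatMatchResult:
    """Assign detections to reference cardiac cycles and label TP/FP/FN.

    Cycles are bounded by the midpoints between consecutive reference
    beats; the first and last cycles extend to the record bounds. Within
    a cycle, the detection closest to the reference beat is the TP and all
    others are FPs; an empty cycle is an FN.
    """
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(np.diff(detected) < 0) or np.any(np.diff(reference) < 0):
        raise ConfigError("detected and reference beat times must be sorted")
    if len(reference) < 2:
        raise ConfigError("need at least two reference beats to define cycles")

    midpoints = (reference[:-1] + reference[1:]) / 2.0
    cycle_of = np.searchsorted(midpoints, detected, side="right")

    n_cycles = len(reference)
    assignment = np.full(n_cycles, -1, dtype=int)
    labels = ["FP"] * len(detected)
    for c in range(n_cycles):
        members = np.nonzero(cycle_of == c)[0]
        if len(members) == 0:
            continue
        best = members[np.argmin(np.abs(detected[members] - reference[c]))]
        assignment[c] = best
        labels[best] = "TP"
    tp = int(np.sum(assignment >= 0))
    fn = n_cycles - tp
    fp = len(detected) - tp
    assert tp + fn == n_cycles and tp + fp == len(detected)
    return BeatMatchResult(
        tp=tp, fp=fp, fn=fn, detection_labels=labels, cycle_assignment=assignment
    )


def sensitivity_ppv(match: BeatMatchResult) -> DetectionMetrics:
    """Sensitivity and PPV as percentages; raises on empty denominators."""
    if match.tp + match.fn == 0 or match.tp + match.fp == 0:
        raise UndefinedMetricError("sensitivity/PPV undefined with zero denominator")
    return DetectionMetrics(
        sensitivity_pct=100.0 * match.tp / (match.tp + match.fn),
        ppv_pct=100.0 * match.tp / (match.tp + match.fp),
    )


def pair_ibis_excluding_errors(
    detected: np.ndarray, reference: np.ndarray, match: BeatMatchResult
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (detected, reference) IBIs in ms, dropping FP/FN-touched ones.

    The IBI between reference beats i and i+1 is retained only when both
    beats were TP-matched and no FP detection falls between their matched
    detections.
    """
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    fp_times = detected[[i for i, lab in enumerate(match.detection_labels) if lab == "FP"]]
    det_ms, ref_ms = [], []
    for i in range(len(reference) - 1):
        a, b = match.cycle_assignment[i], match.cycle_assignment[i + 1]
        if a < 0 or b < 0:
            continue
        ta, tb = detected[a], detected[b]
        if np.any((fp_times > ta) & (fp_times < tb)):
            continue
        det_ms.append((tb - ta) * 1000.0)
        ref_ms.append((reference[i + 1] - reference[i]) * 1000.0)
    return np.asarray(det_ms), np.asarray(ref_ms)


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slope: float
    slope_ci: tuple[float, float]
    intercept_ms: float
    intercept_ci: tuple[float, float]
    r_squared: float
    r_squared_ci: tuple[float, float]
    n: int


@dataclass
class BlandAltmanResult:
    bias_ms: float
    loa_low_ms: float
    loa_high_ms: float
    bias_ci: tuple[float, float]
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    method: str  # parametric | percentile
    normality_p: float
    n: int = 0


def ols_regression_with_ci(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of detected on reference IBIs with 95% CIs.

    Slope/intercept CIs come from the t distribution; the R^2 CI squares
    the Fisher-z interval of the Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise SampleSizeError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ConfigError("reference IBIs are constant; regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) < 1.0 and n > 3:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        r_lo, r_hi = np.tanh(z - half), np.tanh(z + half)
        r2_ci = tuple(sorted((float(r_lo**2), float(r_hi**2))))
    else:
        r2_ci = (r**2, r**2)
    return RegressionResult(
        slope=float(model.params[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ms=float(model.params[0]),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        r_squared=float(r**2),
        r_squared_ci=r2_ci,
        n=n,
    )


def bland_altman(x: np.ndarray, y: np.ndarray, seed: int = 0) -> BlandAltmanResult:
    """Bland-Altman agreement of y vs. x with a non-normal fallback.

    Differences d = y - x are tested for normality (Shapiro-Wilk at
    alpha 0.05, subsampled to 5000 when larger). Normal: bias = mean,
    limits of agreement = bias +- 1.96 SD, CIs from the standard
    Bland-Altman variance formulas. Non-normal: bias = median, limits =
    2.5th/97.5th percentiles (linear interpolation), CIs from a seeded
    2000-resample bootstrap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ConfigError("x and y must have equal length")
    n = len(x)
    if n < 10:
        raise SampleSizeError("Bland-Altman needs at least 10 pairs")
    d = y - x
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        # all differences identical: both branches coincide
        b = float(d[0])
        return BlandAltmanResult(
            bias_ms=b, loa_low_ms=b, loa_high_ms=b,
            bias_ci=(b, b), loa_low_ci=(b, b), loa_high_ci=(b, b),
            method="parametric", normality_p=1.0, n=n,
        )
    rng = np.random.default_rng(seed)
    d_test = d if n <= _SHAPIRO_MAX_N else rng.choice(d, _SHAPIRO_MAX_N, replace=False)
    p_norm = float(stats.shapiro(d_test).pvalue)

    if p_norm >= _NORMALITY_ALPHA:
        bias = float(np.mean(d))
        z = 1.96
        lo, hi = bias - z * sd, bias + z * sd
        t = stats.t.ppf(0.975, n - 1)
        se_bias = sd / np.sqrt(n)
        se_loa = sd * np.sqrt(1.0 / n + z**2 / (2 * (n - 1)))
        return BlandAltmanResult(
            bias_ms=bias, loa_low_ms=lo, loa_high_ms=hi,
            bias_ci=(bias - t * se_bias, bias + t * se_bias),
            loa_low_ci=(lo - t * se_loa, lo + t * se_loa),
            loa_high_ci=(hi - t * se_loa, hi + t * se_loa),
            method="parametric", normality_p=p_norm, n=n,
        )

    bias = float(np.median(d))
    lo, hi = (float(q) for q in np.percentile(d, [2.5, 97.5]))
    boot = np.empty((_BOOTSTRAP_RESAMPLES, 3))
    for b in range(_BOOTSTRAP_RESAMPLES):
        s = rng.choice(d, n, replace=True)
        boot[b] = (np.median(s), *np.percentile(s, [2.5, 97.5]))
    cis = np.percentile(boot, [2.5, 97.5], axis=0)
    return BlandAltmanResult(
        bias_ms=bias, loa_low_ms=lo, loa_high_ms=hi,
        bias_ci=(float(cis[0, 0]), float(cis[1, 0])),
        loa_low_ci=(float(cis[0, 1]), float(cis[1, 1])),
        loa_high_ci=(float(cis[0, 2]), float(cis[1, 2])),
        method="percentile", normality_p=p_norm, n=n,
    )
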