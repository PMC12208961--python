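"""Template matching by normalized cross-correlation (NCC).

The NCC series is the sliding Pearson correlation between the selected
heartbeat template and every window of the preprocessed signal: value k
compares the template with ``signal[k : k+L]``. Because both the window
and the template are mean-subtracted and variance-normalized, NCC is
bounded in [-1, 1] and invariant to any positive rescaling or offset of
the signal — the reason the detector needs no amplitude calibration.

Beats are the NCC local maxima with prominence >= 0.5 that survive a
0.5 s minimum-distance pruning (higher peak wins; equal heights, earlier
wins). Each retained lag is reported as a beat at the template's anchor
position, ``(lag + anchor) / fs`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DegenerateTemplateError, LengthError
from .preprocess import preprocess_channel
from .records import DetectorConfig, WaveformRecord, resample_linear
from .template import HeartbeatTemplate, auto_select_template

#: records sampled below this rate are linearly oversampled to 1 kHz
#: before detection, to give beat times adequate temporal resolution
MIN_DETECTION_FS = 500.0
OVERSAMPLE_FS = 1000.0


@dataclass
class NCCSeries:
    """Per-lag normalized cross-correlation, aligned to the signal grid."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class BeatDetections:
    """Detected beat times with the NCC value at each matched peak."""

    beat_times_s: np.ndarray
    ncc_at_peak: np.ndarray
    template_ref: HeartbeatTemplate | None = None

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.ncc_at_peak = np.asarray(self.ncc_at_peak, dtype=float)

    def __len__(self) -> int:
        return len(self.beat_times_s)


@dataclass
class IBISeries:
    """Inter-beat intervals (ms) between consecutive detections."""

    ibis_ms: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ibis_ms = np.asarray(self.ibis_ms, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.ibis_ms), dtype=bool)


def normalized_cross_correlation(x: np.ndarray, template: np.ndarray) -> NCCSeries:
    """Zero-normalized (Pearson) sliding correlation of template vs. signal.

    Computed with running window sums, O(N) after the correlation product;
    signal windows with zero variance yield NCC 0 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    if isinstance(template, HeartbeatTemplate):
        fs, t = template.fs, np.asarray(template.waveform, dtype=float)
    else:
        fs, t = float("nan"), np.asarray(template, dtype=float)
    L = len(t)
    if L > len(x):
        raise LengthError("template longer than signal")
    t0 = t - t.mean()
    t_norm = np.sqrt(np.sum(t0**2))
    if t_norm == 0:
        raise DegenerateTemplateError("constant template has no shape to match")

    # numerator: correlation of the signal with the zero-mean template
    num = np.correlate(x, t0, mode="valid")
    # denominator: sqrt of the windowed sum of squared deviations
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x**2)))
    win_sum = csum[L:] - csum[:-L]
    win_sum2 = csum2[L:] - csum2[:-L]
    win_ssd = np.maximum(win_sum2 - win_sum**2 / L, 0.0)
    denom = t_norm * np.sqrt(win_ssd)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, num / denom, 0.0)
    return NCCSeries(values=np.clip(values, -1.0, 1.0), fs=fs)


def detect_ncc_peaks(
    ncc: NCCSeries, cfg: DetectorConfig | None = None, fs: float | None = None
) -> np.ndarray:
    """NCC peak lags (samples) after prominence and min-distance selection.

    All local maxima with prominence >= ``ncc_min_prominence`` are ranked
    by height (ties broken toward the earlier peak) and greedily retained
    unless a taller already-kept peak lies within ``ncc_min_distance_s``.
    """
    cfg = cfg or DetectorConfig()
    fs = fs if fs is not None else ncc.fs
    idx, _ = sps.find_peaks(ncc.values, prominence=cfg.ncc_min_prominence)
    if len(idx) == 0:
        return idx
    min_dist = cfg.ncc_min_distance_s * fs
    order = sorted(range(len(idx)), key=lambda i: (-ncc.values[idx[i]], idx[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(idx[i] - idx[j]) >= min_dist for j in kept):
            kept.append(i)
    return np.sort(idx[kept])


def beats_from_ncc_peaks(
    peak_lags: np.ndarray,
    template: HeartbeatTemplate,
    fs: float,
    ncc: NCCSeries | None = None,
) -> BeatDetections:
    """Convert NCC peak lags into beat times at the template anchor.

    Lag k aligns the template start with sample k, so the heartbeat
    landmark (the envelope peak that anchored the template) falls at
    ``(k + anchor_offset_samples) / fs`` seconds.
    """
    peak_lags = np.asarray(peak_lags, dtype=int)
    times = (peak_lags + template.anchor_offset_samples) / fs
    ncc_vals = (
        ncc.values[peak_lags] if ncc is not None else np.full(len(peak_lags), np.nan)
    )
    return BeatDetections(beat_times_s=times, ncc_at_peak=ncc_vals, template_ref=template)


def compute_ibis(beats: BeatDetections | np.ndarray) -> IBISeries:
    """Inter-beat intervals in ms between consecutive detections."""
    times = beats.beat_times_s if isinstance(beats, BeatDetections) else np.asarray(beats)
    return IBISeries(ibis_ms=np.diff(times) * 1000.0)


def detect_heartbeats(
    record: WaveformRecord,
    channel: str,
    cfg: DetectorConfig | None = None,
    role: str | None = None,
) -> tuple[BeatDetections, HeartbeatTemplate, NCCSeries]:
    """Run the full detector on one cardiomechanical channel.

    Pipeline: (oversample low-rate records to 1 kHz) -> role-specific
    conditioning -> automatic template selection -> NCC against the whole
    signal -> peak localization -> beat-time reconstruction. Returns the
    detections together with the template and the NCC trace so every
    intermediate can be inspected.
    """
    cfg = cfg or DetectorConfig()
    role = role or record.channel_roles.get(channel)
    if role not in ("scg", "gcg", "fcg_raw", "dhf_fcg"):
        from .errors import ConfigError

        raise ConfigError(f"detection requires a cardiomechanical role, got {role!r}")
    if record.fs < MIN_DETECTION_FS:
        record = resample_linear(record, OVERSAMPLE_FS)
    fs = record.fs
    if record.n_samples < int(round(cfg.window_s * fs)):
        raise LengthError("record shorter than one template-search window")
    x = preprocess_channel(record, channel, role=role, cfg=cfg)
    template = auto_select_template(x, fs, cfg)
    ncc = normalized_cross_correlation(x, template.waveform)
    ncc.fs = fs
    lags = detect_ncc_peaks(ncc, cfg, fs=fs)
    beats = beats_from_ncc_peaks(lags, template, fs, ncc=ncc)
    return beats, template, ncc
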