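"""Signal conditioning for cardiomechanical and ECG channels.

The cardiac component of SCG/GCG signals lives in the 7-30 Hz band; it is
isolated with a 4th-order zero-lag Butterworth band-pass. Raw force (FCG)
signals additionally carry a large respiratory baseline that is estimated
with a 3rd-order Savitzky-Golay smoother over a ~1.5 s frame and
subtracted, and after band-passing the first forward difference is taken
(dHF-FCG). ECG channels get a 0.5-40 Hz band-pass plus a powerline notch
bank.

"Zero-lag" means forward-backward application of the stated-order filter
(scipy ``sosfiltfilt``), so the effective magnitude response is the square
of the single-pass response and the phase response is identically zero.
Finite records are edge-padded by reflection (sosfiltfilt's default
padding) before the backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, LengthError
from .records import DetectorConfig, WaveformRecord


@dataclass
class FilterSpec:
    """Specification of one conditioning filter."""

    kind: str  # bandpass | lowpass | notch
    order: int
    cutoffs: tuple[float, ...]  # Hz
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "lowpass", "notch"):
            raise ConfigError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")


def _design_butter_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    nyq = fs / 2
    if any(c >= nyq for c in spec.cutoffs):
        raise ConfigError(f"cutoffs {spec.cutoffs} must be below Nyquist {nyq} Hz")
    if any(c <= 0 for c in spec.cutoffs):
        raise ConfigError("cutoffs must be positive")
    if spec.kind == "bandpass":
        return sps.butter(spec.order, spec.cutoffs, btype="bandpass", fs=fs, output="sos")
    if spec.kind == "lowpass":
        return sps.butter(spec.order, spec.cutoffs[0], btype="lowpass", fs=fs, output="sos")
    raise ConfigError("use notch_powerline for notch filters")


def butterworth_zero_lag(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply a Butterworth filter forward and backward (zero phase).

    Output has the same length as the input. Raises
    :class:`~beatmatch.errors.LengthError` when the record is shorter than
    the reflective edge padding requires.
    """
    x = np.asarray(x, dtype=float)
    sos = _design_butter_sos(spec, fs)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= padlen:
        raise LengthError(f"signal of {len(x)} samples too short for padlen {padlen}")
    return sps.sosfiltfilt(sos, x)


def bandpass_cardiac(x: np.ndarray, fs: float, cfg: DetectorConfig) -> np.ndarray:
    """7-30 Hz (configurable) zero-lag band-pass isolating the cardiac band."""
    spec = FilterSpec("bandpass", cfg.bp_order, (cfg.band_low_hz, cfg.band_high_hz))
    return butterworth_zero_lag(x, fs, spec)


def notch_powerline(
    x: np.ndarray, fs: float, base_hz: float = 50.0, n_harmonics: int = 10, q: float = 35.0
) -> np.ndarray:
    """Remove powerline interference and harmonics with zero-lag IIR notches.

    Second-order notches (quality factor ``q``) at ``base_hz`` and its
    harmonics; harmonics at or above Nyquist are silently skipped.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2
    if base_hz >= nyq:
        raise ConfigError(f"notch base {base_hz} Hz is at or above Nyquist {nyq} Hz")
    y = x
    for k in range(1, n_harmonics + 1):
        f0 = k * base_hz
        if f0 >= nyq:
            break
        b, a = sps.iirnotch(f0, q, fs=fs)
        padlen = 3 * max(len(a), len(b))
        if len(y) <= padlen:
            raise LengthError("signal too short for notch filtering")
        y = sps.filtfilt(b, a, y)
    return y


def savgol_frame_length(fs: float, frame_s: float, n_samples: int) -> int:
    """Nearest odd integer to ``frame_s * fs``, clamped to the signal length."""
    frame = int(round(frame_s * fs))
    if frame % 2 == 0:
        frame += 1
    max_odd = n_samples if n_samples % 2 == 1 else n_samples - 1
    return min(frame, max_odd)


def remove_respiration_savgol(
    raw_fcg: np.ndarray, fs: float, order: int = 3, frame_s: float = 1.5
) -> np.ndarray:
    """Subtract the Savitzky-Golay respiratory baseline from a raw FCG signal.

    A polynomial smoother of the given order over a frame of ~``frame_s``
    seconds tracks the slow (< ~0.5 Hz) respiratory component; returning
    ``raw - smoothed`` leaves the cardiac component.
    """
    raw_fcg = np.asarray(raw_fcg, dtype=float)
    frame = savgol_frame_length(fs, frame_s, len(raw_fcg))
    if frame <= order or len(raw_fcg) < frame:
        raise LengthError(
            f"signal of {len(raw_fcg)} samples shorter than Savitzky-Golay frame"
        )
    baseline = sps.savgol_filter(raw_fcg, frame, order)
    return raw_fcg - baseline


def forward_difference(x: np.ndarray, fs: float) -> np.ndarray:
    """First forward difference scaled to units per second; length n-1."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise LengthError("forward difference needs at least 2 samples")
    return np.diff(x) * fs


def preprocess_channel(
    record: WaveformRecord, channel: str, role: str | None = None, cfg: DetectorConfig | None = None
) -> np.ndarray:
    """Condition one channel according to its role.

    scg/gcg/dhf_fcg -> cardiac band-pass; fcg_raw -> respiration removal,
    band-pass, forward difference (output one sample shorter); ecg ->
    0.5-40 Hz band-pass plus powerline notch bank.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate_for_fs(record.fs)
    role = role or record.channel_roles.get(channel)
    x = record.samples[channel]
    fs = record.fs
    if role in ("scg", "gcg", "dhf_fcg"):
        return bandpass_cardiac(x, fs, cfg)
    if role == "fcg_raw":
        cardiac = remove_respiration_savgol(x, fs, cfg.savgol_order, cfg.savgol_frame_s)
        hf = bandpass_cardiac(cardiac, fs, cfg)
        return forward_difference(hf, fs)
    if role == "ecg":
        spec = FilterSpec("bandpass", cfg.bp_order, tuple(cfg.ecg_band))
        y = butterworth_zero_lag(x, fs, spec)
        return notch_powerline(y, fs, base_hz=cfg.notch_base_hz)
    raise ConfigError(f"unknown or missing role {role!r} for channel {channel!r}")
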