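"""Data model and I/O for uniformly sampled cardiomechanical records.

A :class:`WaveformRecord` holds one or more equal-length channels sampled at
a common rate ``fs``; sample ``n`` of any channel is taken at time ``n/fs``
seconds (0-based). Channel roles tag each channel with what it measures:
chest acceleration (``scg``), chest angular rate (``gcg``), raw force
(``fcg_raw``), the derivative of the high-frequency force component
(``dhf_fcg``), an ECG reference, or ``other``.

Waveforms travel as delimited text with one header row and an optional
leading ``time`` column; beat annotations as CSV with columns
``sample,time_s,label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, SamplingError

CHANNEL_ROLES = ("scg", "gcg", "fcg_raw", "dhf_fcg", "ecg", "other")


@dataclass
class WaveformRecord:
    """Uniformly sampled multi-channel waveform.

    Parameters
    ----------
    samples : dict of str -> ndarray
        One equal-length 1-D float array per channel name.
    fs : float
        Sampling rate in Hz (> 0).
    channel_roles : dict of str -> str
        Role of each channel, one of :data:`CHANNEL_ROLES`.
    record_id : str
        Free-text identifier.
    """

    samples: dict[str, np.ndarray]
    fs: float
    channel_roles: dict[str, str] = field(default_factory=dict)
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if not self.samples:
            raise FormatError("record has no channels")
        self.samples = {k: np.asarray(v, dtype=float).ravel() for k, v in self.samples.items()}
        lengths = {len(v) for v in self.samples.values()}
        if len(lengths) != 1:
            raise FormatError(f"channels have unequal lengths: {sorted(lengths)}")
        if lengths.pop() < 1:
            raise FormatError("channels must contain at least one sample")
        for ch, role in self.channel_roles.items():
            if role not in CHANNEL_ROLES:
                raise ConfigError(f"unknown role {role!r} for channel {ch!r}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.samples.values())))

    @property
    def duration_s(self) -> float:
        """Time of the last sample, (n-1)/fs."""
        return (self.n_samples - 1) / self.fs

    @property
    def channels(self) -> list[str]:
        return list(self.samples)

    def channel_by_role(self, role: str) -> str:
        """Return the first channel name carrying ``role``."""
        for ch, r in self.channel_roles.items():
            if r == role:
                return ch
        raise ConfigError(f"no channel with role {role!r}")


@dataclass
class BeatAnnotations:
    """Detected or reference beat times in seconds, strictly increasing."""

    beat_times: np.ndarray
    source: str = "template_matching"  # template_matching | ecg_rpeak | ground_truth
    labels: list[str] | None = None  # optional per-beat TP/FP marks

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float).ravel()
        if len(self.beat_times) > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise FormatError("beat times must be strictly increasing")
        if self.labels is not None and len(self.labels) != len(self.beat_times):
            raise FormatError("labels length must match beat_times")

    def __len__(self) -> int:
        return len(self.beat_times)


@dataclass
class DetectorConfig:
    """All tunable parameters of the detection pipeline.

    Defaults are the published operating point: a 7-30 Hz 4th-order
    zero-lag band-pass for the cardiac component; envelope = 4th power
    low-passed at 3 Hz (2nd order, zero-lag) with peak prominence 0.25;
    a 10 s template-search window requiring >= 5 beats and IBI mean
    absolute deviation < 335 ms; beat segments from 200 ms before to
    500 ms after each envelope peak; NCC peaks with prominence 0.5 and
    minimum spacing 0.5 s.
    """

    band_low_hz: float = 7.0
    band_high_hz: float = 30.0
    bp_order: int = 4
    env_lp_hz: float = 3.0
    env_lp_order: int = 2
    env_power: int = 4
    env_min_prominence: float = 0.25
    window_s: float = 10.0
    min_beats: int = 5
    mad_threshold_ms: float = 335.0
    seg_pre_ms: float = 200.0
    seg_post_ms: float = 500.0
    ncc_min_prominence: float = 0.5
    ncc_min_distance_s: float = 0.5
    savgol_order: int = 3
    savgol_frame_s: float = 1.5
    ecg_band: tuple[float, float] = (0.5, 40.0)
    notch_base_hz: float = 50.0

    def __post_init__(self) -> None:
        numeric = {k: v for k, v in asdict(self).items() if k != "ecg_band"}
        for name, value in numeric.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        lo, hi = self.ecg_band
        if not (0 < lo < hi):
            raise ConfigError(f"invalid ecg_band {self.ecg_band}")
        if not self.band_low_hz < self.band_high_hz:
            raise ConfigError("band_low_hz must be below band_high_hz")

    def validate_for_fs(self, fs: float) -> None:
        if self.band_high_hz >= fs / 2:
            raise ConfigError(
                f"band_high_hz={self.band_high_hz} must be below Nyquist {fs / 2}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "DetectorConfig":
        """Load a config from a YAML mapping of field names to values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise FormatError(f"config file {path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "ecg_band" in data:
            data = dict(data)
            data["ecg_band"] = tuple(data["ecg_band"])
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["ecg_band"] = list(data["ecg_band"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_waveform_csv(
    path: str | Path,
    fs: float | str = "from header",
    roles: Mapping[str, str] | None = None,
    record_id: str | None = None,
) -> WaveformRecord:
    """Read a delimited-text waveform into a :class:`WaveformRecord`.

    The file must have one header row; a leading column named ``time``
    (seconds) is used to derive ``fs`` after checking uniform spacing to a
    relative tolerance of 1e-6. Otherwise ``fs`` must be given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"{path} contains no data rows")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"column {col!r} in {path} is not numeric")
    if df.isna().any().any():
        raise FormatError(f"{path} has missing values (ragged rows?)")

    if df.columns[0].strip().lower() == "time":
        t = df.iloc[:, 0].to_numpy(dtype=float)
        if len(t) < 2:
            raise SamplingError("time column needs at least two samples to derive fs")
        dt = np.diff(t)
        if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
            raise SamplingError(f"time column in {path} is not uniformly spaced")
        fs_derived = 1.0 / dt[0]
        if fs not in ("from header", None) and abs(float(fs) - fs_derived) > 1e-6 * fs_derived:
            raise SamplingError(
                f"given fs={fs} conflicts with time column spacing ({fs_derived:g} Hz)"
            )
        fs_value = fs_derived
        df = df.iloc[:, 1:]
        if df.shape[1] == 0:
            raise FormatError(f"{path} has a time column but no signal channels")
    else:
        if fs in ("from header", None):
            raise ConfigError(f"{path} has no time column; fs must be provided")
        fs_value = float(fs)

    samples = {str(c): df[c].to_numpy(dtype=float) for c in df.columns}
    roles = dict(roles or {})
    return WaveformRecord(
        samples=samples,
        fs=fs_value,
        channel_roles=roles,
        record_id=record_id or path.stem,
    )


def write_waveform_csv(path: str | Path, record: WaveformRecord, time_column: bool = True) -> None:
    """Write a record as CSV, optionally with a leading time column."""
    data = {}
    if time_column:
        data["time"] = np.arange(record.n_samples) / record.fs
    data.update(record.samples)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def write_beat_annotations(path: str | Path, ann: BeatAnnotations, fs: float) -> None:
    """Write beats as ``sample,time_s,label`` rows (sample = round(t*fs))."""
    if fs <= 0:
        raise ConfigError(f"fs must be positive, got {fs}")
    labels = ann.labels if ann.labels is not None else [""] * len(ann)
    df = pd.DataFrame(
        {
            "sample": np.rint(ann.beat_times * fs).astype(int),
            "time_s": [f"{t:.6f}" for t in ann.beat_times],
            "label": labels,
        }
    )
    df.to_csv(path, index=False)


def read_beat_annotations(path: str | Path, source: str = "template_matching") -> BeatAnnotations:
    """Read beats written by :func:`write_beat_annotations`."""
    df = pd.read_csv(path)
    required = {"sample", "time_s", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path} is missing columns {sorted(required - set(df.columns))}")
    labels = None
    if df["label"].notna().any():
        labels = ["" if pd.isna(v) else str(v) for v in df["label"]]
    return BeatAnnotations(
        beat_times=df["time_s"].to_numpy(dtype=float), source=source, labels=labels
    )


def resample_linear(record: WaveformRecord, target_fs: float) -> WaveformRecord:
    """Linearly interpolate all channels onto a uniform ``target_fs`` grid.

    The new grid is 0, 1/target_fs, ... up to the last original sample time;
    the first sample is preserved exactly. This mirrors the oversampling of
    low-rate recordings (e.g. 256 Hz) to 1 kHz before detection.
    """
    if target_fs <= 0:
        raise ConfigError(f"target_fs must be positive, got {target_fs}")
    t_old = np.arange(record.n_samples) / record.fs
    # tiny epsilon guards float rounding when target_fs is a multiple of fs
    n_new = int(np.floor(t_old[-1] * target_fs + 1e-9)) + 1
    t_new = np.arange(n_new) / target_fs
    samples = {ch: np.interp(t_new, t_old, v) for ch, v in record.samples.items()}
    return WaveformRecord(
        samples=samples,
        fs=float(target_fs),
        channel_roles=dict(record.channel_roles),
        record_id=record.record_id,
    )
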