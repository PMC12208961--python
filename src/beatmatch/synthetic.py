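"""Seedable generator of paired cardiomechanical + ECG records.

Real SCG/GCG/FCG recordings are quasi-periodic trains of short wave
packets in the 7-30 Hz band, amplitude-modulated by respiration and buried
in broadband noise, alongside a simultaneous ECG whose R peaks precede the
mechanical events by a roughly constant electromechanical delay. This
module emulates that structure with known ground truth so every stage of
the detector can be tested without real data.

The heartbeat kernel is a sum of Gabor atoms forming two complexes: a
multi-wave systolic complex spanning roughly -100..+250 ms around the
anchor (mitral closure, aortic opening, ejection sub-waves at 13-24 Hz)
and a smaller diastolic complex ~320-385 ms after the anchor — matching
the morphology of real cardiomechanical beats within the analysis band.
A "pathological" mode jitters atom amplitudes and latencies per beat to
mimic the unstable morphologies of diseased hearts.

Inter-beat intervals follow mean IBI + AR(1) variability + respiratory
sinus arrhythmia; realized noise is calibrated so the in-band (7-30 Hz)
signal-to-noise ratio equals ``snr_db`` exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .records import WaveformRecord

_AR1_COEF = 0.4
_MIN_IBI_MS = 300.0
_EM_DELAY_S = 0.040  # R peak precedes the mechanical anchor by 40 ms


@dataclass
class GaborAtom:
    """One Gaussian-windowed cosine packet of the heartbeat kernel."""

    freq_hz: float
    sigma_s: float
    amplitude: float
    latency_s: float  # center offset relative to the beat anchor

    def waveform(self, t: np.ndarray) -> np.ndarray:
        u = t - self.latency_s
        return self.amplitude * np.exp(-(u**2) / (2 * self.sigma_s**2)) * np.cos(
            2 * np.pi * self.freq_hz * u
        )


#: systolic (anchor) + diastolic complexes; carrier frequencies inside 7-30 Hz.
#: Real cardiomechanical beats are oscillatory trains: the systolic complex
#: spans ~300 ms with several sub-waves (mitral closure, aortic opening,
#: ejection), the diastolic complex (~aortic closure, rapid filling) follows
#: ~320 ms after the anchor at reduced amplitude.
DEFAULT_KERNEL: tuple[GaborAtom, ...] = (
    GaborAtom(freq_hz=18.0, sigma_s=0.018, amplitude=0.45, latency_s=-0.060),
    GaborAtom(freq_hz=15.0, sigma_s=0.022, amplitude=1.0, latency_s=0.0),
    GaborAtom(freq_hz=21.0, sigma_s=0.018, amplitude=0.65, latency_s=0.065),
    GaborAtom(freq_hz=13.0, sigma_s=0.024, amplitude=0.50, latency_s=0.135),
    GaborAtom(freq_hz=24.0, sigma_s=0.015, amplitude=0.30, latency_s=0.200),
    GaborAtom(freq_hz=12.0, sigma_s=0.020, amplitude=0.40, latency_s=0.320),
    GaborAtom(freq_hz=16.0, sigma_s=0.016, amplitude=0.22, latency_s=0.385),
)


@dataclass
class SynthParams:
    """Generator settings; defaults emulate a healthy supine recording."""

    duration_s: float = 120.0
    fs: float = 1000.0
    mean_hr_bpm: float = 70.0
    ibi_sd_ms: float = 30.0
    rsa_depth_ms: float = 20.0
    resp_rate_hz: float = 0.25
    kernel: tuple[GaborAtom, ...] = DEFAULT_KERNEL
    amp_mod_depth: float = 0.2
    snr_db: float = 20.0
    morph_jitter: float = 0.0  # 0 = healthy; >0 scales per-beat morphology jitter
    include_fcg: bool = False
    n_artifact_bursts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * max(a.freq_hz for a in self.kernel):
            raise ParameterError("fs must exceed twice the highest kernel frequency")
        mean_ibi_s = 60.0 / self.mean_hr_bpm
        kernel_span = max(a.latency_s + 3 * a.sigma_s for a in self.kernel)
        if mean_ibi_s <= kernel_span:
            raise ParameterError("mean IBI must exceed the kernel duration")
        if not 0 <= self.amp_mod_depth < 1:
            raise ParameterError("amp_mod_depth must be in [0, 1)")
        if not np.isfinite(self.snr_db):
            raise ParameterError("snr_db must be finite")


@dataclass
class SynthRecord:
    """A generated record plus its ground truth."""

    record: WaveformRecord
    truth_beats: np.ndarray  # mechanical anchor times (s)
    truth_r_peaks: np.ndarray  # ECG R-peak times = truth_beats - 40 ms
    params: SynthParams = None  # type: ignore[assignment]
    burst_times: np.ndarray = field(default_factory=lambda: np.empty(0))


def pathological_preset(**overrides) -> SynthParams:
    """Unstable-morphology preset: strong per-beat jitter, higher IBI SD."""
    defaults = dict(morph_jitter=1.0, ibi_sd_ms=60.0)
    defaults.update(overrides)
    return SynthParams(**defaults)


def synth_ibi_sequence(params: SynthParams, n_beats: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate ``n_beats`` inter-beat intervals in ms.

    IBI_i = 60000/mean_hr + AR(1) noise (coefficient 0.4, innovation SD
    chosen so the stationary SD equals ``ibi_sd_ms``) + respiratory sinus
    arrhythmia ``rsa_depth * sin(2 pi resp_rate t_i)`` evaluated at the
    running beat time. IBIs are clamped at 300 ms; parameters that force
    clamping of more than 5% of beats are rejected.
    """
    if n_beats < 1:
        raise ParameterError("n_beats must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    base = 60000.0 / params.mean_hr_bpm
    innov_sd = params.ibi_sd_ms * np.sqrt(1 - _AR1_COEF**2)
    ibis = np.empty(n_beats)
    ar = 0.0
    t = 0.0
    n_clamped = 0
    for i in range(n_beats):
        ar = _AR1_COEF * ar + rng.normal(0.0, innov_sd) if params.ibi_sd_ms > 0 else 0.0
        rsa = params.rsa_depth_ms * np.sin(2 * np.pi * params.resp_rate_hz * t)
        ibi = base + ar + rsa
        if ibi < _MIN_IBI_MS:
            ibi = _MIN_IBI_MS
            n_clamped += 1
        ibis[i] = ibi
        t += ibi / 1000.0
    if n_clamped > 0.05 * n_beats:
        raise ParameterError(
            f"{n_clamped}/{n_beats} IBIs clamped at {_MIN_IBI_MS} ms; "
            "reduce variability or raise mean IBI"
        )
    return ibis


def _kernel_train(
    t: np.ndarray,
    beat_times: np.ndarray,
    kernel: tuple[GaborAtom, ...],
    fs: float,
    jitter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Superpose one kernel instance per beat, optionally jittered per beat."""
    x = np.zeros_like(t)
    span = max(a.latency_s + 4 * a.sigma_s for a in kernel) + 0.05
    pre = min(a.latency_s - 4 * a.sigma_s for a in kernel) - 0.05
    for tb in beat_times:
        atoms = kernel
        if jitter > 0:
            # amplitudes perturbed +-40%, latencies +-20 ms at jitter=1
            atoms = tuple(
                replace(
                    a,
                    amplitude=a.amplitude * (1 + jitter * rng.uniform(-0.4, 0.4)),
                    latency_s=a.latency_s + jitter * rng.uniform(-0.020, 0.020),
                )
                for a in kernel
            )
        lo = max(0, int((tb + pre) * fs))
        hi = min(len(t), int((tb + span) * fs) + 1)
        seg = t[lo:hi] - tb
        for a in atoms:
            x[lo:hi] += a.waveform(seg)
    return x


def _band_power(x: np.ndarray, fs: float, lo: float = 7.0, hi: float = 30.0) -> float:
    f, pxx = sps.periodogram(x, fs=fs)
    band = (f >= lo) & (f <= hi)
    return float(np.trapezoid(pxx[band], f[band]))


def _ecg_wave(t: np.ndarray, r_times: np.ndarray, fs: float) -> np.ndarray:
    """QRS spikes (Mexican-hat, ~20 ms) with small P and T bumps."""
    ecg = np.zeros_like(t)
    for tr in r_times:
        lo = max(0, int((tr - 0.35) * fs))
        hi = min(len(t), int((tr + 0.45) * fs) + 1)
        u = t[lo:hi] - tr
        qrs = (1 - (u / 0.012) ** 2) * np.exp(-(u**2) / (2 * 0.012**2))
        p = 0.15 * np.exp(-((u + 0.16) ** 2) / (2 * 0.025**2))
        tw = 0.3 * np.exp(-((u - 0.30) ** 2) / (2 * 0.05**2))
        ecg[lo:hi] += qrs + p + tw
    return ecg


def generate_record(params: SynthParams) -> SynthRecord:
    """Build a fully deterministic synthetic record from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    # ground-truth beat times: start after the first R-T span, stop at the end
    t0 = 0.5
    max_beats = int(np.ceil(params.duration_s / (60.0 / params.mean_hr_bpm))) + 10
    ibis = synth_ibi_sequence(params, max_beats, rng=rng)
    beats = t0 + np.concatenate(([0.0], np.cumsum(ibis / 1000.0)))
    # keep every beat whose kernel support fits inside the record
    kernel_tail = max(a.latency_s + 4 * a.sigma_s for a in params.kernel) + 0.05
    beats = beats[beats < params.duration_s - kernel_tail]
    r_peaks = beats - _EM_DELAY_S

    clean = _kernel_train(t, beats, params.kernel, params.fs, params.morph_jitter, rng)
    resp_mod = 1.0 + params.amp_mod_depth * np.sin(2 * np.pi * params.resp_rate_hz * t)
    clean = clean * resp_mod

    # white + pink noise mixed 1:1 by power, scaled so the 7-30 Hz band SNR
    # equals snr_db exactly
    white = rng.standard_normal(n)
    pink = _pink_noise(n, rng)
    noise = white / np.sqrt(_band_power(white, params.fs)) + pink / np.sqrt(
        _band_power(pink, params.fs)
    )
    sig_bp = _band_power(clean, params.fs)
    noise_bp = _band_power(noise, params.fs)
    target_noise_bp = sig_bp / 10 ** (params.snr_db / 10.0)
    noise *= np.sqrt(target_noise_bp / noise_bp)
    scg = clean + noise

    ecg = _ecg_wave(t, r_peaks, params.fs)
    ecg += 0.02 * rng.standard_normal(n)

    samples = {"scg": scg, "ecg": ecg}
    roles = {"scg": "scg", "ecg": "ecg"}
    if params.include_fcg:
        respiration = 5.0 * np.sin(2 * np.pi * 0.3 * t)  # 0.2-0.4 Hz baseline
        samples["fcg"] = clean + respiration + 0.5 * noise
        roles["fcg"] = "fcg_raw"

    record = WaveformRecord(
        samples=samples,
        fs=params.fs,
        channel_roles=roles,
        record_id=f"synth-seed{params.seed}",
    )
    return SynthRecord(record=record, truth_beats=beats, truth_r_peaks=r_peaks, params=params)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if len(f) > 1 else 1.0
    spec /= np.sqrt(f)
    return np.fft.irfft(spec, n)


def inject_spurious_bursts(
    synth: SynthRecord,
    n: int,
    magnitude: float = 3.0,
    seed: int = 0,
    channel: str = "scg",
    protect: tuple[float, float] | None = None,
) -> tuple[SynthRecord, np.ndarray]:
    """Add broadband motion-artifact bursts to one channel.

    ``n`` bursts of 100-300 ms, each in-band (7-30 Hz) noise scaled to
    ``magnitude`` times the channel's peak amplitude, placed uniformly at
    random while avoiding the ``protect`` interval (seconds). Restricting
    the burst spectrum to the cardiac analysis band makes the stated
    ``magnitude`` meaningful after the detector's band-pass stage.
    Returns the modified record (a copy) and the burst center times.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    rec = synth.record
    x = rec.samples[channel].copy()
    fs = rec.fs
    duration = rec.n_samples / fs
    peak = np.max(np.abs(x)) or 1.0
    sos = sps.butter(2, [7.0, 30.0], btype="bandpass", fs=fs, output="sos")
    times = []
    attempts = 0
    while len(times) < n and attempts < 1000 * max(n, 1):
        attempts += 1
        tc = rng.uniform(0.2, duration - 0.2)
        if protect is not None and protect[0] <= tc <= protect[1]:
            continue
        width = rng.uniform(0.100, 0.300)
        lo = max(0, int((tc - width / 2) * fs))
        hi = min(len(x), int((tc + width / 2) * fs))
        burst = sps.sosfiltfilt(sos, rng.standard_normal(hi - lo))
        burst *= sps.windows.tukey(hi - lo, 0.5)
        x[lo:hi] += magnitude * peak * burst / max(np.max(np.abs(burst)), 1e-12)
        times.append(tc)
    samples = dict(rec.samples)
    samples[channel] = x
    new_rec = WaveformRecord(
        samples=samples, fs=fs, channel_roles=dict(rec.channel_roles), record_id=rec.record_id
    )
    return (
        SynthRecord(
            record=new_rec,
            truth_beats=synth.truth_beats,
            truth_r_peaks=synth.truth_r_peaks,
            params=synth.params,
            burst_times=np.sort(np.asarray(times)),
        ),
        np.sort(np.asarray(times)),
    )
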