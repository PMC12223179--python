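"""Energy-based impulse detection and feature screening in calibrated audio.

Stage 1 of the click-identification chain: raw 16-bit counts are converted
to absolute sound pressure with the hydrophone calibration, a 5 kHz
high-pass isolates the echolocation band, impulses are located where the
Hilbert envelope exceeds an adaptive (MAD-based) noise-floor threshold, and
each detection is characterised by its -10 dB envelope duration, peak
frequency on a 500 Hz spectral grid, peak-to-peak received level, envelope
asymmetry ratio, and clipping flag.  A feature filter then retains only
detections inside the acceptance envelope (duration 30-1200 us, peak
frequency 5-100 kHz, envelope ratio -0.5..0.9, RL >= 118 dB_pp, unclipped).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, hilbert, sosfiltfilt

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationSpec",
    "DetectorConfig",
    "ImpulseDetection",
    "counts_to_pressure",
    "pressure_to_counts",
    "read_wav_counts",
    "detect_impulses",
    "compute_click_features",
    "filter_impulses",
]


@dataclass(frozen=True)
class CalibrationSpec:
    """Flat-response hydrophone calibration.

    The conversion chain is counts -> volts (ADC full scale) -> uPa via the
    end-to-end sensitivity ``sensitivity + gain`` in dB re V/uPa.  A flat
    frequency response is assumed over the band of interest.
    """

    sensitivity_db_re_v_per_upa: float = -200.0
    preamp_gain_db: float = 50.0
    adc_vpp: float = 2.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.bit_depth not in (16, 24):
            raise ValueError("bit_depth must be 16 or 24")
        if not self.adc_vpp > 0:
            raise ValueError("adc_vpp must be positive")

    @property
    def full_scale_counts(self) -> int:
        return 2 ** (self.bit_depth - 1) - 1

    @property
    def counts_per_upa(self) -> float:
        """Linear transfer: counts produced by 1 uPa."""
        v_per_upa = 10.0 ** ((self.sensitivity_db_re_v_per_upa + self.preamp_gain_db) / 20.0)
        counts_per_volt = self.full_scale_counts / (self.adc_vpp / 2.0)
        return v_per_upa * counts_per_volt


@dataclass(frozen=True)
class DetectorConfig:
    highpass_hz: float = 5000.0
    min_rl_db_pp: float = 118.0
    duration_bounds_us: tuple[float, float] = (30.0, 1200.0)
    peak_freq_bounds_khz: tuple[float, float] = (5.0, 100.0)
    envelope_ratio_bounds: tuple[float, float] = (-0.5, 0.9)
    clip_fraction: float = 0.98
    spectrum_window_samples: int = 200
    spectrum_resolution_hz: float = 500.0
    threshold_factor: float = 4.0
    dead_time_us: float = 500.0

    def __post_init__(self) -> None:
        for name in ("duration_bounds_us", "peak_freq_bounds_khz", "envelope_ratio_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered pair")
        if not 0 < self.clip_fraction <= 1:
            raise ValueError("clip_fraction must be in (0, 1]")


@dataclass
class ImpulseDetection:
    time_s: float
    snippet: np.ndarray = field(repr=False)
    duration_us: float = np.nan
    peak_freq_khz: float = np.nan
    rl_db_pp: float = np.nan
    envelope_ratio: float = np.nan
    spectrum: np.ndarray | None = field(default=None, repr=False)
    clipped: bool = False
    label: str | None = None  # ground-truth label, when known


def counts_to_pressure(samples, cal: CalibrationSpec) -> np.ndarray:
    """Linear counts -> uPa conversion through the calibration chain."""
    return np.asarray(samples, dtype=float) / cal.counts_per_upa


def pressure_to_counts(pressure_upa, cal: CalibrationSpec) -> np.ndarray:
    """Inverse of :func:`counts_to_pressure`; used when writing scene WAVs."""
    return np.asarray(pressure_upa, dtype=float) * cal.counts_per_upa


def read_wav_counts(path) -> tuple[int, np.ndarray]:
    """Read a 16-bit PCM WAV as integer counts, (fs_hz, samples)."""
    fs, data = wavfile.read(path)
    if data.dtype != np.int16:
        raise ValueError(f"expected 16-bit PCM WAV, got dtype {data.dtype}")
    if data.ndim > 1:
        data = data[:, 0]
    return int(fs), data.astype(np.int64)


def _highpass(x: np.ndarray, fs: float, corner_hz: float) -> np.ndarray:
    sos = butter(4, corner_hz, btype="highpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def compute_click_features(
    snippet: np.ndarray,
    fs_hz: float,
    cfg: DetectorConfig = DetectorConfig(),
):
    """Feature vector of one band-passed impulse snippet.

    * ``rl_db_pp`` = 20 log10(max - min) of the pressure series (uPa).
    * peak frequency: argmax of the magnitude spectrum of a
      ``spectrum_window_samples``-sample Hann-windowed segment centred on the
      envelope peak, zero-padded so bins fall on the 500 Hz grid.
    * duration: span where the Hilbert envelope exceeds -10 dB of its peak.
    * envelope ratio: (E_before - E_after)/(E_before + E_after) with the
      envelope energy split at the envelope maximum; bounded in [-1, 1].
    """
    x = np.asarray(snippet, dtype=float)
    if not np.any(x):
        raise ValueError("all-zero snippet: degenerate input")
    rl_db_pp = 20.0 * np.log10(np.max(x) - np.min(x))

    env = np.abs(hilbert(x))
    pk = int(np.argmax(env))

    above = env >= env[pk] * 10.0 ** (-10.0 / 20.0)
    # contiguous -10 dB region around the peak
    lo = pk
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = pk
    while hi < len(x) - 1 and above[hi + 1]:
        hi += 1
    duration_us = (hi - lo + 1) / fs_hz * 1e6

    e2 = env**2
    e_before = float(np.sum(e2[:pk]))
    e_after = float(np.sum(e2[pk + 1 :]))
    tot = e_before + e_after
    envelope_ratio = 0.0 if tot == 0 else (e_before - e_after) / tot

    nwin = cfg.spectrum_window_samples
    half = nwin // 2
    seg = x[max(0, pk - half) : pk - half + nwin]
    if len(seg) < nwin:
        seg = np.pad(seg, (0, nwin - len(seg)))
    nfft = int(round(fs_hz / cfg.spectrum_resolution_hz))
    if nfft < nwin:
        nfft = nwin
    spec = np.abs(np.fft.rfft(seg * np.hanning(nwin), n=nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs_hz)
    with np.errstate(divide="ignore"):
        spectrum_db = 20.0 * np.log10(np.where(spec > 0, spec, np.finfo(float).tiny))
    peak_freq_khz = freqs[int(np.argmax(spec))] / 1000.0
    return duration_us, peak_freq_khz, rl_db_pp, envelope_ratio, spectrum_db


def detect_impulses(
    pressure_upa: np.ndarray,
    fs_hz: float,
    cfg: DetectorConfig = DetectorConfig(),
    raw_counts: np.ndarray | None = None,
    cal: CalibrationSpec | None = None,
    snippet_ms: float = 2.0,
) -> list[ImpulseDetection]:
    """Locate impulsive signals whose envelope exceeds the adaptive threshold.

    The high-pass-filtered Hilbert envelope is compared against
    ``noise_floor x threshold_factor`` where the floor is the MAD-scaled
    median absolute envelope (median x 1.4826).  Detections closer than the
    dead time to the previous one are merged.  Detections with received
    level below ``min_rl_db_pp`` are discarded (the level floor is applied
    after high-pass filtering).  Output is time-sorted.
    """
    x = np.asarray(pressure_upa, dtype=float)
    if len(x) < cfg.spectrum_window_samples:
        warnings.warn("segment shorter than the spectrum window; no detections")
        return []
    xf = _highpass(x, fs_hz, cfg.highpass_hz)
    env = np.abs(hilbert(xf))
    floor = np.median(np.abs(env)) * 1.4826
    thresh = floor * cfg.threshold_factor

    above = env > thresh
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    dead = max(1, int(cfg.dead_time_us * 1e-6 * fs_hz))
    breaks = np.flatnonzero(np.diff(idx) > dead)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])

    half = int(snippet_ms * 1e-3 * fs_hz / 2)
    detections: list[ImpulseDetection] = []
    for a, b in zip(starts, ends):
        pk = a + int(np.argmax(env[a : b + 1]))
        lo = max(0, pk - half)
        hi = min(len(xf), pk + half)
        snippet = xf[lo:hi]
        if not np.any(snippet):
            continue
        dur, pf, rl, er, spec = compute_click_features(snippet, fs_hz, cfg)
        if rl < cfg.min_rl_db_pp:
            continue
        clipped = False
        if raw_counts is not None:
            fs_counts = (2**15 - 1) if (cal is None or cal.bit_depth == 16) else (2**23 - 1)
            clipped = bool(
                np.max(np.abs(raw_counts[lo:hi])) > cfg.clip_fraction * fs_counts
            )
        detections.append(
            ImpulseDetection(
                time_s=a / fs_hz,
                snippet=snippet,
                duration_us=dur,
                peak_freq_khz=pf,
                rl_db_pp=rl,
                envelope_ratio=er,
                spectrum=spec,
                clipped=clipped,
            )
        )
    detections.sort(key=lambda d: d.time_s)
    return detections


def filter_impulses(
    detections: list[ImpulseDetection], cfg: DetectorConfig = DetectorConfig()
) -> tuple[list[ImpulseDetection], dict[str, int]]:
    """Retain detections inside the acceptance envelope; count rejections.

    Order-preserving and idempotent.  A detection failing several rules is
    counted once under each rule it violates.
    """
    counts = {"duration": 0, "peak_freq": 0, "envelope": 0, "rl": 0, "clipped": 0}
    kept: list[ImpulseDetection] = []
    d_lo, d_hi = cfg.duration_bounds_us
    f_lo, f_hi = cfg.peak_freq_bounds_khz
    e_lo, e_hi = cfg.envelope_ratio_bounds
    for d in detections:
        ok = True
        if not d_lo <= d.duration_us <= d_hi:
            counts["duration"] += 1
            ok = False
        if not f_lo <= d.peak_freq_khz <= f_hi:
            counts["peak_freq"] += 1
            ok = False
        if not e_lo <= d.envelope_ratio <= e_hi:
            counts["envelope"] += 1
            ok = False
        if d.rl_db_pp < cfg.min_rl_db_pp:
            counts["rl"] += 1
            ok = False
        if d.clipped:
            counts["clipped"] += 1
            ok = False
        if ok:
            kept.append(d)
    return kept, counts
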