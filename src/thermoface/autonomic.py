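"""Autonomic benchmark channels: GSR preprocessing, R-peak and inter-beat
interval extraction, and time-resolved autoregressive HRV spectra.

GSR is linearly detrended, low-pass filtered with a zero-phase FIR (so the
latencies of the slow electrodermal response are preserved), and z-scored.
HRV is computed from the IBI series resampled to a uniform 2 Hz grid by
cubic spline, on 16 s sliding windows with 15-sample overlap: per window an
AR model is fitted by the Burg method, its spectral density evaluated on an
nfft grid, and power integrated over the standard vLF/LF/HF bands,
expressed as percent of the within-band total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg as _burg

from .io import SignalTrace

__all__ = [
    "GSRConfig",
    "HRVConfig",
    "IBISeries",
    "HRVSpectraSeries",
    "DEFAULT_BANDS",
    "preprocess_gsr",
    "detect_r_peaks",
    "compute_ibi",
    "hrv_spectra",
    "ar_psd",
]

#: band edges in Hz: vLF [0.003, 0.04), LF [0.04, 0.15), HF [0.15, 0.4]
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}


@dataclass(frozen=True)
class GSRConfig:
    lowpass_hz: float = 5.0
    filter_taps: int = 501
    detrend: str = "linear"

    def __post_init__(self) -> None:
        if self.filter_taps % 2 == 0:
            raise ValueError("filter_taps must be odd")
        if not self.lowpass_hz > 0:
            raise ValueError("lowpass_hz must be positive")


@dataclass(frozen=True)
class HRVConfig:
    window_s: float = 16.0
    overlap_samples: int = 15
    nfft: int = 1024
    resample_hz: float = 2.0
    ar_order: int = 16
    bands: tuple = tuple(DEFAULT_BANDS.items())

    def __post_init__(self) -> None:
        if not self.window_s * self.resample_hz > self.ar_order:
            raise ValueError("window must hold more samples than the AR order")
        win = int(round(self.window_s * self.resample_hz))
        if not 0 <= self.overlap_samples < win:
            raise ValueError("overlap_samples must be smaller than the window")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.resample_hz))

    @property
    def hop_samples(self) -> int:
        return self.window_samples - self.overlap_samples


@dataclass
class IBISeries:
    """Inter-beat intervals in ms, located at the later beat of each pair."""

    beat_t_s: np.ndarray
    ibi_ms: np.ndarray
    ibi_z: np.ndarray

    @property
    def t_s(self) -> np.ndarray:
        """Times the intervals are attributed to (second beat of each pair)."""
        return self.beat_t_s[1:]


@dataclass
class HRVSpectraSeries:
    """Percent power per band on sliding windows; ``valid`` marks windows
    with enough spectral power for the percent to be defined."""

    t_s: np.ndarray  # window centre times
    percent: np.ndarray  # (n_windows, n_bands)
    power: np.ndarray  # (n_windows, n_bands), absolute band power
    band_names: tuple[str, ...]
    valid: np.ndarray  # (n_windows,) bool


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant signal")
    return (x - x.mean()) / sd


def preprocess_gsr(raw: SignalTrace, cfg: GSRConfig = GSRConfig()) -> SignalTrace:
    """Detrend, zero-phase FIR low-pass, and z-score a raw GSR trace.

    The FIR is a windowed-sinc (Hamming) design applied forward-backward,
    so the group delay is zero and peak latencies of the slow skin
    conductance response survive filtering untouched.
    """
    if cfg.lowpass_hz >= raw.fs_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    if len(raw) < 3 * cfg.filter_taps:
        raise ValueError(
            f"trace too short ({len(raw)} samples) for a {cfg.filter_taps}-tap filter")
    x = sps.detrend(raw.values, type="linear")
    b = sps.firwin(cfg.filter_taps, cfg.lowpass_hz, fs=raw.fs_hz)
    y = sps.filtfilt(b, [1.0], x)
    return SignalTrace(_zscore(y), fs_hz=raw.fs_hz, units="z", t0_s=raw.t0_s)


def detect_r_peaks(ecg: SignalTrace, min_rr_s: float = 0.3, mad_k: float = 8.0,
                   precomputed: np.ndarray | None = None) -> np.ndarray:
    """Beat times in seconds from an ECG trace.

    Intentionally simple: peaks of a smoothed squared-derivative transform
    above an adaptive median + k*MAD threshold, with a refractory period of
    ``min_rr_s``, then refined to the local ECG maximum. Beat lists from an
    external detector (possibly manually corrected) can be passed through
    verbatim via ``precomputed``.
    """
    if precomputed is not None:
        return np.asarray(precomputed, dtype=float)
    v = ecg.values
    if not np.all(np.isfinite(v)):
        raise ValueError("ECG contains non-finite samples")
    fs = ecg.fs_hz
    d = np.gradient(v) * fs
    s = d * d
    # ~30 ms moving-average smoothing of the energy signal
    win = max(1, int(round(0.03 * fs)))
    s = np.convolve(s, np.ones(win) / win, mode="same")
    med = np.median(s)
    mad = np.median(np.abs(s - med))
    thr = med + mad_k * mad
    if mad == 0 or not np.any(s > thr):
        warnings.warn("no R peaks found", stacklevel=2)
        return np.empty(0)
    idx, _ = sps.find_peaks(s, height=thr, distance=max(1, int(round(min_rr_s * fs))))
    # refine to the ECG local maximum within +/-50 ms
    half = max(1, int(round(0.05 * fs)))
    beats = []
    for i in idx:
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        beats.append(lo + int(np.argmax(v[lo:hi])))
    beats = np.unique(beats)
    return ecg.t0_s + beats / fs


def compute_ibi(beats_s: np.ndarray) -> IBISeries:
    """Intervals in ms between successive beats, plus the z-scored variant
    (all zeros for a perfectly regular rhythm, where the SD is 0)."""
    b = np.asarray(beats_s, dtype=float)
    if len(b) < 3:
        raise ValueError("need at least 3 beats")
    if np.any(np.diff(b) <= 0):
        raise ValueError("beat times must be strictly increasing")
    ibi = np.diff(b) * 1000.0
    z = _zscore(ibi) if np.std(ibi, ddof=1) > 0 else np.zeros_like(ibi)
    return IBISeries(beat_t_s=b, ibi_ms=ibi, ibi_z=z)


def ar_psd(x: np.ndarray, order: int, fs: float, nfft: int) -> tuple[np.ndarray, np.ndarray]:
    """One-sided AR power spectral density via Burg coefficient estimation.

    Returns (freqs, psd) on the nfft/2+1 grid. The AR(p) model
    x_t = sum_k a_k x_{t-k} + e_t gives S(f) = (sigma^2/fs) / |1 - sum_k
    a_k exp(-2*pi*i*f*k/fs)|^2, doubled off DC/Nyquist for a one-sided
    spectrum.
    """
    x = np.asarray(x, dtype=float)
    ar, sigma2 = _burg(x - x.mean(), order=order, demean=False)
    # a noiseless sinusoid drives the Burg residual variance to (numerical)
    # zero or slightly negative; clamp so the PSD stays a valid density
    sigma2 = max(float(sigma2), 1e-15 * float(np.var(x)) + np.finfo(float).tiny)
    freqs = np.arange(nfft // 2 + 1) * fs / nfft
    k = np.arange(1, order + 1)
    ejw = np.exp(-2j * np.pi * np.outer(freqs / fs, k))
    denom = np.abs(1.0 - ejw @ ar) ** 2
    psd = sigma2 / fs / denom
    psd[1:-1] *= 2.0  # fold negative frequencies
    return freqs, psd


def resample_ibi(ibi: IBISeries, fs: float) -> SignalTrace:
    """Cubic-spline resampling of the IBI series onto a uniform grid."""
    t = ibi.t_s
    n = int(np.floor((t[-1] - t[0]) * fs)) + 1
    grid = t[0] + np.arange(n) / fs
    values = CubicSpline(t, ibi.ibi_ms)(grid)
    return SignalTrace(values, fs_hz=fs, units="ms", t0_s=float(t[0]))


def hrv_spectra(ibi: IBISeries, cfg: HRVConfig = HRVConfig()) -> HRVSpectraSeries:
    """Sliding-window AR-Burg band powers of the IBI series.

    Per window the mean is removed, AR coefficients are estimated by the
    Burg method, the PSD is evaluated on the nfft grid and integrated over
    each band; percents are relative to the sum over the defined bands and
    add to 100 per valid window. Windows with (numerically) zero spectral
    power are flagged invalid and carry NaN percents.
    """
    trace = resample_ibi(ibi, cfg.resample_hz)
    win, hop = cfg.window_samples, cfg.hop_samples
    x = trace.values
    if len(x) < win:
        raise ValueError(f"record ({len(x)} samples) shorter than window ({win})")
    band_names = tuple(name for name, _ in cfg.bands)
    starts = np.arange(0, len(x) - win + 1, hop)
    centres = trace.t0_s + (starts + (win - 1) / 2) / cfg.resample_hz
    power = np.zeros((len(starts), len(band_names)))
    valid = np.zeros(len(starts), dtype=bool)
    for i, s0 in enumerate(starts):
        seg = x[s0:s0 + win]
        # relative floor: beat times built from cumulative sums carry
        # ~1e-10 ms float noise that is not physiological variance
        if np.std(seg) < 1e-8 * (1.0 + abs(float(seg.mean()))):
            continue
        freqs, psd = ar_psd(seg, cfg.ar_order, cfg.resample_hz, cfg.nfft)
        for j, (_, (f_lo, f_hi)) in enumerate(cfg.bands):
            m = (freqs >= f_lo) & (freqs <= f_hi)
            if m.sum() >= 2:
                power[i, j] = np.trapezoid(psd[m], freqs[m])
        valid[i] = power[i].sum() > 0
    percent = np.full_like(power, np.nan)
    tot = power.sum(axis=1)
    percent[valid] = 100.0 * power[valid] / tot[valid, None]
    return HRVSpectraSeries(t_s=centres, percent=percent, power=power,
                            band_names=band_names, valid=valid)
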