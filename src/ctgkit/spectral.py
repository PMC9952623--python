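"""Time-variant PSD of the FHRV signal and band powers (VLF / LF / HF, SVB).

The estimator is a short-time Fourier transform with frame averaging: the
FHRV signal is resampled to a fixed 0.25 s step, cut into 32 s frames,
mean-subtracted, windowed (Hanning by default) and Fourier transformed on a
1024-point grid.  Each frame contributes

    P_i(w) = |FT(w)|^2 / (L * U * fs)      with  U = (1/L) * sum_n w(n)^2

and the reported spectrum is the average of the P_i over all frames — i.e. a
Welch-style modified periodogram average.  The extra 1/fs converts the power
spectrum into a density (bpm^2/Hz) so that the integral over frequency obeys
Parseval; the one-sided spectrum doubles every bin except DC and Nyquist.

Band powers are integrals of the mean PSD over the very-low (0–0.05 Hz), low
(0.05–0.2 Hz) and high (0.2–1 Hz) frequency bands; the sympatho-vagal
balance (SVB) is the LF/HF power ratio — high values reflect sympathetic
predominance (fetal reactivity), low values vagal predominance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import get_window

from .errors import ContractError, InsufficientDataError
from .variability import FHRVSignal

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "VLF": (0.0, 0.05),
    "LF": (0.05, 0.2),
    "HF": (0.2, 1.0),
}


@dataclass(frozen=True)
class SpectralConfig:
    window_type: str = "hann"
    window_len_s: float = 32.0
    resample_step_s: float = 0.25
    nfft: int = 1024
    overlap_fraction: float = 0.5
    detrend_frames: bool = True
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        nyq = 0.5 / self.resample_step_s
        edges = sorted(self.bands.values())
        for (l1, h1), (l2, h2) in zip(edges, edges[1:]):
            if h1 > l2:
                raise ContractError("spectral bands overlap")
        if max(h for _, h in self.bands.values()) > nyq + 1e-12:
            raise ContractError("band edge above Nyquist frequency")
        if self.nfft < self.window_len_samples:
            raise ContractError("nfft smaller than the analysis window")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ContractError("overlap_fraction must be in [0, 1)")

    @property
    def fs_hz(self) -> float:
        return 1.0 / self.resample_step_s

    @property
    def window_len_samples(self) -> int:
        return int(round(self.window_len_s * self.fs_hz))


@dataclass
class SpectralEstimate:
    freqs_hz: np.ndarray
    mean_psd: np.ndarray  # bpm^2 / Hz, one-sided
    n_frames: int
    band_power: dict[str, float] | None = None
    total_power: float | None = None
    svb: float | None = None


def _resample(values: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if math.isclose(fs_in, fs_out):
        return np.asarray(values, dtype=float)
    t_in = np.arange(values.size) / fs_in
    t_out = np.arange(0.0, t_in[-1] + 0.5 / fs_out, 1.0 / fs_out)
    t_out = t_out[t_out <= t_in[-1]]
    return CubicSpline(t_in, values)(t_out)


def compute_mean_psd(
    fhrv: FHRVSignal | np.ndarray,
    config: SpectralConfig | None = None,
    fs_hz: float | None = None,
) -> SpectralEstimate:
    """Frame-averaged one-sided PSD of the FHRV signal.

    Accepts either an :class:`FHRVSignal` or a bare array plus ``fs_hz``.
    The result already carries band powers, total power and SVB (see
    :func:`band_powers`).
    """
    config = config or SpectralConfig()
    if isinstance(fhrv, FHRVSignal):
        values, fs_in = fhrv.values_bpm, fhrv.fs_hz
    else:
        if fs_hz is None:
            raise ContractError("fs_hz required when passing a bare array")
        values, fs_in = np.asarray(fhrv, dtype=float), fs_hz
    x = _resample(values, fs_in, config.fs_hz)

    L = config.window_len_samples
    if x.size < L:
        raise InsufficientDataError("signal shorter than one analysis window")
    w = get_window(config.window_type, L, fftbins=True)
    U = float(np.mean(w**2))  # window power normalisation
    hop = max(1, int(round(L * (1.0 - config.overlap_fraction))))
    starts = range(0, x.size - L + 1, hop)

    fs = config.fs_hz
    acc = np.zeros(config.nfft // 2 + 1)
    n_frames = 0
    for s in starts:
        seg = x[s : s + L]
        if config.detrend_frames:
            seg = seg - seg.mean()
        spec = np.fft.rfft(seg * w, n=config.nfft)
        p = (np.abs(spec) ** 2) / (L * U * fs)
        acc += p
        n_frames += 1
    mean_psd = acc / n_frames
    # one-sided scaling: double everything except DC and Nyquist
    mean_psd[1:-1] *= 2.0
    freqs = np.fft.rfftfreq(config.nfft, d=1.0 / fs)
    est = SpectralEstimate(freqs_hz=freqs, mean_psd=mean_psd, n_frames=n_frames)
    band_powers(est, config.bands)
    return est


def _band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], band edges interpolated
    onto the grid so adjacent bands tile the axis without double counting."""
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, freqs, psd)
    return float(np.trapezoid(vals, grid))


def band_powers(
    est: SpectralEstimate, bands: dict[str, tuple[float, float]] | None = None
) -> SpectralEstimate:
    """Fill band powers, total power and SVB on a spectral estimate.

    SVB = LF/HF; when the HF power is exactly zero the ratio is undefined
    and reported as ``None`` (never infinity).
    """
    bands = bands or DEFAULT_BANDS
    bp = {
        name: _band_integral(est.freqs_hz, est.mean_psd, lo, hi)
        for name, (lo, hi) in bands.items()
    }
    est.band_power = bp
    est.total_power = float(sum(bp.values()))
    hf = bp.get("HF", 0.0)
    est.svb = None if hf == 0.0 else bp.get("LF", 0.0) / hf
    return est
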