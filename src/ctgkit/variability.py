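"""Fetal heart rate variability (FHRV) and the short-term variability index.

The FHRV signal is the FHR minus the floating line.  The short-term
variability (STV) index is the sample standard deviation

    STV = sqrt( 1/(n-1) * sum_i (F(i) - Fbar)^2 )

computed on 30-second segments of the FHRV signal (n = samples per segment,
Fbar = segment mean), and summarised as the mean over good-quality segments.
A segment is good when fewer than half of its samples are interpolated and
none belongs to a long-interpolation run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baseline import BaselineResult
from .errors import ContractError, InsufficientDataError
from .records import CTGRecord

#: STV below this is treated as clinical absence of variability
STV_ABSENT_THRESHOLD = 0.02


@dataclass(frozen=True)
class FHRVSignal:
    values_bpm: np.ndarray
    fs_hz: float
    window_s: float
    window_quality: np.ndarray  # one bool per complete window

    @property
    def n_windows(self) -> int:
        return self.window_quality.size


@dataclass(frozen=True)
class STVResult:
    stv_per_window: np.ndarray
    window_used: np.ndarray
    stv_mean: float
    n_windows_used: int

    @property
    def absent_variability(self) -> bool:
        return self.stv_mean < STV_ABSENT_THRESHOLD


def compute_fhrv(
    record: CTGRecord, baseline: BaselineResult, window_s: float = 30.0
) -> FHRVSignal:
    """Detrend the FHR by the floating line and grade 30-s windows.

    The trailing partial window is not graded (it is discarded by
    :func:`compute_stv` as well).
    """
    if baseline.floating_line_bpm.size != record.n_samples:
        raise ContractError("floating line length differs from record length")
    values = record.fhr_bpm - baseline.floating_line_bpm
    wlen = int(round(window_s * record.fs_hz))
    n_win = record.n_samples // wlen
    quality = np.ones(n_win, dtype=bool)
    for w in range(n_win):
        sl = slice(w * wlen, (w + 1) * wlen)
        if record.long_interp_mask[sl].any():
            quality[w] = False
        elif record.interpolated_mask[sl].mean() >= 0.5:
            quality[w] = False
    return FHRVSignal(
        values_bpm=values, fs_hz=record.fs_hz, window_s=window_s, window_quality=quality
    )


def compute_stv(fhrv: FHRVSignal, window_s: float | None = None) -> STVResult:
    """Windowed STV of the FHRV signal, averaged over good-quality windows.

    Windows tile the signal without overlap; the trailing partial window is
    discarded.  Raises :class:`InsufficientDataError` when no usable window
    exists.
    """
    window_s = fhrv.window_s if window_s is None else window_s
    wlen = int(round(window_s * fhrv.fs_hz))
    if wlen < 2:
        raise ContractError("window must contain at least 2 samples")
    n_win = fhrv.values_bpm.size // wlen
    if n_win == 0:
        raise InsufficientDataError("record shorter than one STV window")
    segs = fhrv.values_bpm[: n_win * wlen].reshape(n_win, wlen)
    stv = segs.std(axis=1, ddof=1)
    if window_s == fhrv.window_s and fhrv.window_quality.size == n_win:
        used = fhrv.window_quality.copy()
    else:  # caller re-tiled with a different window: no quality grading known
        used = np.ones(n_win, dtype=bool)
    if not used.any():
        raise InsufficientDataError("no good-quality STV window")
    return STVResult(
        stv_per_window=stv,
        window_used=used,
        stv_mean=float(stv[used].mean()),
        n_windows_used=int(used.sum()),
    )
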