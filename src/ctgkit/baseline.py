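"""Baseline / floating-line estimation and FHR event detection.

Two trend lines are computed from the interpolated FHR signal:

* the **baseline** — the slowly varying mean heart-rate level with
  accelerations and decelerations suppressed.  Implemented as an iterative
  trimmed running median: start from a plain 10-minute running median, then
  repeatedly recompute it after replacing samples further than 15 bpm from
  the current estimate by the estimate itself.  Transient excursions
  (events) are thereby excluded from the trend while sustained level shifts
  (tachycardia/bradycardia) are tracked.
* the **floating line** — a short (2-minute) running median that follows the
  signal *through* accelerations and decelerations; subtracting it yields
  the heart-rate variability signal.

Event detection follows the FIGO conventions: an acceleration is an
excursion of at least +15 bpm above baseline sustained for at least 15 s
(and shorter than 10 min, beyond which it counts as a baseline change);
a deceleration is at least −15 bpm for at least 15 s, *prolonged* when it
exceeds 3 min.  Events that overlap a long-interpolation segment are kept in
the output but flagged ``figo_valid=False`` so they do not enter counts.

Arrhythmia recognition runs on the baseline vector: tachycardia is a run of
baseline samples strictly above 160 bpm lasting at least 10 min (severe when
the run mean exceeds 180 bpm); bradycardia is a run strictly below 110 bpm
lasting more than 3 min.  Invalid source samples break a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, InsufficientDataError
from .records import CTGRecord, FHR_RANGE_BPM


@dataclass(frozen=True)
class BaselineConfig:
    trend_window_s: float = 600.0
    trim_bpm: float = 15.0
    n_iterations: int = 3
    floating_window_s: float = 120.0


@dataclass(frozen=True)
class BaselineResult:
    baseline_bpm: np.ndarray
    floating_line_bpm: np.ndarray


@dataclass(frozen=True)
class FigoThresholds:
    """Event and arrhythmia thresholds (all configurable)."""

    accel_delta_bpm: float = 15.0
    decel_delta_bpm: float = 15.0
    #: hysteresis: a run extends while the excursion stays within this many
    #: bpm below the threshold, so beat-to-beat noise does not fragment events
    hysteresis_bpm: float = 5.0
    min_event_s: float = 15.0
    max_accel_s: float = 600.0
    prolonged_decel_s: float = 180.0
    tachy_bpm: float = 160.0
    tachy_min_s: float = 600.0          # "at least 10 min" -> inclusive
    severe_tachy_bpm: float = 180.0
    brady_bpm: float = 110.0
    brady_min_s: float = 180.0          # "more than 3 min" -> exclusive


@dataclass
class Episode:
    """A detected interval event on the FHR trace.

    ``start_idx``/``end_idx`` delimit a half-open sample interval.
    ``peak_deviation_bpm`` is signed: the largest excursion from baseline for
    accelerations/decelerations, or from the normal-band edge (160/110 bpm)
    for arrhythmia episodes.
    """

    kind: str  # acceleration | deceleration | tachycardia | bradycardia
    start_idx: int
    end_idx: int
    duration_s: float
    peak_deviation_bpm: float
    figo_valid: bool = True
    overlaps_long_interpolation: bool = False
    prolonged: bool = False
    severe: bool = False


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    window = max(1, int(window))
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def estimate_baseline(
    record: CTGRecord, config: BaselineConfig | None = None
) -> BaselineResult:
    """Estimate the event-insensitive baseline and the floating line.

    Requires an interpolated record (no unusable samples) at least one trend
    window long.
    """
    config = config or BaselineConfig()
    if record.duration_s < config.trend_window_s:
        raise InsufficientDataError(
            f"record of {record.duration_s:.0f}s shorter than the "
            f"{config.trend_window_s:.0f}s trend window"
        )
    if not record.usable_mask.all():
        raise ContractError("baseline estimation requires an interpolated record")
    x = record.fhr_bpm
    w_trend = int(round(config.trend_window_s * record.fs_hz))
    baseline = _running_median(x, w_trend)
    for _ in range(config.n_iterations):
        trimmed = np.where(np.abs(x - baseline) <= config.trim_bpm, x, baseline)
        baseline = _running_median(trimmed, w_trend)
    lo, hi = FHR_RANGE_BPM
    baseline = np.clip(baseline, lo, hi)
    w_float = int(round(config.floating_window_s * record.fs_hz))
    floating = np.clip(_running_median(x, w_float), lo, hi)
    return BaselineResult(baseline_bpm=baseline, floating_line_bpm=floating)


def _mask_runs(mask: np.ndarray):
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask.size and mask[0]:
        starts = np.r_[0, starts]
    if mask.size and mask[-1]:
        stops = np.r_[stops, mask.size]
    return zip(starts.tolist(), stops.tolist())


def detect_accel_decel(
    record: CTGRecord,
    baseline: BaselineResult,
    figo: FigoThresholds | None = None,
) -> list[Episode]:
    """Detect accelerations and decelerations relative to the baseline.

    Every threshold-crossing excursion is returned; only those satisfying
    the FIGO duration rules *and* free of long-interpolation overlap carry
    ``figo_valid=True``.  Episodes of one kind never overlap and are sorted
    by start index.
    """
    figo = figo or FigoThresholds()
    if baseline.baseline_bpm.size != record.n_samples:
        raise ContractError("baseline length differs from record length")
    dev = record.fhr_bpm - baseline.baseline_bpm
    episodes: list[Episode] = []
    for kind, th in (
        ("acceleration", figo.accel_delta_bpm),
        ("deceleration", -figo.decel_delta_bpm),
    ):
        # Schmitt-trigger detection: the run is delimited at a relaxed level
        # (threshold minus hysteresis) but must reach the full threshold
        if kind == "acceleration":
            mask = dev >= th - figo.hysteresis_bpm
        else:
            mask = dev <= th + figo.hysteresis_bpm
        for start, stop in _mask_runs(mask):
            seg = dev[start:stop]
            peak = float(seg.max() if kind == "acceleration" else seg.min())
            if (kind == "acceleration" and peak < th) or (
                kind == "deceleration" and peak > th
            ):
                continue
            dur = (stop - start) / record.fs_hz
            long_ov = bool(record.long_interp_mask[start:stop].any())
            ok = dur >= figo.min_event_s and not long_ov
            if kind == "acceleration" and dur >= figo.max_accel_s:
                ok = False
            episodes.append(
                Episode(
                    kind=kind,
                    start_idx=int(start),
                    end_idx=int(stop),
                    duration_s=dur,
                    peak_deviation_bpm=peak,
                    figo_valid=ok,
                    overlaps_long_interpolation=long_ov,
                    prolonged=(kind == "deceleration" and dur > figo.prolonged_decel_s),
                )
            )
    episodes.sort(key=lambda e: (e.start_idx, e.kind))
    return episodes


def detect_arrhythmia(
    baseline: BaselineResult | np.ndarray,
    kind: str,
    fs_hz: float,
    valid_mask: np.ndarray | None = None,
    figo: FigoThresholds | None = None,
) -> list[Episode]:
    """Find tachycardia / bradycardia runs on the baseline vector.

    Tachycardia: maximal runs strictly above 160 bpm with duration >= 10 min,
    flagged severe when the run mean exceeds 180 bpm.  Bradycardia: maximal
    runs strictly below 110 bpm with duration > 3 min.  Samples marked
    invalid in ``valid_mask`` break a run ("excluding zeros").
    """
    figo = figo or FigoThresholds()
    b = baseline.baseline_bpm if isinstance(baseline, BaselineResult) else np.asarray(baseline, float)
    if b.size == 0:
        raise InsufficientDataError("empty baseline vector")
    if kind == "tachycardia":
        mask = b > figo.tachy_bpm
    elif kind == "bradycardia":
        mask = b < figo.brady_bpm
    else:
        raise ContractError(f"unknown arrhythmia kind {kind!r}")
    if valid_mask is not None:
        mask = mask & np.asarray(valid_mask, dtype=bool)

    episodes: list[Episode] = []
    for start, stop in _mask_runs(mask):
        dur = (stop - start) / fs_hz
        if kind == "tachycardia":
            if dur < figo.tachy_min_s:
                continue
            seg = b[start:stop]
            episodes.append(
                Episode(
                    kind=kind,
                    start_idx=int(start),
                    end_idx=int(stop),
                    duration_s=dur,
                    peak_deviation_bpm=float(seg.max() - figo.tachy_bpm),
                    severe=bool(seg.mean() > figo.severe_tachy_bpm),
                )
            )
        else:
            if not dur > figo.brady_min_s:
                continue
            seg = b[start:stop]
            episodes.append(
                Episode(
                    kind=kind,
                    start_idx=int(start),
                    end_idx=int(stop),
                    duration_s=dur,
                    peak_deviation_bpm=float(seg.min() - figo.brady_bpm),
                )
            )
    return episodes
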