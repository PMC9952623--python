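"""CTG record container, file I/O, quality screening and gap interpolation.

A cardiotocographic (CTG) record is an evenly sampled fetal heart rate (FHR)
trace in beats per minute, optionally paired with a uterine activity (UC)
channel, plus the per-record metadata (gestational week, singleton pregnancy,
antepartum recording) needed for eligibility screening.

Missing FHR samples are encoded with the conventional sentinel value 0 bpm in
files; in memory they are tracked with a per-sample ``valid_mask``.  A sample
is *invalid* if it is the sentinel, lies outside the physiological range
[50, 240] bpm, or is an isolated spike (it jumps more than 25 bpm away from
both of its neighbours).  Invalid runs are filled by linear interpolation;
runs longer than a configurable threshold (15 s by default) are additionally
flagged so that event detection can discard events supported only by
interpolated data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, ParseError

#: physiological FHR range in bpm; anything outside is treated as an artifact
FHR_RANGE_BPM = (50.0, 240.0)

#: sentinel value used for missing FHR samples in files
MISSING_SENTINEL = 0.0

#: maximum plausible sample-to-sample jump; larger isolated jumps are spikes
MAX_JUMP_BPM = 25.0


@dataclass
class CTGRecord:
    """An evenly sampled CTG recording.

    Attributes
    ----------
    record_id : str
        Identifier of the trace.
    fs_hz : float
        Sampling frequency in samples per second (0.25 s step -> 4 Hz).
    fhr_bpm : np.ndarray
        FHR samples in bpm.  Invalid samples keep their raw (sentinel or
        artifact) value until :func:`interpolate_gaps` fills them.
    uc : np.ndarray | None
        Uterine activity channel, arbitrary units; may be absent.
    valid_mask : np.ndarray
        True where the sample was actually measured and passed screening.
    interpolated_mask : np.ndarray
        True where the value was filled in by interpolation.
    long_interp_mask : np.ndarray
        True where the fill belongs to an interpolated run longer than the
        long-gap threshold; events overlapping such runs are not trusted.
    gestational_week : int
    singleton : bool
    antepartum : bool
    """

    record_id: str
    fs_hz: float
    fhr_bpm: np.ndarray
    uc: np.ndarray | None = None
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    interpolated_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    long_interp_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    gestational_week: int = 38
    singleton: bool = True
    antepartum: bool = True

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz must be positive")
        self.fhr_bpm = np.asarray(self.fhr_bpm, dtype=float)
        n = self.fhr_bpm.size
        if self.valid_mask is None:
            self.valid_mask = screen_samples(self.fhr_bpm)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.interpolated_mask is None:
            self.interpolated_mask = np.zeros(n, dtype=bool)
        else:
            self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
        if self.long_interp_mask is None:
            self.long_interp_mask = np.zeros(n, dtype=bool)
        else:
            self.long_interp_mask = np.asarray(self.long_interp_mask, dtype=bool)
        if self.uc is not None:
            self.uc = np.asarray(self.uc, dtype=float)
            if self.uc.size != n:
                raise ConfigurationError("uc length differs from fhr length")
        for m in (self.valid_mask, self.interpolated_mask, self.long_interp_mask):
            if m.size != n:
                raise ConfigurationError("mask length differs from fhr length")

    # -- derived quantities -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.fhr_bpm.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    @property
    def usable_mask(self) -> np.ndarray:
        """Samples carrying a value (measured or interpolated)."""
        return self.valid_mask | self.interpolated_mask

    def copy(self) -> "CTGRecord":
        return replace(
            self,
            fhr_bpm=self.fhr_bpm.copy(),
            uc=None if self.uc is None else self.uc.copy(),
            valid_mask=self.valid_mask.copy(),
            interpolated_mask=self.interpolated_mask.copy(),
            long_interp_mask=self.long_interp_mask.copy(),
        )


@dataclass(frozen=True)
class QualityCriteria:
    """Eligibility thresholds for antepartum CTG screening."""

    min_gestational_week: int = 36
    max_gestational_week: int = 40
    min_duration_min: float = 20.0
    max_signal_loss_pct: float = 30.0
    max_outlier_pct: float = 5.0
    require_singleton: bool = True
    require_antepartum: bool = True


@dataclass(frozen=True)
class QualityReport:
    duration_min: float
    signal_loss_pct: float
    outlier_pct: float
    eligible: bool
    reasons: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "duration_min": self.duration_min,
            "signal_loss_pct": self.signal_loss_pct,
            "outlier_pct": self.outlier_pct,
            "eligible": self.eligible,
            "reasons": list(self.reasons),
        }


def screen_samples(fhr_bpm: np.ndarray) -> np.ndarray:
    """Per-sample validity mask: sentinel, out-of-range and spike rejection."""
    x = np.asarray(fhr_bpm, dtype=float)
    lo, hi = FHR_RANGE_BPM
    valid = (x != MISSING_SENTINEL) & (x >= lo) & (x <= hi) & np.isfinite(x)
    # isolated spikes: > 25 bpm away from both neighbours
    if x.size >= 3:
        d_prev = np.abs(np.diff(x, prepend=x[0]))
        d_next = np.abs(np.diff(x, append=x[-1]))
        spike = (d_prev > MAX_JUMP_BPM) & (d_next > MAX_JUMP_BPM)
        valid &= ~spike
    return valid


def missing_mask(fhr_bpm: np.ndarray) -> np.ndarray:
    """True where the raw file value is the missing sentinel."""
    x = np.asarray(fhr_bpm, dtype=float)
    return (x == MISSING_SENTINEL) | ~np.isfinite(x)


def assess_quality(
    record: CTGRecord, criteria: QualityCriteria | None = None
) -> QualityReport:
    """Screen a record against the antepartum eligibility criteria.

    Signal loss counts sentinel/missing samples; the outlier percentage
    counts measured samples rejected by the physiological-range / spike
    screen.  Ineligibility is a report outcome, never an exception.
    """
    if record.n_samples == 0:
        raise InsufficientDataError("empty record")
    criteria = criteria or QualityCriteria()
    n = record.n_samples
    miss = missing_mask(record.fhr_bpm) & ~record.interpolated_mask
    outl = ~record.valid_mask & ~miss & ~record.interpolated_mask
    loss_pct = 100.0 * int(miss.sum()) / n
    outlier_pct = 100.0 * int(outl.sum()) / n

    reasons: list[str] = []
    wk = record.gestational_week
    if criteria.require_antepartum and not record.antepartum:
        reasons.append("not_antepartum")
    if not (criteria.min_gestational_week <= wk <= criteria.max_gestational_week):
        reasons.append("gestational_week_out_of_range")
    if not record.duration_min > criteria.min_duration_min:
        reasons.append("duration_too_short")
    if not loss_pct < criteria.max_signal_loss_pct:
        reasons.append("signal_loss_too_high")
    if not outlier_pct < criteria.max_outlier_pct:
        reasons.append("outliers_too_high")
    if criteria.require_singleton and not record.singleton:
        reasons.append("not_singleton")

    return QualityReport(
        duration_min=record.duration_min,
        signal_loss_pct=loss_pct,
        outlier_pct=outlier_pct,
        eligible=not reasons,
        reasons=tuple(reasons),
    )


def interpolate_gaps(record: CTGRecord, long_gap_s: float = 15.0) -> CTGRecord:
    """Fill invalid runs by linear interpolation between flanking valid samples.

    Leading/trailing invalid runs are filled by nearest-valid extension.
    Runs strictly longer than ``long_gap_s`` are flagged in
    ``long_interp_mask`` so downstream event detection can reject events that
    rest on interpolated data.  Idempotent: a record with no remaining
    invalid samples is returned unchanged (as a copy).
    """
    out = record.copy()
    todo = ~out.usable_mask
    if not todo.any():
        return out
    anchors = np.flatnonzero(~todo)
    if anchors.size < 2:
        raise InsufficientDataError("need at least two valid samples to interpolate")
    idx = np.arange(out.n_samples)
    # np.interp holds edge values constant outside the anchor range, which is
    # exactly the nearest-valid extension wanted for leading/trailing runs
    out.fhr_bpm[todo] = np.interp(idx[todo], anchors, out.fhr_bpm[anchors])
    out.interpolated_mask |= todo

    long_n = long_gap_s * out.fs_hz
    for start, stop in _runs(todo):
        if (stop - start) > long_n:
            out.long_interp_mask[start:stop] = True
    return out


def _runs(mask: np.ndarray):
    """Yield (start, stop) half-open index pairs of True runs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        stops = np.r_[stops, m.size]
    yield from zip(starts.tolist(), stops.tolist())


# ---------------------------------------------------------------------------
# file I/O
#
# CSV dialect: header ``time_s,fhr_bpm,uc`` (uc optional), one row per sample
# at a fixed step of 1/fs_hz seconds, missing FHR written as the sentinel 0.
# Metadata lives in a sidecar JSON named ``<stem>.json`` next to the CSV, or
# everything in one ``json-bundle`` file.
# ---------------------------------------------------------------------------

_META_FIELDS = ("record_id", "fs_hz", "gestational_week", "singleton", "antepartum")


def load_ctg_record(path: str | Path, format: str = "csv") -> CTGRecord:
    """Load a record from ``csv`` (+ sidecar JSON) or a ``json-bundle`` file."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    if format == "json-bundle":
        with open(path) as fh:
            bundle = json.load(fh)
        meta = {k: bundle[k] for k in _META_FIELDS if k in bundle}
        if "fs_hz" not in meta:
            raise ConfigurationError(f"{path}: missing fs_hz")
        fhr = np.asarray(bundle["fhr_bpm"], dtype=float)
        uc = np.asarray(bundle["uc"], dtype=float) if bundle.get("uc") is not None else None
        return CTGRecord(fhr_bpm=fhr, uc=uc, **meta)
    if format != "csv":
        raise ConfigurationError(f"unknown format {format!r}")

    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("time_s", "fhr_bpm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ConfigurationError(f"{sidecar}: sidecar metadata not found (fs_hz)")
    with open(sidecar) as fh:
        meta = json.load(fh)
    if "fs_hz" not in meta:
        raise ConfigurationError(f"{sidecar}: missing fs_hz")
    meta = {k: meta[k] for k in _META_FIELDS if k in meta}
    uc = df["uc"].to_numpy(float) if "uc" in df.columns else None
    return CTGRecord(fhr_bpm=df["fhr_bpm"].to_numpy(float), uc=uc, **meta)


def save_ctg_record(record: CTGRecord, path: str | Path, format: str = "csv") -> None:
    """Write a record in the CSV (+ sidecar JSON) or json-bundle dialect.

    Interpolated samples are written back as the missing sentinel so a save →
    load round trip reproduces the original measured data and masks; raw
    artifact values are preserved verbatim (the load-time screen rejects them
    again identically).
    """
    path = Path(path)
    fhr = record.fhr_bpm.copy()
    fhr[record.interpolated_mask] = MISSING_SENTINEL
    meta = {
        "record_id": record.record_id,
        "fs_hz": record.fs_hz,
        "gestational_week": record.gestational_week,
        "singleton": record.singleton,
        "antepartum": record.antepartum,
    }
    if format == "json-bundle":
        bundle = dict(meta)
        bundle["fhr_bpm"] = fhr.tolist()
        bundle["uc"] = None if record.uc is None else record.uc.tolist()
        with open(path, "w") as fh:
            json.dump(bundle, fh)
        return
    if format != "csv":
        raise ConfigurationError(f"unknown format {format!r}")
    t = np.arange(record.n_samples) / record.fs_hz
    cols = {"time_s": t, "fhr_bpm": fhr}
    if record.uc is not None:
        cols["uc"] = record.uc
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
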