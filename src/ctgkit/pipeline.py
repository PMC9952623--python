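"""End-to-end feature extraction: record -> feature row.

Chains gap interpolation, baseline/floating-line estimation, event and
arrhythmia detection, STV and spectral analysis, and uterine-contraction
counting into a single :class:`CTGFeatures` row ready for annotation and
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .annotation import CTGFeatures
from .baseline import (
    BaselineConfig,
    BaselineResult,
    Episode,
    FigoThresholds,
    detect_accel_decel,
    detect_arrhythmia,
    estimate_baseline,
)
from .records import CTGRecord, interpolate_gaps
from .spectral import SpectralConfig, SpectralEstimate, compute_mean_psd
from .variability import STV_ABSENT_THRESHOLD, FHRVSignal, STVResult, compute_fhrv, compute_stv


@dataclass
class AnalysisResult:
    """Feature row plus every intermediate artifact, for inspection/plotting."""

    record: CTGRecord
    baseline: BaselineResult
    episodes: list[Episode]
    arrhythmias: list[Episode]
    fhrv: FHRVSignal
    stv: STVResult
    spectrum: SpectralEstimate
    features: CTGFeatures


def count_contractions(uc: np.ndarray | None, fs_hz: float) -> int:
    """Count uterine contractions as prominent, sustained peaks of the UC
    channel (prominence >= 15 units, width >= 30 s)."""
    if uc is None or uc.size == 0:
        return 0
    peaks, _ = find_peaks(uc, prominence=15.0, width=30.0 * fs_hz)
    return int(peaks.size)


def analyze_record(
    record: CTGRecord,
    baseline_config: BaselineConfig | None = None,
    figo: FigoThresholds | None = None,
    spectral_config: SpectralConfig | None = None,
    long_gap_s: float = 15.0,
) -> AnalysisResult:
    """Run the full analysis chain on one record."""
    figo = figo or FigoThresholds()
    rec = interpolate_gaps(record, long_gap_s=long_gap_s)
    base = estimate_baseline(rec, baseline_config)
    episodes = detect_accel_decel(rec, base, figo)
    # arrhythmia runs on the baseline vector; originally-missing long-
    # interpolation stretches break the runs ("excluding zeros")
    run_valid = ~rec.long_interp_mask
    arr = detect_arrhythmia(base, "tachycardia", rec.fs_hz, run_valid, figo)
    arr += detect_arrhythmia(base, "bradycardia", rec.fs_hz, run_valid, figo)

    fhrv = compute_fhrv(rec, base)
    stv = compute_stv(fhrv)
    spectrum = compute_mean_psd(fhrv, spectral_config)

    acc = [e for e in episodes if e.kind == "acceleration" and e.figo_valid]
    dec = [e for e in episodes if e.kind == "deceleration" and e.figo_valid]
    tach = [e for e in arr if e.kind == "tachycardia"]
    brad = [e for e in arr if e.kind == "bradycardia"]
    features = CTGFeatures(
        bl_bpm=float(base.baseline_bpm.mean()),
        brad=len(brad),
        tach=len(tach),
        acc=len(acc),
        dec=len(dec),
        uc_count=count_contractions(rec.uc, rec.fs_hz),
        stv=stv.stv_mean,
        vlf=spectrum.band_power["VLF"],
        lf=spectrum.band_power["LF"],
        hf=spectrum.band_power["HF"],
        svb=spectrum.svb,
        severe_tach=any(e.severe for e in tach),
        prolonged_dec=any(e.prolonged for e in dec),
        total_power=spectrum.total_power,
        stv_absent=stv.stv_mean < STV_ABSENT_THRESHOLD,
    )
    return AnalysisResult(
        record=rec,
        baseline=base,
        episodes=episodes,
        arrhythmias=arr,
        fhrv=fhrv,
        stv=stv,
        spectrum=spectrum,
        features=features,
    )


def extract_features(record: CTGRecord, **kwargs) -> CTGFeatures:
    """Convenience wrapper returning only the feature row."""
    return analyze_record(record, **kwargs).features


#: feature-table columns fed to the SVM classifier
CLASSIFIER_COLUMNS = ("BRAD", "TACH", "ACC", "DEC", "STV", "SVB")


def feature_matrix(rows: list[CTGFeatures]) -> np.ndarray:
    """Stack feature rows into the (n, 6) classifier input matrix."""
    out = np.empty((len(rows), len(CLASSIFIER_COLUMNS)))
    for i, f in enumerate(rows):
        svb = np.nan if f.svb is None else f.svb
        out[i] = (f.brad, f.tach, f.acc, f.dec, f.stv, svb)
    # an undefined SVB (zero HF power) is maximally non-reactive: impute 0
    out[np.isnan(out)] = 0.0
    return out
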