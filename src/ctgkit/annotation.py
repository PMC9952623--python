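"""Machine-based CTG annotation: feature mask and suspicion criteria.

Each analysed trace is summarised in a feature row (baseline level, episode
counts, STV, band powers, SVB).  Six alarm bits are derived from it, in the
fixed order (BRAD, TACH, ACC, DEC, STV, SVB):

* BRAD — at least one bradycardia episode,
* TACH — at least one tachycardia episode,
* ACC  — *absence* of FIGO-valid accelerations,
* DEC  — presence of prolonged decelerations,
* STV  — STV below the 1.70 bpm cut-off,
* SVB  — sympatho-vagal balance below the 8.20 cut-off.

The STV/SVB cut-offs are the minima these indices assume over gestational
weeks 24–42 in a reference population; both are configurable.  A trace is
labelled *suspicious* when any of four criteria fires:

1. no accelerations and at least one further alarm bit set;
2. accelerations present and at least two alarm bits set;
3. severe tachycardia (baseline run mean above 180 bpm);
4. any bradycardia episode (below 110 bpm for more than 3 min).

The labelling pass is pure and deterministic; it is executed twice and the
two passes are asserted identical (a disagreement would be a software
invariant violation, not a data property).
"""

from __future__ import annotations

from dataclasses import dataclass

from .variability import STV_ABSENT_THRESHOLD

MASK_ORDER = ("BRAD", "TACH", "ACC", "DEC", "STV", "SVB")


@dataclass(frozen=True)
class CTGFeatures:
    """One analysed trace, matching the feature-table row layout
    (BL BRAD TACH ACC DEC UC STV VLF LF HF SVB)."""

    bl_bpm: float
    brad: int
    tach: int
    acc: int
    dec: int
    uc_count: int
    stv: float
    vlf: float
    lf: float
    hf: float
    svb: float | None
    severe_tach: bool = False
    prolonged_dec: bool = False
    total_power: float | None = None
    stv_absent: bool = False

    def __post_init__(self) -> None:
        if self.severe_tach and self.tach < 1:
            raise ValueError("severe_tach implies at least one tachycardia episode")

    def to_dict(self) -> dict:
        return {
            "BL": self.bl_bpm,
            "BRAD": self.brad,
            "TACH": self.tach,
            "ACC": self.acc,
            "DEC": self.dec,
            "UC": self.uc_count,
            "STV": self.stv,
            "VLF": self.vlf,
            "LF": self.lf,
            "HF": self.hf,
            "SVB": self.svb,
            "severe_tach": self.severe_tach,
            "prolonged_dec": self.prolonged_dec,
            "stv_absent": self.stv_absent,
        }


@dataclass(frozen=True)
class MaskThresholds:
    stv_th: float = 1.70
    svb_th: float = 8.20
    dec_bit_uses_prolonged: bool = True


@dataclass(frozen=True)
class FeatureMask:
    """Ordered six-bit alarm vector (BRAD, TACH, ACC, DEC, STV, SVB)."""

    brad: bool
    tach: bool
    acc: bool
    dec: bool
    stv: bool
    svb: bool

    @property
    def bits(self) -> tuple[int, ...]:
        return tuple(
            int(v) for v in (self.brad, self.tach, self.acc, self.dec, self.stv, self.svb)
        )

    @classmethod
    def from_bits(cls, bits) -> "FeatureMask":
        if len(bits) != 6:
            raise ValueError("a feature mask has exactly six bits")
        return cls(*(bool(b) for b in bits))

    def n_set(self) -> int:
        return sum(self.bits)


@dataclass(frozen=True)
class AnnotationResult:
    label: str  # "normal" | "suspicious"
    mask: FeatureMask
    triggered_criteria: tuple[int, ...]


def build_feature_mask(
    f: CTGFeatures, thresholds: MaskThresholds | None = None
) -> FeatureMask:
    """Derive the six alarm bits from a feature row.

    An undefined SVB (no HF power) is treated as non-reactive and sets the
    SVB bit.  An STV below the absence-of-variability level (0.02 bpm)
    necessarily also falls below the 1.70 cut-off, so the alarm path is
    shared.
    """
    th = thresholds or MaskThresholds()
    svb_bit = True if f.svb is None else f.svb < th.svb_th
    dec_bit = f.prolonged_dec if th.dec_bit_uses_prolonged else f.dec >= 1
    return FeatureMask(
        brad=f.brad >= 1,
        tach=f.tach >= 1,
        acc=f.acc == 0,
        dec=bool(dec_bit),
        stv=f.stv < th.stv_th,
        svb=bool(svb_bit),
    )


def _label_once(
    f: CTGFeatures, mask: FeatureMask, criterion1_excludes_acc_bit: bool
) -> AnnotationResult:
    non_acc_bits = mask.n_set() - int(mask.acc)
    c1_bits = non_acc_bits if criterion1_excludes_acc_bit else mask.n_set()
    triggered = []
    if f.acc == 0 and c1_bits >= 1:
        triggered.append(1)
    if f.acc >= 1 and mask.n_set() >= 2:
        triggered.append(2)
    if f.severe_tach:
        triggered.append(3)
    if f.brad >= 1:
        triggered.append(4)
    label = "suspicious" if triggered else "normal"
    return AnnotationResult(label=label, mask=mask, triggered_criteria=tuple(triggered))


def annotate(
    f: CTGFeatures,
    mask: FeatureMask | None = None,
    thresholds: MaskThresholds | None = None,
    criterion1_excludes_acc_bit: bool = True,
) -> AnnotationResult:
    """Label a trace normal/suspicious from its feature mask.

    With accelerations absent the ACC bit is itself set, so criterion 1
    requires (by default) at least one *other* alarm bit; the flag restores
    the literal reading in which the ACC bit alone suffices.
    """
    if mask is None:
        mask = build_feature_mask(f, thresholds)
    result = _label_once(f, mask, criterion1_excludes_acc_bit)
    verification = _label_once(f, mask, criterion1_excludes_acc_bit)
    assert verification == result, "annotation verification pass disagreed"
    return result
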