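"""Synthetic CTG generator with known ground truth.

Records are built additively from interpretable components:

* a baseline level, optionally shifted by trapezoidal tachycardia /
  bradycardia episodes (30 s ramps, slow enough for the baseline estimator
  to follow, fast enough for sharp ground truth);
* trapezoidal accelerations / decelerations (5 s ramps);
* beat-to-beat variability: white Gaussian noise low-pass filtered inside
  the physiological FHRV band and rescaled to an exact target standard
  deviation;
* two sinusoids of configurable amplitude at a low-frequency (0.1 Hz) and a
  high-frequency (0.4 Hz) carrier, giving direct control over the LF/HF
  spectral balance (power ratio ~ lf_amp^2 / hf_amp^2);
* uterine activity as a sum of bell-shaped contraction pulses;
* signal loss as short masked gaps and isolated out-of-range outliers.

Every record is reproducible from its seed; cohorts draw one child seed per
record from a single root generator so members are independently
reproducible.  :func:`generate_cohort` emulates an antepartum screening
population: normal traces carry accelerations, adequate variability and a
reactive (high) sympatho-vagal balance, while suspicious traces are drawn
from the four suspicion mechanisms (non-reactive with no accelerations,
globally reduced variability, severe tachycardia, bradycardia).  Parameter
ranges deliberately include borderline draws near the STV/SVB cut-offs so
the two classes overlap the way screening data do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError
from .records import CTGRecord

LF_CARRIER_HZ = 0.1
HF_CARRIER_HZ = 0.4


@dataclass(frozen=True)
class EventSpec:
    kind: str  # acceleration | deceleration | tachycardia | bradycardia
    start_s: float
    duration_s: float
    amplitude_bpm: float  # signed: accelerations/tachycardia +, others -

    def __post_init__(self) -> None:
        sign = 1.0 if self.kind in ("acceleration", "tachycardia") else -1.0
        if self.amplitude_bpm * sign <= 0:
            raise ConfigurationError(
                f"{self.kind} amplitude must be {'positive' if sign > 0 else 'negative'}"
            )


@dataclass(frozen=True)
class SyntheticConfig:
    duration_min: float = 30.0
    fs_hz: float = 4.0
    baseline_bpm: float = 140.0
    variability_sd_bpm: float = 2.5
    lf_amp_bpm: float = 2.5
    hf_amp_bpm: float = 0.3
    lf_freq_hz: float = LF_CARRIER_HZ
    hf_freq_hz: float = HF_CARRIER_HZ
    noise_cutoff_hz: float = 0.08
    events: tuple[EventSpec, ...] = ()
    n_contractions: int = 3
    signal_loss_fraction: float = 0.02
    outlier_fraction: float = 0.002
    event_ramp_s: float = 5.0
    shift_ramp_s: float = 30.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_min * 60.0 * self.fs_hz))


@dataclass(frozen=True)
class TrueEvent:
    kind: str
    start_s: float
    end_s: float
    amplitude_bpm: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class GroundTruth:
    true_events: tuple[TrueEvent, ...]
    true_stv: float
    true_svb_proxy: float
    intended_label: str
    config: SyntheticConfig


def _trapezoid(t: np.ndarray, start: float, dur: float, amp: float, ramp: float) -> np.ndarray:
    """Trapezoidal pulse: linear ramps of length ``ramp`` inside [start, start+dur]."""
    ramp = min(ramp, dur / 2.0)
    up = np.clip((t - start) / max(ramp, 1e-9), 0.0, 1.0)
    down = np.clip((start + dur - t) / max(ramp, 1e-9), 0.0, 1.0)
    return amp * np.minimum(up, down)


def _shaped_noise(n: int, fs: float, cutoff_hz: float, sd: float, rng) -> np.ndarray:
    if sd <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    b, a = butter(4, cutoff_hz / (fs / 2.0), btype="low")
    x = filtfilt(b, a, white)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def generate_record(config: SyntheticConfig) -> tuple[CTGRecord, GroundTruth]:
    """Synthesize one CTG record plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    fs = config.fs_hz
    t = np.arange(n) / fs
    dur_s = n / fs

    level = np.full(n, config.baseline_bpm)  # true baseline track
    excursions = np.zeros(n)  # accel/decel track
    true_events: list[TrueEvent] = []
    for ev in config.events:
        if ev.start_s < 0 or ev.start_s + ev.duration_s > dur_s:
            raise ConfigurationError(f"event does not fit inside the record: {ev}")
        if ev.kind in ("tachycardia", "bradycardia"):
            pulse = _trapezoid(t, ev.start_s, ev.duration_s, ev.amplitude_bpm, config.shift_ramp_s)
            level = level + pulse
            # ground-truth interval: where the shifted level crosses the
            # clinical threshold (160 / 110 bpm)
            th = 160.0 if ev.kind == "tachycardia" else 110.0
            beyond = (level > th) if ev.kind == "tachycardia" else (level < th)
            idx = np.flatnonzero(beyond)
            if idx.size:
                true_events.append(
                    TrueEvent(ev.kind, idx[0] / fs, (idx[-1] + 1) / fs, ev.amplitude_bpm)
                )
        else:
            excursions += _trapezoid(t, ev.start_s, ev.duration_s, ev.amplitude_bpm, config.event_ramp_s)
            true_events.append(
                TrueEvent(ev.kind, ev.start_s, ev.start_s + ev.duration_s, ev.amplitude_bpm)
            )

    noise = _shaped_noise(n, fs, config.noise_cutoff_hz, config.variability_sd_bpm, rng)
    lf = config.lf_amp_bpm * np.sin(2 * np.pi * config.lf_freq_hz * t + rng.uniform(0, 2 * np.pi))
    hf = config.hf_amp_bpm * np.sin(2 * np.pi * config.hf_freq_hz * t + rng.uniform(0, 2 * np.pi))
    fhr = level + excursions + noise + lf + hf

    # signal loss: gaps with exponential lengths (mean 4 s, capped at 12 s)
    if config.signal_loss_fraction > 0:
        target = int(round(config.signal_loss_fraction * n))
        lost = 0
        guard = 0
        gap_mask = np.zeros(n, dtype=bool)
        while lost < target and guard < 10_000:
            guard += 1
            glen = int(np.clip(rng.exponential(4.0) * fs, 2, 12 * fs))
            gstart = int(rng.integers(0, max(1, n - glen)))
            new = ~gap_mask[gstart : gstart + glen]
            gap_mask[gstart : gstart + glen] = True
            lost += int(new.sum())
        fhr[gap_mask] = 0.0

    if config.outlier_fraction > 0:
        k = int(round(config.outlier_fraction * n))
        if k:
            pos = rng.choice(n, size=k, replace=False)
            fhr[pos] = rng.choice([30.0, 250.0], size=k)

    uc = _uterine_activity(t, config.n_contractions, rng)

    record = CTGRecord(
        record_id=f"synthetic-{config.seed}",
        fs_hz=fs,
        fhr_bpm=fhr,
        uc=uc,
        gestational_week=int(rng.integers(36, 41)),
        singleton=True,
        antepartum=True,
    )
    truth = GroundTruth(
        true_events=tuple(true_events),
        true_stv=float(
            np.sqrt(
                config.variability_sd_bpm**2
                + config.lf_amp_bpm**2 / 2
                + config.hf_amp_bpm**2 / 2
            )
        ),
        true_svb_proxy=(
            float("inf")
            if config.hf_amp_bpm == 0
            else (config.lf_amp_bpm / config.hf_amp_bpm) ** 2
        ),
        intended_label=_intended_label(config),
        config=config,
    )
    return record, truth


def _uterine_activity(t: np.ndarray, n_contractions: int, rng) -> np.ndarray:
    uc = np.full(t.size, 10.0)  # basal tone
    dur = t[-1] if t.size else 0.0
    for _ in range(n_contractions):
        center = rng.uniform(0.05, 0.95) * dur
        width = rng.uniform(35.0, 60.0)
        amp = rng.uniform(25.0, 45.0)
        uc += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return uc


def _intended_label(config: SyntheticConfig) -> str:
    """Annotation rules applied to the *generating* parameters."""
    has_acc = any(e.kind == "acceleration" for e in config.events)
    severe_tach = any(
        e.kind == "tachycardia" and config.baseline_bpm + e.amplitude_bpm > 180
        for e in config.events
    )
    brady = any(e.kind == "bradycardia" for e in config.events)
    tach = any(e.kind == "tachycardia" for e in config.events)
    prolonged_dec = any(
        e.kind == "deceleration" and e.duration_s > 180 for e in config.events
    )
    stv_proxy = np.sqrt(
        (0.75 * config.variability_sd_bpm) ** 2
        + config.lf_amp_bpm**2 / 2
        + config.hf_amp_bpm**2 / 2
    )
    lf_p = config.variability_sd_bpm**2 * 0.45 + config.lf_amp_bpm**2 / 2
    hf_p = config.variability_sd_bpm**2 * 0.02 + config.hf_amp_bpm**2 / 2
    svb_proxy = float("inf") if hf_p == 0 else lf_p / hf_p
    bits = [
        brady,
        tach,
        not has_acc,
        prolonged_dec,
        stv_proxy < 1.70,
        svb_proxy < 8.20,
    ]
    non_acc = sum(bits) - int(not has_acc)
    if (not has_acc and non_acc >= 1) or (has_acc and sum(bits) >= 2):
        return "suspicious"
    if severe_tach or brady:
        return "suspicious"
    return "normal"


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cohort:
    records: list[CTGRecord]
    labels: list[str]
    ground_truths: list[GroundTruth]

    @property
    def n(self) -> int:
        return len(self.records)


def _place_events(rng, n_events: int, dur_s: float, kind: str, amp_range, len_range):
    """Non-overlapping event placement with 30 s margins."""
    events: list[EventSpec] = []
    taken: list[tuple[float, float]] = []
    attempts = 0
    while len(events) < n_events and attempts < 200:
        attempts += 1
        length = rng.uniform(*len_range)
        start = rng.uniform(30.0, dur_s - 30.0 - length)
        if any(start < e + 20.0 and s < start + length + 20.0 for s, e in taken):
            continue
        amp = rng.uniform(*amp_range)
        if kind in ("deceleration", "bradycardia"):
            amp = -amp
        events.append(EventSpec(kind, start, length, amp))
        taken.append((start, start + length))
    return events


def _normal_config(rng, seed: int, duration_min: float) -> SyntheticConfig:
    """Draw one normal record.

    Four sub-families keep the class realistic rather than cleanly
    separable: classic reactive traces, traces borderline in STV only,
    traces borderline in SVB only (a single alarm bit cannot make a trace
    with accelerations suspicious), and rest-state traces without
    accelerations but with fully reassuring variability and reactivity.
    """
    dur_s = duration_min * 60.0
    u = rng.random()
    n_acc = int(rng.integers(2, 9))
    if u < 0.15:  # borderline STV, comfortably reactive spectrum
        sd = rng.uniform(1.3, 1.8)
        lf = rng.uniform(1.3, 1.8)
        hf = rng.uniform(0.25, 0.4)
    elif u < 0.30:  # borderline SVB, comfortable STV
        sd = rng.uniform(2.0, 2.8)
        lf = rng.uniform(1.2, 1.8)
        hf = rng.uniform(0.6, 0.9)
    elif u < 0.45:  # fetal rest state: no accelerations, no alarms
        n_acc = 0
        sd = rng.uniform(2.2, 3.2)
        lf = rng.uniform(2.2, 3.2)
        hf = rng.uniform(0.2, 0.4)
    else:  # classic reactive trace
        sd = rng.uniform(2.0, 3.4)
        lf = rng.uniform(2.0, 3.2)
        hf = rng.uniform(0.2, 0.45)
    events = _place_events(
        rng, n_acc, dur_s, "acceleration", (17.0, 26.0), (20.0, 60.0)
    )
    if rng.random() < 0.3:  # occasional brief, non-prolonged deceleration
        events += _place_events(rng, 1, dur_s, "deceleration", (16.0, 20.0), (18.0, 45.0))
    return SyntheticConfig(
        duration_min=duration_min,
        baseline_bpm=float(rng.uniform(125.0, 152.0)),
        variability_sd_bpm=sd,
        lf_amp_bpm=lf,
        hf_amp_bpm=hf,
        events=tuple(events),
        n_contractions=int(rng.integers(1, 5)),
        seed=seed,
    )


def _suspicious_config(rng, seed: int, duration_min: float, mechanism: int) -> SyntheticConfig:
    dur_s = duration_min * 60.0
    baseline = float(rng.uniform(125.0, 152.0))
    events: list[EventSpec] = []
    if mechanism == 0:  # criterion 1: no accelerations, non-reactive (low SVB)
        sd, lf, hf = rng.uniform(1.8, 2.6), rng.uniform(0.2, 0.6), rng.uniform(1.2, 2.0)
    elif mechanism == 1:  # criterion 1: no accelerations, reduced variability
        sd, lf, hf = rng.uniform(0.25, 0.7), rng.uniform(0.2, 0.45), rng.uniform(0.05, 0.2)
    elif mechanism == 2:  # criterion 2: accelerations but low STV *and* low SVB
        sd, lf, hf = rng.uniform(0.7, 1.2), rng.uniform(0.5, 0.9), rng.uniform(0.7, 1.4)
        events += _place_events(
            rng, int(rng.integers(1, 4)), dur_s, "acceleration", (17.0, 24.0), (20.0, 50.0)
        )
    elif mechanism == 3:  # criterion 3: severe tachycardia
        sd, lf, hf = rng.uniform(2.0, 3.0), rng.uniform(2.0, 3.0), rng.uniform(0.2, 0.4)
        shift = rng.uniform(183.0, 192.0) - baseline
        length = rng.uniform(12.0, 15.0) * 60.0
        start = rng.uniform(60.0, dur_s - length - 60.0)
        events.append(EventSpec("tachycardia", start, length, shift))
        events += _place_events(
            rng, int(rng.integers(0, 3)), dur_s, "acceleration", (17.0, 24.0), (20.0, 40.0)
        )
    else:  # criterion 4: bradycardia
        sd, lf, hf = rng.uniform(2.0, 3.0), rng.uniform(2.0, 3.0), rng.uniform(0.2, 0.4)
        shift = baseline - rng.uniform(95.0, 105.0)
        length = rng.uniform(8.0, 12.0) * 60.0
        start = rng.uniform(60.0, dur_s - length - 60.0)
        events.append(EventSpec("bradycardia", start, length, -shift))
    return SyntheticConfig(
        duration_min=duration_min,
        baseline_bpm=baseline,
        variability_sd_bpm=sd,
        lf_amp_bpm=lf,
        hf_amp_bpm=hf,
        events=tuple(events),
        n_contractions=int(rng.integers(1, 5)),
        seed=seed,
    )


def generate_cohort(
    n_normal: int,
    n_suspicious: int,
    seed: int,
    duration_min: float = 30.0,
    mechanism_weights: tuple[float, float, float, float, float] | None = None,
) -> Cohort:
    """Generate a labeled cohort of synthetic CTG records.

    ``mechanism_weights`` controls the mixture of the suspicious archetypes
    (criterion 1 non-reactive, criterion 1 low-variability, criterion 2,
    criterion 3 severe tachycardia, criterion 4 bradycardia); uniform by
    default.
    """
    if n_normal < 1 or n_suspicious < 1:
        raise ConfigurationError("both classes need at least one record")
    root = np.random.default_rng(seed)
    w = np.asarray(mechanism_weights if mechanism_weights else [1.0] * 5, float)
    w = w / w.sum()
    records, labels, truths = [], [], []
    for i in range(n_normal + n_suspicious):
        child_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(child_seed)
        if i < n_normal:
            cfg = _normal_config(rng, child_seed, duration_min)
        else:
            mech = int(rng.choice(5, p=w))
            cfg = _suspicious_config(rng, child_seed, duration_min, mech)
        rec, truth = generate_record(cfg)
        records.append(rec)
        labels.append(truth.intended_label)
        truths.append(truth)
    return Cohort(records=records, labels=labels, ground_truths=truths)
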