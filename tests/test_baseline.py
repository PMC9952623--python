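"""Baseline estimation, FIGO event detection and arrhythmia recognition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctgkit import (
    BaselineResult,
    FigoThresholds,
    InsufficientDataError,
    detect_accel_decel,
    detect_arrhythmia,
    estimate_baseline,
    interpolate_gaps,
)

from conftest import make_record

FS = 4.0


def _trapezoid(n, start_s, dur_s, amp, ramp_s=5.0, fs=FS):
    t = np.arange(n) / fs
    up = np.clip((t - start_s) / ramp_s, 0, 1)
    down = np.clip((start_s + dur_s - t) / ramp_s, 0, 1)
    return amp * np.minimum(up, down)


class TestEstimateBaseline:
    def test_constant_signal(self, constant_record):
        res = estimate_baseline(constant_record)
        np.testing.assert_allclose(res.baseline_bpm, 140.0)
        np.testing.assert_allclose(res.floating_line_bpm, 140.0)

    def test_acceleration_does_not_lift_baseline(self):
        n = int(30 * 60 * FS)
        fhr = 140.0 + _trapezoid(n, 900, 30, 20.0)
        res = estimate_baseline(make_record(fhr))
        assert np.abs(res.baseline_bpm - 140.0).max() <= 2.0
        # oracle: median over samples outside the event
        mask = _trapezoid(n, 900, 30, 20.0) == 0
        assert res.baseline_bpm.mean() == pytest.approx(
            np.median(fhr[mask]), abs=0.5
        )

    def test_tracks_slow_drift(self):
        n = int(30 * 60 * FS)
        ramp = np.linspace(130.0, 150.0, n)
        res = estimate_baseline(make_record(ramp))
        # edges are held by the centred window; check the interior
        sl = slice(n // 6, -n // 6)
        assert np.abs(res.baseline_bpm[sl] - ramp[sl]).max() <= 2.0

    def test_baseline_slowly_varying(self):
        rng = np.random.default_rng(3)
        n = int(30 * 60 * FS)
        fhr = 140 + rng.normal(0, 4, n) + _trapezoid(n, 600, 40, 22.0)
        res = estimate_baseline(make_record(fhr))
        win = int(60 * FS)
        b = res.baseline_bpm
        span = [b[i : i + win].max() - b[i : i + win].min() for i in range(0, n - win, win)]
        assert max(span) <= 10.0

    def test_short_record_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_baseline(make_record(np.full(int(5 * 60 * FS), 140.0)))


class TestAccelDecel:
    def _run(self, fhr, **kw):
        rec = interpolate_gaps(make_record(fhr))
        base = BaselineResult(
            baseline_bpm=np.full(rec.n_samples, 140.0),
            floating_line_bpm=np.full(rec.n_samples, 140.0),
        )
        return rec, detect_accel_decel(rec, base, **kw)

    def test_valid_acceleration(self):
        n = int(20 * 60 * FS)
        _, eps = self._run(140.0 + _trapezoid(n, 300, 30, 20.0))
        acc = [e for e in eps if e.kind == "acceleration" and e.figo_valid]
        assert len(acc) == 1
        assert acc[0].peak_deviation_bpm == pytest.approx(20.0)

    def test_too_short_acceleration_not_figo(self):
        n = int(20 * 60 * FS)
        _, eps = self._run(140.0 + _trapezoid(n, 300, 10, 20.0, ramp_s=2.0))
        assert not any(e.kind == "acceleration" and e.figo_valid for e in eps)

    def test_prolonged_deceleration(self):
        n = int(20 * 60 * FS)
        _, eps = self._run(140.0 + _trapezoid(n, 300, 240, -20.0))
        dec = [e for e in eps if e.kind == "deceleration" and e.figo_valid]
        assert len(dec) == 1 and dec[0].prolonged

    def test_event_inside_long_interpolation_excluded(self):
        n = int(20 * 60 * FS)
        fhr = 140.0 + _trapezoid(n, 300, 30, 20.0)
        # knock out 20 s covering the event -> interpolation bridges it flat,
        # and anything detected there must be figo-invalid
        i0, i1 = int(295 * FS), int(335 * FS)
        fhr[i0:i1] = 0.0
        rec = interpolate_gaps(make_record(fhr))
        assert rec.long_interp_mask[i0:i1].all()
        base = BaselineResult(
            baseline_bpm=np.full(n, 140.0), floating_line_bpm=np.full(n, 140.0)
        )
        eps = detect_accel_decel(rec, base)
        assert not any(e.kind == "acceleration" and e.figo_valid for e in eps)

    def test_same_kind_episodes_disjoint_and_sorted(self):
        n = int(20 * 60 * FS)
        fhr = (
            140.0
            + _trapezoid(n, 200, 30, 20.0)
            + _trapezoid(n, 400, 40, 25.0)
            + _trapezoid(n, 700, 30, -20.0)
        )
        _, eps = self._run(fhr)
        for kind in ("acceleration", "deceleration"):
            ep = [e for e in eps if e.kind == kind]
            assert all(a.end_idx <= b.start_idx for a, b in zip(ep, ep[1:]))


def brute_force_arrhythmia(baseline, kind, fs, valid=None):
    """Independent run-scan oracle: walk the vector sample by sample."""
    th, cmp_ = (160.0, lambda v: v > 160.0) if kind == "tachycardia" else (
        110.0,
        lambda v: v < 110.0,
    )
    min_s, inclusive = (600.0, True) if kind == "tachycardia" else (180.0, False)
    runs = []
    start = None
    for i, v in enumerate(baseline):
        ok = cmp_(v) and (valid is None or valid[i])
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(baseline)))
    out = []
    for s, e in runs:
        dur = (e - s) / fs
        if (dur >= min_s) if inclusive else (dur > min_s):
            out.append((s, e))
    return out


class TestArrhythmia:
    def test_normal_band_no_episodes(self):
        b = np.full(int(30 * 60 * FS), 150.0)
        assert detect_arrhythmia(b, "tachycardia", FS) == []
        assert detect_arrhythmia(b, "bradycardia", FS) == []

    def test_tachycardia_run(self):
        b = np.full(int(30 * 60 * FS), 140.0)
        b[: int(12 * 60 * FS)] = 165.0
        eps = detect_arrhythmia(b, "tachycardia", FS)
        assert len(eps) == 1
        assert eps[0].duration_s == pytest.approx(12 * 60)
        assert not eps[0].severe

    def test_severe_tachycardia(self):
        b = np.full(int(30 * 60 * FS), 140.0)
        b[: int(11 * 60 * FS)] = 185.0
        eps = detect_arrhythmia(b, "tachycardia", FS)
        assert len(eps) == 1 and eps[0].severe

    def test_short_bradycardia_rejected(self):
        b = np.full(int(30 * 60 * FS), 140.0)
        b[: int(2 * 60 * FS)] = 105.0
        assert detect_arrhythmia(b, "bradycardia", FS) == []

    @pytest.mark.parametrize(
        "kind,level,minutes,expected",
        [
            # inclusive >= 10 min for tachycardia, strict > 3 min for bradycardia
            ("tachycardia", 165.0, 10.0, 1),
            ("tachycardia", 165.0, 9.99, 0),
            ("bradycardia", 105.0, 3.0, 0),
            ("bradycardia", 105.0, 3.01, 1),
            # thresholds are strict: exactly 160 / 110 never qualifies
            ("tachycardia", 160.0, 20.0, 0),
            ("bradycardia", 110.0, 20.0, 0),
        ],
    )
    def test_duration_and_threshold_edges(self, kind, level, minutes, expected):
        b = np.full(int(30 * 60 * FS), 140.0)
        b[: int(minutes * 60 * FS)] = level
        assert len(detect_arrhythmia(b, kind, FS)) == expected

    def test_invalid_samples_break_runs(self):
        b = np.full(int(30 * 60 * FS), 165.0)
        valid = np.ones(b.size, dtype=bool)
        valid[int(8 * 60 * FS)] = False  # splits 30 min into 8 + ~22 min
        eps = detect_arrhythmia(b, "tachycardia", FS, valid_mask=valid)
        assert len(eps) == 1  # only the >=10 min tail survives
        assert eps[0].start_idx == int(8 * 60 * FS) + 1

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_on_piecewise_constant(self, data):
        n_seg = data.draw(st.integers(1, 8))
        levels = data.draw(
            st.lists(st.floats(90, 200), min_size=n_seg, max_size=n_seg)
        )
        lens = data.draw(
            st.lists(st.integers(10, 4000), min_size=n_seg, max_size=n_seg)
        )
        b = np.concatenate([np.full(l, v) for v, l in zip(levels, lens)])
        for kind in ("tachycardia", "bradycardia"):
            got = [(e.start_idx, e.end_idx) for e in detect_arrhythmia(b, kind, FS)]
            assert got == brute_force_arrhythmia(b, kind, FS)
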