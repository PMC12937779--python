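"""Feature extraction: baseline, events, lost beats, STV, episodes."""

import numpy as np
import pytest

from ctgrisk.errors import ExtractionError, ValidationError
from ctgrisk.features import (
    Baseline,
    FHREvent,
    compute_stv,
    detect_events,
    extract_features,
    fit_baseline,
    lost_beats,
    most_lost_beats,
    variation_episodes,
)

from conftest import FS, constant_trace, make_trace, plateau_trace


def trimmed_mean_oracle(fhr: np.ndarray, trim: float = 10.0) -> float:
    """Brute-force trimmed mean around the global median (baseline oracle)."""
    med = np.median(fhr)
    kept = fhr[np.abs(fhr - med) <= trim]
    return float(kept.mean())


class TestBaseline:
    def test_constant_trace_identity(self, flat_trace):
        base = fit_baseline(flat_trace)
        assert np.allclose(base.baseline_bpm, 140.0)

    def test_excursion_robustness(self):
        # +15 bpm for 20 s on a flat trace: baseline stays within 140 +/- 2
        trace = plateau_trace(140.0, 15.0, 20.0)
        base = fit_baseline(trace)
        assert np.all(np.abs(base.baseline_bpm - 140.0) < 2.0)
        oracle = trimmed_mean_oracle(trace.fhr_bpm)
        assert abs(base.baseline_bpm.mean() - oracle) < 0.5

    def test_deceleration_robustness(self):
        # planted 60 s / 30 bpm deceleration moves the estimate < 2 bpm
        trace = plateau_trace(140.0, -30.0, 60.0)
        base = fit_baseline(trace)
        assert np.all(np.abs(base.baseline_bpm - 140.0) < 2.0)

    def test_tracks_linear_drift(self):
        n = int(60 * 60 * FS)
        fhr = np.linspace(130.0, 150.0, n)
        base = fit_baseline(make_trace(fhr))
        assert np.all(np.abs(base.baseline_bpm - fhr) < 3.0)

    def test_all_missing_raises(self):
        trace = constant_trace(140.0, 10.0)
        trace.missing_mask[:] = True
        with pytest.raises(ExtractionError):
            fit_baseline(trace)


class TestEventDetection:
    @pytest.mark.parametrize(
        "delta,plateau_s,kind,count",
        [
            (12.0, 10.0, "acceleration", 0),  # too short: duration <= 15 s
            (12.0, 20.0, "acceleration", 1),
            (-25.0, 40.0, "deceleration", 1),  # >= 20 bpm for > 30 s
            (-25.0, 25.0, "deceleration", 0),  # deep but too short
            (-12.0, 45.0, "deceleration", 0),  # fails both criteria
            (-12.0, 70.0, "deceleration", 1),  # >= 10 bpm for > 60 s
        ],
    )
    def test_threshold_examples(self, delta, plateau_s, kind, count):
        trace = plateau_trace(140.0, delta, plateau_s)
        base = Baseline(np.full(len(trace), 140.0))
        events = [e for e in detect_events(trace, base) if e.kind == kind]
        assert len(events) == count

    def test_gap_bridging_merges_one_event(self):
        # a 3 s dropout inside a qualifying acceleration must not split it
        fhr = np.full(int(20 * 60 * FS), 140.0)
        i0 = int(300 * FS)
        fhr[i0 : i0 + int(25 * FS)] = 155.0
        fhr[i0 + int(10 * FS) : i0 + int(13 * FS)] = 140.0
        base = Baseline(np.full(len(fhr), 140.0))
        events = detect_events(make_trace(fhr), base)
        assert [e.kind for e in events] == ["acceleration"]

    def test_events_sorted_and_typed(self):
        fhr = np.full(int(30 * 60 * FS), 140.0)
        fhr[int(600 * FS) : int(640 * FS)] = 110.0  # deceleration at 10 min
        fhr[int(120 * FS) : int(140 * FS)] = 155.0  # acceleration at 2 min
        base = Baseline(np.full(len(fhr), 140.0))
        events = detect_events(make_trace(fhr), base)
        assert [e.kind for e in events] == ["acceleration", "deceleration"]
        assert events[0].onset_s < events[1].onset_s
        assert events[0].peak_deviation_bpm >= 10.0
        assert events[1].peak_deviation_bpm <= -10.0


class TestLostBeats:
    def test_rectangular_product(self):
        trace = plateau_trace(140.0, -30.0, 60.0, start_s=300.0)
        ev = FHREvent("deceleration", 300.0, 360.0, -30.0)
        base = Baseline(np.full(len(trace), 140.0))
        assert lost_beats(ev, trace, base) == pytest.approx(30.0, abs=1e-9)

    def test_rectangular_two_minutes(self):
        trace = plateau_trace(140.0, -10.0, 120.0, start_s=300.0)
        ev = FHREvent("deceleration", 300.0, 420.0, -10.0)
        base = Baseline(np.full(len(trace), 140.0))
        assert lost_beats(ev, trace, base) == pytest.approx(20.0, abs=1e-9)

    def test_triangular_integrated_area(self):
        # triangle peak 20 bpm over 60 s: area = 1/2 * 20 * 1 min = 10 beats
        n = int(20 * 60 * FS)
        t = np.arange(n) / FS
        depth = np.clip(20.0 * (1.0 - np.abs(t - 330.0) / 30.0), 0.0, None)
        trace = make_trace(140.0 - depth)
        ev = FHREvent("deceleration", 300.0, 360.0, -20.0)
        base = Baseline(np.full(n, 140.0))
        got = lost_beats(ev, trace, base)
        oracle = float(np.sum(depth[(t >= 300) & (t < 360)]) * (1 / FS) / 60.0)
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got == pytest.approx(10.0, abs=0.05)

    def test_acceleration_rejected(self, flat_trace):
        ev = FHREvent("acceleration", 10.0, 40.0, 15.0)
        with pytest.raises(ValidationError):
            lost_beats(ev, flat_trace, Baseline(np.full(len(flat_trace), 140.0)))

    def test_most_lost_beats(self):
        evs = [
            FHREvent("deceleration", 0.0, 40.0, -25.0, lost_beats=12.0),
            FHREvent("deceleration", 100.0, 140.0, -25.0, lost_beats=30.0),
            FHREvent("deceleration", 200.0, 240.0, -25.0, lost_beats=7.0),
            FHREvent("acceleration", 300.0, 340.0, 15.0),
        ]
        assert most_lost_beats(evs) == 30.0
        assert most_lost_beats([]) == 0.0


class TestSTV:
    def test_constant_trace_zero(self, flat_trace):
        assert compute_stv(flat_trace, events=[]) == 0.0

    def test_alternating_epochs_closed_form(self):
        # epochs alternating 140/150 bpm: STV = |60000/140 - 60000/150|
        per_epoch = int(3.75 * FS)
        blocks = [np.full(per_epoch, 140.0 if e % 2 == 0 else 150.0) for e in range(320)]
        trace = make_trace(np.concatenate(blocks))
        expected = abs(60000.0 / 140.0 - 60000.0 / 150.0)
        assert compute_stv(trace, events=[]) == pytest.approx(expected, abs=1e-9)

    def test_planted_noise_converges(self):
        # pulse-interval steps of +/- d give STV -> d
        rng = np.random.default_rng(0)
        d = 12.0
        n_epochs = 640
        steps = rng.choice([-d, d], size=n_epochs)
        w = np.cumsum(steps)
        w -= w.mean()
        w = np.clip(w, -40, 40)  # bounded walk; most steps keep |delta| = d
        pi = 60000.0 / 140.0 + np.repeat(w, int(3.75 * FS))
        trace = make_trace(60000.0 / pi)
        got = compute_stv(trace, events=[])
        oracle = float(np.abs(np.diff(w)).mean())
        assert got == pytest.approx(oracle, rel=0.02)

    def test_insufficient_signal_raises(self):
        trace = constant_trace(140.0, 10.0)
        trace.missing_mask[:] = True
        trace.missing_mask[:4] = False
        with pytest.raises(ExtractionError):
            compute_stv(trace, events=[])


def _variability_trace(minute_ranges_ms, base_bpm=140.0):
    """Trace whose e-th epoch pulse interval alternates within each minute."""
    per_epoch = int(3.75 * FS)
    pi0 = 60000.0 / base_bpm
    blocks = []
    for rng_ms in minute_ranges_ms:
        for e in range(16):
            offset = (rng_ms / 2.0) * (1 if e % 2 == 0 else -1)
            blocks.append(np.full(per_epoch, pi0 + offset))
    pi = np.concatenate(blocks)
    return make_trace(60000.0 / pi)


class TestVariationEpisodes:
    def test_constant_trace_low_everywhere(self, flat_trace):
        high, low = variation_episodes(flat_trace, events=[])
        assert high == 0.0
        assert low == 30.0

    def test_planted_high_block_recovered(self):
        ranges = [10.0] * 10 + [45.0] * 10 + [10.0] * 10
        high, low = variation_episodes(_variability_trace(ranges), events=[])
        assert high == 10.0
        assert low == 20.0

    def test_three_qualifying_minutes_no_episode(self):
        ranges = [10.0] * 10 + [45.0] * 3 + [10.0] * 10
        high, low = variation_episodes(_variability_trace(ranges), events=[])
        assert high == 0.0

    def test_five_of_six_rule(self):
        # 5 qualifying minutes + 1 interloper inside the 6-minute window
        ranges = [10.0] * 8 + [45.0, 45.0, 10.0, 45.0, 45.0, 45.0] + [10.0] * 8
        high, _ = variation_episodes(_variability_trace(ranges), events=[])
        assert high == 5.0

    def test_brute_force_scan_agreement(self):
        # random qualification patterns vs an exhaustive window scanner
        rng = np.random.default_rng(3)
        for _ in range(20):
            qual = rng.random(30) < 0.5
            ranges = [45.0 if q else 10.0 for q in qual]
            high, _ = variation_episodes(_variability_trace(ranges), events=[])
            counted = set()
            for start in range(len(qual) - 5):
                if qual[start : start + 6].sum() >= 5:
                    counted |= {m for m in range(start, start + 6) if qual[m]}
            assert high == float(len(counted))


class TestExtractFeatures:
    def test_constant_trace_vector(self, flat_trace):
        fv = extract_features(flat_trace)
        assert fv.basal_fhr == pytest.approx(140.0, abs=1e-6)
        assert (fv.accelerations, fv.decelerations) == (0, 0)
        assert fv.most_lost_beats == 0.0
        assert fv.stv == 0.0
        assert fv.high_variation_min == 0.0
        assert fv.low_variation_min == 30.0
        assert fv.analysed_duration_min == pytest.approx(30.0)
        assert fv.signal_loss_pct == 0.0

    def test_cap_excludes_late_events(self):
        # 90-minute trace with a deceleration at minute 70: not counted
        fhr = np.full(int(90 * 60 * FS), 140.0)
        i0 = int(70 * 60 * FS)
        fhr[i0 : i0 + int(40 * FS)] = 110.0
        fv = extract_features(make_trace(fhr))
        assert fv.decelerations == 0
        assert fv.analysed_duration_min == pytest.approx(60.0)
        # same event at minute 50 is counted
        fhr2 = np.full(int(90 * 60 * FS), 140.0)
        j0 = int(50 * 60 * FS)
        fhr2[j0 : j0 + int(40 * FS)] = 110.0
        assert extract_features(make_trace(fhr2)).decelerations == 1

    def test_signal_loss_percentage(self):
        trace = constant_trace(140.0, 30.0)
        n = len(trace)
        trace.missing_mask[: n // 10] = True
        trace.fhr_bpm[: n // 10] = np.nan
        fv = extract_features(trace)
        assert fv.signal_loss_pct == pytest.approx(10.0, abs=0.1)

    def test_translation_invariance(self):
        fhr = np.full(int(20 * 60 * FS), 140.0)
        fhr[int(300 * FS) : int(325 * FS)] = 155.0
        a = extract_features(make_trace(fhr, t0=0.0))
        b = extract_features(make_trace(fhr, t0=1234.5))
        assert a.as_dict() == b.as_dict()

    def test_baseline_shift_equivariance(self):
        fhr = np.full(int(20 * 60 * FS), 140.0)
        fhr[int(300 * FS) : int(325 * FS)] = 155.0
        fhr[int(600 * FS) : int(640 * FS)] = 110.0
        a = extract_features(make_trace(fhr))
        b = extract_features(make_trace(fhr + 5.0))
        assert b.basal_fhr == pytest.approx(a.basal_fhr + 5.0, abs=0.1)
        assert b.accelerations == a.accelerations
        assert b.decelerations == a.decelerations
        assert b.high_variation_min == a.high_variation_min
        assert b.low_variation_min == a.low_variation_min

    def test_deepening_deceleration_monotone_mlb(self):
        mlbs = []
        for depth in (22.0, 28.0, 34.0):
            trace = plateau_trace(140.0, -depth, 45.0)
            mlbs.append(extract_features(trace).most_lost_beats)
        assert mlbs == sorted(mlbs)
        assert mlbs[0] > 0
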