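import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from synctap.descriptors import (
    Window,
    coefficient_of_variation,
    drift_slope,
    inter_tap_intervals,
    match_nearest_pulse,
    periodicity_error,
    phase_angle,
    plv,
    reaction_times,
    select_window,
    summarize_train,
)
from synctap.errors import (
    InvalidArgumentError,
    ShortTrainWarning,
    UndefinedStatisticError,
    UnsupportedCombinationError,
    UnsupportedTaskError,
)
from synctap.signal import TapEvent
from synctap.stimuli import Strength, Task, make_react_sequence


def _taps(times, amp=0.8):
    return [TapEvent(t, amp) for t in times]


class TestMatchNearestPulse:
    def test_simple_positive_asynchrony(self, iso_pattern):
        t0 = iso_pattern.tap_phase_start_ms
        m = match_nearest_pulse(_taps([t0 + 100.0]), iso_pattern)
        assert m[0].asynchrony_ms == pytest.approx(100.0)
        assert m[0].phase_angle_deg == pytest.approx(72.0)

    def test_wraps_to_next_pulse(self, iso_pattern):
        # +300 ms past a pulse is -200 ms to the next one
        t0 = iso_pattern.tap_phase_start_ms
        m = match_nearest_pulse(_taps([t0 + 300.0]), iso_pattern)
        assert m[0].asynchrony_ms == pytest.approx(-200.0)
        assert m[0].ref_time_ms == pytest.approx(t0 + 500.0)

    def test_matches_brute_force_nearest(self, iso_pattern, rng):
        refs = np.array([e.time_ms for e in iso_pattern.reference_events()])
        times = rng.uniform(refs[0], refs[-1], size=200)
        m = match_nearest_pulse(_taps(sorted(times)), iso_pattern)
        for mt in m:
            brute = refs[np.argmin(np.abs(mt.tap_time_ms - refs))]
            brute_asyn = mt.tap_time_ms - brute
            if abs(brute_asyn) != 250.0:
                assert mt.asynchrony_ms == pytest.approx(brute_asyn)

    def test_midpoint_tie_goes_negative(self, iso_pattern):
        t0 = iso_pattern.tap_phase_start_ms
        m = match_nearest_pulse(_taps([t0 + 250.0]), iso_pattern)
        assert m[0].asynchrony_ms == -250.0
        assert m[0].phase_angle_deg == -180.0
        assert m[0].ref_time_ms == pytest.approx(t0 + 500.0)

    def test_wrap_bound_under_fuzzing(self, iso_pattern, rng):
        times = np.sort(rng.uniform(0, 12_000, size=500))
        m = match_nearest_pulse(_taps(times), iso_pattern)
        asyn = np.array([x.asynchrony_ms for x in m])
        assert np.all(asyn >= -250.0) and np.all(asyn < 250.0)

    def test_strength_copied_from_reference(self, iso_pattern):
        t0 = iso_pattern.tap_phase_start_ms
        m = match_nearest_pulse(_taps([t0 - 30.0, t0 + 500.0]), iso_pattern)
        assert m[0].strength is Strength.STRONG  # beat 1
        assert m[1].strength is Strength.WEAK  # beat 2

    def test_noniso_uses_note_grid(self, noniso_pattern):
        # a tap at a half-beat note must get a half-beat reference
        t0 = noniso_pattern.tap_phase_start_ms
        m = match_nearest_pulse(_taps([t0 + 2.5 * 500.0 + 10.0]),
                                noniso_pattern)
        assert m[0].strength is Strength.HALF
        assert m[0].asynchrony_ms == pytest.approx(10.0)

    def test_react_unsupported(self):
        p = make_react_sequence(seed=0)
        with pytest.raises(UnsupportedTaskError):
            match_nearest_pulse(_taps([100.0]), p)

    def test_empty_taps(self, iso_pattern):
        assert match_nearest_pulse([], iso_pattern) == []

    def test_order_canonicalized(self, iso_pattern, rng):
        t0 = iso_pattern.tap_phase_start_ms
        times = list(t0 + np.arange(24) * 500.0 + rng.normal(0, 20, 24))
        shuffled = list(times)
        rng.shuffle(shuffled)
        a = match_nearest_pulse(_taps(times), iso_pattern)
        b = match_nearest_pulse(_taps(shuffled), iso_pattern)
        assert [x.tap_time_ms for x in a] == [x.tap_time_ms for x in b]
        assert [x.asynchrony_ms for x in a] == [x.asynchrony_ms for x in b]


class TestPhaseAngle:
    @pytest.mark.parametrize("asyn,ioi,expected", [
        (-250.0, 500.0, -180.0),
        (0.0, 500.0, 0.0),
        (125.0, 500.0, 90.0),
        (-125.0, 500.0, -90.0),
    ])
    def test_values(self, asyn, ioi, expected):
        assert phase_angle(asyn, ioi) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            phase_angle(300.0, 500.0)

    @given(hst.floats(min_value=-249.9, max_value=249.9))
    @settings(max_examples=50, deadline=None)
    def test_linear_and_odd(self, a):
        assert phase_angle(-a, 500.0) == pytest.approx(-phase_angle(a, 500.0))


class TestPLV:
    @pytest.mark.parametrize("const", [-170.0, -29.4, 0.0, 90.0])
    def test_constant_angles_give_one(self, const):
        assert plv([const] * 16) == pytest.approx(1.0)

    def test_opposite_vectors_cancel(self):
        assert plv([0.0, 180.0]) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_pair(self):
        assert plv([0.0, 90.0]) == pytest.approx(np.sqrt(2) / 2, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            plv([])

    def test_matches_complex_sum_oracle(self, rng):
        """1000 random angle sets agree with an independent complex-mean
        oracle to 1e-12."""
        for _ in range(1000):
            ang = rng.uniform(-180, 180, size=rng.integers(1, 40))
            oracle = abs(np.sum(np.exp(1j * np.deg2rad(ang)))) / len(ang)
            assert abs(plv(ang) - oracle) < 1e-12

    def test_rotation_invariance(self, rng):
        ang = rng.uniform(-180, 180, size=30)
        for shift in (10.0, 90.0, 180.0, 271.3):
            assert plv(ang + shift) == pytest.approx(plv(ang), abs=1e-12)


class TestReactionTimes:
    def test_simple_subtraction(self):
        p = make_react_sequence(seed=1)
        s0 = p.events[3].time_ms
        rts, dropped = reaction_times(_taps([s0 + 232.0]), p)
        assert dropped == 0
        assert rts[0] == pytest.approx(232.0)

    def test_tap_before_first_stimulus_dropped(self):
        p = make_react_sequence(seed=1)
        rts, dropped = reaction_times(_taps([-50.0]), p)
        assert dropped == 1 and rts.size == 0

    def test_closest_preceding_not_first(self, rng):
        p = make_react_sequence(seed=2)
        stim = [e.time_ms for e in p.events]
        tap_t = stim[5] + 150.0
        rts, _ = reaction_times(_taps([tap_t]), p)
        # brute-force closest-preceding oracle
        oracle = tap_t - max(s for s in stim if s <= tap_t)
        assert rts[0] == pytest.approx(oracle)
        assert np.all(rts >= 0)

    def test_non_react_rejected(self, iso_pattern):
        with pytest.raises(UnsupportedTaskError):
            reaction_times(_taps([100.0]), iso_pattern)


class TestIntervalDescriptors:
    def test_iti_values(self):
        assert np.allclose(inter_tap_intervals(_taps([0, 500, 1000])),
                           [500, 500])
        assert np.allclose(inter_tap_intervals(_taps([0, 450, 1000])),
                           [450, 550])

    def test_iti_needs_two_taps(self):
        with pytest.raises(UndefinedStatisticError):
            inter_tap_intervals(_taps([100.0]))

    def test_iti_monotonicity_enforced(self):
        with pytest.raises(InvalidArgumentError):
            inter_tap_intervals(_taps([0.0, 500.0, 400.0]))

    def test_cv_hand_oracle(self):
        # sd([450,550]) = 70.71 (n-1), mean 500 -> 14.142 %
        assert coefficient_of_variation([450.0, 550.0]) == pytest.approx(
            14.142, abs=1e-3)

    def test_cv_zero_for_constant(self):
        assert coefficient_of_variation([500.0] * 10) == 0.0

    @given(hst.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_cv_scale_invariance(self, k):
        itis = np.array([480.0, 505.0, 520.0, 495.0])
        assert coefficient_of_variation(k * itis) == pytest.approx(
            coefficient_of_variation(itis), rel=1e-9)

    @pytest.mark.parametrize("mean_iti,expected", [(500.0, 0.0),
                                                   (513.0, 13.0),
                                                   (487.0, 13.0)])
    def test_periodicity_error(self, mean_iti, expected):
        itis = [mean_iti - 5, mean_iti + 5]
        assert periodicity_error(itis, 500.0) == pytest.approx(expected)

    def test_drift_slope_exact_line(self):
        slope, p = drift_slope([490.0, 495.0, 500.0, 505.0, 510.0])
        assert slope == pytest.approx(5.0)
        assert p < 1e-6

    def test_drift_slope_zero_for_constant(self):
        slope, p = drift_slope([500.0] * 10)
        assert slope == 0.0

    def test_drift_type_one_error_calibration(self, rng):
        """White-noise trains reject H0: slope=0 at about the nominal 5%."""
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            _, p = drift_slope(rng.normal(500, 20, size=23))
            hits += p < 0.05
        rate = hits / n_sim
        assert 0.03 < rate < 0.07

    def test_drift_needs_three(self):
        with pytest.raises(UndefinedStatisticError):
            drift_slope([500.0, 510.0])


class TestSelectWindow:
    def test_unpaced_ordinal_windows(self, repro_pattern):
        taps = _taps(np.arange(24) * 500.0 + repro_pattern.tap_phase_start_ms)
        first = select_window(taps, "first_cycle", repro_pattern)
        stab = select_window(taps, "stabilized", repro_pattern)
        assert len(first) == 8 and len(stab) == 16
        assert stab[0] is taps[8]

    def test_paced_cycle_windows_use_matched_cycle(self, iso_pattern):
        t0 = iso_pattern.tap_phase_start_ms
        # tap leading cycle-2 beat 1 by 40 ms must land in "stabilized"
        times = list(t0 + np.arange(8) * 500.0) + [t0 + 8 * 500.0 - 40.0]
        m = match_nearest_pulse(_taps(times), iso_pattern)
        stab = select_window(m, Window.STABILIZED, iso_pattern)
        assert len(stab) == 1
        assert stab[0].ref_cycle == 2

    def test_short_train_warns_and_returns_partial(self, repro_pattern):
        taps = _taps(np.arange(10) * 500.0)
        with pytest.warns(ShortTrainWarning):
            out = select_window(taps, "stabilized", repro_pattern)
        assert len(out) == 2


class TestSummarizeTrain:
    def _matched_perfect(self, pattern, asyn=0.0, amp=0.8):
        refs = pattern.reference_events()
        return match_nearest_pulse(
            _taps([e.time_ms + asyn for e in refs], amp=amp), pattern)

    def test_iso_sync_stabilized_fields(self, iso_pattern):
        m = self._matched_perfect(iso_pattern, asyn=-40.0)
        s = summarize_train(m, Task.ISO_SYNC_1_1, "stabilized")
        assert s.plv is not None and s.cv_percent is not None
        assert s.tf_sd_au is not None
        assert set(s.plv_by_strength) == {"strong", "weak"}
        assert s.rt_mean_ms is None and s.rt_sd_ms is None
        assert s.pe_ms is None  # PE is a reproduction-task descriptor

    def test_react_only_rt_fields(self, react_pattern):
        stim = [e.time_ms for e in react_pattern.events]
        # RT below the 200 ms minimum IOI, so no tap crosses the next beep
        taps = _taps([s + 150.0 for s in stim[:30]])
        s = summarize_train(taps, Task.REACT, "stabilized",
                            pattern=react_pattern)
        assert s.rt_mean_ms == pytest.approx(150.0)
        assert s.rt_sd_ms == pytest.approx(0.0)
        assert s.plv is None and s.cv_percent is None and s.tf_mean_au is None

    def test_noiseless_train_is_perfect(self, iso_pattern):
        m = self._matched_perfect(iso_pattern, asyn=0.0)
        s = summarize_train(m, Task.ISO_SYNC_1_1, "stabilized")
        assert s.plv == pytest.approx(1.0)
        assert s.cv_percent == pytest.approx(0.0)
        assert s.pa_circmean_deg == pytest.approx(0.0)

    def test_repro_pe_and_drift(self, repro_pattern):
        t0 = repro_pattern.tap_phase_start_ms
        taps = _taps(t0 + np.cumsum([0] + [513.0] * 23))
        s = summarize_train(taps, Task.ISO_REPRO, "stabilized",
                            pattern=repro_pattern)
        assert s.pe_ms == pytest.approx(13.0)
        assert s.mean_iti_ms == pytest.approx(513.0)
        assert s.drift_slope_ms_per_tap == pytest.approx(0.0, abs=1e-9)

    def test_strength_counts_conserved(self, noniso_pattern):
        m = self._matched_perfect(noniso_pattern, asyn=10.0)
        s = summarize_train(m, Task.NONISO_SYNC, "stabilized")
        assert sum(s.n_by_strength.values()) == s.n_taps
        assert set(s.n_by_strength) == {"strong", "weak", "half"}

    def test_unsupported_combination(self, react_pattern):
        with pytest.raises(UnsupportedCombinationError):
            summarize_train([], Task.REACT, "first_cycle",
                            pattern=react_pattern)
        with pytest.raises(UnsupportedCombinationError):
            summarize_train([], Task.ISO_SYNC_1_4, "first_cycle")
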