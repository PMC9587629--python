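import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chestpain_cea.markov import (CalibrationError, MarkovState,
                                  TransitionSchedule, build_schedule,
                                  calibrate_schedules, discounted_qalys,
                                  gompertz_mortality, remaining_qalys,
                                  run_cohort)
from chestpain_cea.params import MarkovSettings


def schedule(q, inc=0.0, hr=1.6, start_age=56):
    q = np.asarray(q, dtype=float)
    return TransitionSchedule(start_age=start_age, annual_mortality=q,
                              annual_cvd_incidence=np.full_like(q, inc),
                              hr_cvd_mortality=hr)


def brute_force_trace(q, inc, hr, start_state, horizon):
    """Explicit per-year scalar loop, independent of the engine."""
    non = 1.0 if start_state == "non_cvd" else 0.0
    cvd = 1.0 - non
    dead = 0.0
    occ = [(non, cvd, dead)]
    for t in range(horizon):
        qc = 1 - (1 - q[t]) ** hr
        non2 = non * (1 - q[t]) * (1 - inc[t])
        cvd2 = non * (1 - q[t]) * inc[t] + cvd * (1 - qc)
        dead2 = dead + non * q[t] + cvd * qc
        non, cvd, dead = non2, cvd2, dead2
        occ.append((non, cvd, dead))
    return np.array(occ)


class TestRunCohort:
    def test_certain_death_half_cycle(self):
        """q ≡ 1 over one cycle credits half a cycle alive."""
        trace = run_cohort(schedule([1.0]), MarkovState.non_cvd)
        assert trace.half_cycle_corrected_occupancy[0, :2].sum() == 0.5

    def test_immortal_cohort(self):
        trace = run_cohort(schedule([0.0] * 10, hr=3.0))
        assert np.allclose(trace.alive_fraction(), 1.0)

    def test_three_cycle_hand_computation(self):
        """q = (0.1, 0.2, 0.3), hr = 1, no incidence: survival telescopes."""
        trace = run_cohort(schedule([0.1, 0.2, 0.3], hr=1.0))
        alive = trace.occupancy[:, 0]
        expected = [1.0, 0.9, 0.9 * 0.8, 0.9 * 0.8 * 0.7]
        assert np.allclose(alive, expected)
        corrected = trace.half_cycle_corrected_occupancy[:, 0]
        assert np.allclose(corrected, [(1 + 0.9) / 2, (0.9 + 0.72) / 2,
                                       (0.72 + 0.504) / 2])

    def test_short_schedule_names_missing_ages(self):
        with pytest.raises(ValueError, match="missing ages \\[59, 60\\]"):
            run_cohort(schedule([0.1] * 3), horizon=5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        q=st.lists(st.floats(0, 1), min_size=5, max_size=5),
        inc=st.lists(st.floats(0, 1), min_size=5, max_size=5),
        hr=st.floats(0, 5),
        start=st.sampled_from(["non_cvd", "cvd"]),
    )
    def test_matches_brute_force_oracle(self, q, inc, hr, start):
        sched = TransitionSchedule(
            start_age=50, annual_mortality=np.array(q),
            annual_cvd_incidence=np.array(inc), hr_cvd_mortality=hr)
        trace = run_cohort(sched, start)
        oracle = brute_force_trace(q, inc, hr, start, 5)
        assert np.allclose(trace.occupancy, oracle, atol=1e-14)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        q=st.lists(st.floats(0, 1), min_size=1, max_size=8),
        inc=st.floats(0, 1),
        hr=st.floats(0, 5),
    )
    def test_rows_sum_to_one_and_death_monotone(self, q, inc, hr):
        trace = run_cohort(schedule(q, inc=inc, hr=hr))
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(trace.occupancy[:, 2]) >= -1e-15)

    def test_hazard_ratio_on_survival_scale_near_one(self):
        """With q near 1, naive multiplication would exceed 1."""
        sched = schedule([0.9], hr=1.6)
        assert sched.cvd_mortality()[0] <= 1.0
        assert sched.cvd_mortality()[0] == pytest.approx(1 - 0.1**1.6)


class TestDiscountedQalys:
    def test_immortal_undiscounted(self):
        trace = run_cohort(schedule([0.0] * 10))
        assert discounted_qalys(trace, (1, 1, 0), 0.0) == pytest.approx(10.0)

    def test_immortal_discounted_geometric(self):
        trace = run_cohort(schedule([0.0] * 25))
        expected = sum(1 / 1.04**t for t in range(1, 26))
        assert discounted_qalys(trace, (1, 1, 0), 0.04) == \
            pytest.approx(expected)

    def test_discount_monotonicity(self):
        trace = run_cohort(schedule([0.1] * 20))
        rates = [0.0, 0.02, 0.04, 0.08]
        vals = [discounted_qalys(trace, (0.9, 0.8, 0), r) for r in rates]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_utility_out_of_range(self):
        trace = run_cohort(schedule([0.0]))
        with pytest.raises(ValueError):
            discounted_qalys(trace, (1.2, 1, 0), 0.04)

    def test_half_cycle_correction_bounds(self):
        """Corrected QALYs sit strictly between end- and start-of-cycle sums."""
        trace = run_cohort(schedule([0.1] * 20))
        u = np.array([1.0, 1.0, 0.0])
        disc = 1 / 1.04 ** (np.arange(20) + 1)
        end_of_cycle = float((trace.occupancy[1:] @ u) @ disc)
        start_of_cycle = float((trace.occupancy[:-1] @ u) @ disc)
        corrected = discounted_qalys(trace, u, 0.04)
        assert end_of_cycle < corrected < start_of_cycle

    def test_hr_one_with_equal_utilities_is_label_invariant(self):
        sched = schedule([0.1] * 30, inc=0.05, hr=1.0)
        a = discounted_qalys(run_cohort(sched, "non_cvd"), (0.8, 0.8, 0), 0.04)
        b = discounted_qalys(run_cohort(sched, "cvd"), (0.8, 0.8, 0), 0.04)
        assert a == pytest.approx(b, rel=1e-12)


class TestCalibration:
    def test_hits_published_anchors(self):
        s = MarkovSettings()
        cal = calibrate_schedules((13.3, 11.1), s, (0.85, 0.74, 0.0), 0.04)
        assert abs(cal.residuals[0]) < 0.05
        assert abs(cal.residuals[1]) < 0.05
        assert cal.achieved[0] == pytest.approx(13.3, abs=0.05)
        assert cal.achieved[1] == pytest.approx(11.1, abs=0.05)

    def test_identity_when_targets_equal_model_output(self):
        s = MarkovSettings()
        u = (0.85, 0.74, 0.0)
        targets = (remaining_qalys(56, False, s, u, 0.04),
                   remaining_qalys(56, True, s, u, 0.04))
        cal = calibrate_schedules(targets, s, u, 0.04)
        assert cal.mortality_scale == pytest.approx(1.0, abs=1e-6)
        assert cal.utility_scale == pytest.approx(1.0, abs=1e-6)

    def test_infeasible_target_fails_with_diagnostics(self):
        with pytest.raises(CalibrationError, match="bounds"):
            calibrate_schedules((200.0, 150.0), MarkovSettings(),
                                (0.85, 0.74, 0.0), 0.04)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_schedules((0.0, 11.1), MarkovSettings(),
                                (0.85, 0.74, 0.0), 0.04)


class TestRemainingQalys:
    def test_post_ami_lower(self):
        s = MarkovSettings()
        u = (0.85, 0.74, 0.0)
        assert remaining_qalys(56, True, s, u, 0.04) < \
            remaining_qalys(56, False, s, u, 0.04)

    def test_hr_one_equal_utilities_symmetry(self):
        s = MarkovSettings(hr_cvd_mortality=1.0)
        u = (0.8, 0.8, 0.0)
        assert remaining_qalys(56, True, s, u, 0.04) == \
            pytest.approx(remaining_qalys(56, False, s, u, 0.04), rel=1e-12)

    def test_gompertz_increases_with_age(self):
        ages = np.arange(40, 100)
        q = gompertz_mortality(ages, 2e-5, 0.095)
        assert np.all(np.diff(q) > 0)
        assert np.all((q >= 0) & (q <= 1))

    def test_build_schedule_covers_lifetime(self):
        sched = build_schedule(MarkovSettings())
        assert sched.start_age == 56
        assert sched.horizon == 110 - 56
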