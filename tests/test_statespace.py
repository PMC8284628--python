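"""Model dynamics: elementary steps, full simulation, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saccade_adapt.schedules import Exp2Config, ExperimentSchedule, TrialSpec, \
    build_exp2_schedule
from saccade_adapt.statespace import (
    Model1Params, Model2Params, SensitivityTracker, TwoStateParams,
    error_for_trial, observe_model1, observe_model2, simulate,
    simulate_reference, steady_state, step_model1, step_model2,
    update_sensitivity,
)

M1 = Model1Params(0.9963, 0.8071, 0.002852, 0.03267, 0.9481, 0.0599, 0.3127,
                  7.844e-6, 9.397e-5)
M2 = Model2Params(0.9817, 0.8680, 0.8433, 0.0051, 0.0063, 0.0199, 0.1680,
                  0.0027, 0.3088)


def _trial(r=0.0, clamp=False, brk=False, phase=None, index=0):
    if phase is None:
        phase = "clamp" if clamp else ("perturbation" if r else "baseline")
    return TrialSpec(index, phase, r, clamp, brk)


class TestElementaryOps:
    @pytest.mark.parametrize("r,clamp,y,expected", [
        (5.0, False, 2.0, 3.0),
        (0.0, True, 2.0, 0.0),
        (-5.0, False, -5.0, 0.0),
    ])
    def test_error_for_trial(self, r, clamp, y, expected):
        assert error_for_trial(_trial(r=r, clamp=clamp), y) == expected

    def test_step_model1_learning_from_zero_state(self):
        x = step_model1(np.zeros(2), 5.0, np.array([0.002852, 0.03267]),
                        False, M1)
        np.testing.assert_allclose(x, [0.01426, 0.16335])

    def test_step_model1_pure_retention(self):
        x = step_model1(np.ones(2), 0.0, np.zeros(2), False, M1)
        np.testing.assert_allclose(x, [0.9963, 0.8071])

    def test_step_model1_pure_break_decay(self):
        params = Model1Params(1.0, 1.0, 0.0, 0.0, 0.9481, 0.0599, 0.3127)
        x = step_model1(np.ones(2), 0.0, np.zeros(2), True, params)
        np.testing.assert_allclose(x, [0.9481, 0.0599])

    def test_step_model2_learning_from_zero_state(self):
        x = step_model2(np.zeros(3), 5.0, np.array([0.0051, 0.0063, 0.0199]),
                        False, M2)
        np.testing.assert_allclose(x, [0.0255, 0.0315, 0.0995])

    def test_step_model2_break_hits_deceleration_state_only(self):
        params = Model2Params(1.0, 1.0, 1.0, 0, 0, 0, 0.1680, 0.0, 0.3)
        x = step_model2(np.array([1.0, 0.0, 1.0]), 0.0, np.zeros(3), True,
                        params)
        np.testing.assert_allclose(x, [1.0, 0.0, 0.1680])

    def test_step_model2_pure_retention(self):
        x = step_model2(np.ones(3), 0.0, np.zeros(3), False, M2)
        np.testing.assert_allclose(x, [0.9817, 0.8680, 0.8433])

    def test_step_rejects_non_finite(self):
        from saccade_adapt.errors import SaccadeAdaptError
        with pytest.raises(SaccadeAdaptError):
            step_model1(np.array([np.nan, 0.0]), 1.0, np.zeros(2), False, M1)

    @pytest.mark.parametrize("x,p,expected", [
        ((0.4, 0.6), 0.3127, (0.3127, 0.6873)),
        ((0.4, 0.6), 0.0, (0.0, 1.0)),
        ((0.4, 0.6), 1.0, (1.0, 0.0)),
    ])
    def test_observe_model1(self, x, p, expected):
        np.testing.assert_allclose(observe_model1(np.array(x), p), expected)

    def test_observe_model2_examples(self):
        np.testing.assert_allclose(
            observe_model2(np.array([1.0, 0.1, 0.2]), 0.3088),
            (0.4088, 0.8912))
        for p in (0.0, 0.37, 1.0):
            ya, yd = observe_model2(np.array([1.0, 0.0, 0.0]), p)
            assert ya + yd == pytest.approx(1.0)  # aim conservation
        np.testing.assert_allclose(
            observe_model2(np.array([0.0, 0.3, 0.4]), 0.5), (0.3, 0.4))


class TestSensitivityUpdate:
    def test_zero_growth_leaves_b_unchanged(self):
        b0 = np.array([0.002852, 0.03267])
        params = Model1Params(0.99, 0.8, *b0, 1, 1, 0.3, 0.0, 0.0)
        b = update_sensitivity(b0, _trial(r=5.0), SensitivityTracker(), params)
        np.testing.assert_array_equal(b, b0)

    def test_additive_accumulation_over_perturbation_trials(self):
        b0 = np.array([0.001, 0.01])
        params = Model1Params(0.99, 0.8, *b0, 1, 1, 0.3, 1e-5, 1e-4)
        tracker = SensitivityTracker()
        for _ in range(10):
            b = update_sensitivity(b0, _trial(r=5.0), tracker, params)
        np.testing.assert_allclose(b, b0 + 10 * np.array([1e-5, 1e-4]))

    def test_reset_when_perturbation_switches_sign(self):
        b0 = np.array([0.001, 0.01])
        beta = np.array([1e-5, 1e-4])
        params = Model1Params(0.99, 0.8, *b0, 1, 1, 0.3, *beta)
        tracker = SensitivityTracker()
        for _ in range(20):
            update_sensitivity(b0, _trial(r=5.0), tracker, params)
        b = update_sensitivity(b0, _trial(r=-5.0), tracker, params)
        np.testing.assert_allclose(b, b0 + beta)  # back to start + one step

    def test_clamp_trials_freeze_growth(self):
        b0 = np.array([0.001, 0.01])
        params = Model1Params(0.99, 0.8, *b0, 1, 1, 0.3, 1e-5, 1e-4)
        tracker = SensitivityTracker()
        update_sensitivity(b0, _trial(r=5.0), tracker, params)
        b = update_sensitivity(b0, _trial(clamp=True), tracker, params)
        np.testing.assert_allclose(b, b0 + np.array([1e-5, 1e-4]))


class TestSimulate:
    def test_three_trial_hand_iteration(self):
        """Two learning trials then a clamp: total matches hand arithmetic."""
        trials = [_trial(r=5.0, index=0), _trial(r=5.0, index=1),
                  _trial(clamp=True, index=2)]
        sched = ExperimentSchedule("exp1", trials)
        params = Model1Params(0.9963, 0.8071, 0.002852, 0.03267, 0.9481,
                              0.0599, 0.3127, 0.0, 0.0)
        trace = simulate(sched, params)
        assert trace.y[2] == pytest.approx(0.3173, abs=5e-5)
        assert trace.e[2] == 0.0

    def test_all_clamp_schedule_stays_at_zero(self):
        sched = ExperimentSchedule("exp1", [
            _trial(clamp=True, index=i) for i in range(50)])
        trace = simulate(sched, M2)
        assert np.all(trace.y == 0.0)

    def test_monotone_approach_to_closed_form_fixed_point(self):
        sched = ExperimentSchedule("exp1", [
            _trial(r=5.0, index=i) for i in range(4000)])
        params = Model1Params(0.98, 0.80, 0.01, 0.1, 1, 1, 0.3127, 0.0, 0.0)
        trace = simulate(sched, params)
        assert np.all(np.diff(trace.y) >= -1e-12)
        x_star = steady_state(params, 5.0)
        np.testing.assert_allclose(trace.x[-1], x_star, atol=1e-9)

    def test_model1_with_unit_break_decay_collapses_to_twostate(self, exp2):
        m1 = Model1Params(0.9963, 0.8071, 0.002852, 0.03267, 1.0, 1.0, 0.3127)
        ts = TwoStateParams(0.9963, 0.8071, 0.002852, 0.03267)
        y1 = simulate(exp2, m1).y
        y2 = simulate(exp2, ts).y
        np.testing.assert_allclose(y1, y2, atol=1e-12)

    def test_clamp_trials_have_zero_error(self, exp1, m2_ref):
        trace = simulate(exp1, m2_ref)
        assert np.all(trace.e[trace.clamp] == 0.0)
        not_clamp = ~trace.clamp
        np.testing.assert_allclose(
            trace.e[not_clamp], (trace.r - trace.y)[not_clamp], atol=1e-12)

    def test_conservation_of_expressed_adaptation(self, exp1, m1_ref, m2_ref):
        """yA + yD equals the summed hidden state on every trial."""
        t1 = simulate(exp1, m1_ref)
        np.testing.assert_allclose(t1.yA + t1.yD, t1.x.sum(axis=1),
                                   atol=1e-12)
        t2 = simulate(exp1, m2_ref)
        np.testing.assert_allclose(t2.yA + t2.yD, t2.x.sum(axis=1),
                                   atol=1e-12)

    def test_mismatched_params_raise(self, exp2):
        from saccade_adapt.errors import SaccadeAdaptError
        with pytest.raises(SaccadeAdaptError):
            simulate(exp2, M1, "model2")


# ---------------------------------------------------------------------------
# Oracle equivalence: fast loop vs naive per-trial reference
# ---------------------------------------------------------------------------

_phase_strategy = st.sampled_from([
    (0.0, False), (5.0, False), (-5.0, False), (0.0, True)])


@st.composite
def _random_schedule(draw):
    n = draw(st.integers(min_value=1, max_value=60))
    trials = []
    for i in range(n):
        r, clamp = draw(_phase_strategy)
        brk = draw(st.booleans())
        phase = "clamp" if clamp else ("perturbation" if r else "baseline")
        trials.append(TrialSpec(i, phase, r, clamp, brk))
    return ExperimentSchedule("exp1", trials)


@st.composite
def _random_params(draw):
    model = draw(st.sampled_from(["twostate", "model1", "model2"]))
    u = lambda lo, hi: draw(st.floats(lo, hi, allow_nan=False))
    if model == "model2":
        return Model2Params(u(0, 1), u(0, 1), u(0, 1), u(0, 0.1), u(0, 0.1),
                            u(0, 0.1), u(0, 1), u(0, 0.01), u(0, 1))
    a_s = u(0.5, 1.0)
    a_f = a_s * u(0, 1)
    b_f = u(0, 0.1)
    b_s = b_f * u(0, 1)
    if model == "twostate":
        return TwoStateParams(a_s, a_f, b_s, b_f, u(0, 1), u(0, 1))
    return Model1Params(a_s, a_f, b_s, b_f, u(0, 1), u(0, 1), u(0, 1),
                        u(0, 1e-4), u(0, 1e-4))


@settings(max_examples=80, deadline=None, derandomize=True)
@given(sched=_random_schedule(), params=_random_params())
def test_simulator_matches_naive_reference(sched, params):
    fast = simulate(sched, params)
    ref = simulate_reference(sched, params)
    np.testing.assert_allclose(fast.yA, ref.yA, atol=1e-12)
    np.testing.assert_allclose(fast.yD, ref.yD, atol=1e-12)
    np.testing.assert_allclose(fast.e, ref.e, atol=1e-12)
    np.testing.assert_allclose(fast.x, ref.x, atol=1e-12)
    np.testing.assert_allclose(fast.b, ref.b, atol=1e-12)


# ---------------------------------------------------------------------------
# Spontaneous recovery of the constrained two-state model
# ---------------------------------------------------------------------------


def test_two_state_spontaneous_recovery_sign(exp2):
    """Adaptation -> extinction -> clamp: the error-free phase re-expresses
    the initially learned direction when slow/fast constraints hold strictly
    in the physiologically plausible regime."""
    arr = exp2.as_arrays()
    clamp_idx = np.flatnonzero(arr["phase"] == "clamp")
    rng = np.random.default_rng(20240917)
    for _ in range(30):
        params = TwoStateParams(
            a_s=rng.uniform(0.992, 0.999), a_f=rng.uniform(0.6, 0.9),
            b_s=rng.uniform(0.001, 0.01), b_f=rng.uniform(0.04, 0.25),
        )
        trace = simulate(exp2, params)
        # late clamp displacement carries the sign of the initial +5 learning
        assert np.all(trace.y[clamp_idx[-10:]] > 0)
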