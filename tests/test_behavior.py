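"""Psychometric fits and perturbation-bias statistics."""

import copy

import numpy as np
import pytest

import clickddm as cd
from clickddm.behavior import (
    bilateral_impairment,
    bias_difference,
    epoch_bias,
    fit_psychometric,
    sigmoid4,
    unilateral_bias,
)
from clickddm.stimuli import Session


def _bernoulli_session(x0, b, y0, a, n_per_bin=300, seed=0, side="none"):
    """Trials whose choices are drawn from a known sigmoid of click diff."""
    rng = np.random.default_rng(seed)
    trials = []
    for d in range(-9, 10, 2):
        nl = max(4 - d // 2, 1)
        nr = nl + d
        if nr < 0:
            nl, nr = nl - nr, 0
        p = sigmoid4(d, x0, b, y0, a)
        for _ in range(n_per_bin):
            tr = cd.ClickTrial(
                left_clicks=np.sort(rng.uniform(0, 1, nl)),
                right_clicks=np.sort(rng.uniform(0, 1, nr)),
                duration=1.0, rate_left=max(nl, 1), rate_right=max(nr, 1),
                correct_side="R" if nr >= nl else "L",
                choice="R" if rng.random() < p else "L",
            )
            trials.append(tr)
    return Session(trials=trials, inactivated_side=side,
                   session_role="control" if side == "none" else "perturbation")


class TestPsychometric:
    def test_parameter_recovery(self):
        truth = dict(x0=0.5, b=2.0, y0=0.05, a=0.9)
        sess = _bernoulli_session(**truth, n_per_bin=500, seed=1)
        fit = fit_psychometric(sess)
        assert fit.x0 == pytest.approx(truth["x0"], abs=0.4)
        assert fit.b == pytest.approx(truth["b"], rel=0.25)
        assert fit.y0 == pytest.approx(truth["y0"], abs=0.04)
        assert fit.a == pytest.approx(truth["a"], abs=0.06)
        assert not fit.degenerate

    def test_symmetric_choices_give_small_inflection(self, symmetric_params):
        sess = cd.generate_stimulus_session(3000, seed=61, motor_fraction=0.0)
        cd.simulate_session_choices(sess, symmetric_params, seed=62)
        fit = fit_psychometric(sess)
        assert abs(fit.x0) <= 0.5

    def test_flat_data_flagged_degenerate(self):
        sess = _bernoulli_session(0.0, 2.0, 0.5, 0.0, n_per_bin=100, seed=2)
        fit = fit_psychometric(sess)
        assert fit.degenerate and fit.a == pytest.approx(0.0, abs=0.05)

    def test_too_few_levels_rejected(self, trial_factory):
        trials = []
        for d, n in [(0, 5), (2, 5), (-2, 5)]:
            for _ in range(n):
                t = trial_factory([0.1] * 3, [0.1] * (3 + d) if d >= 0 else [], 1.0)
                t.choice = "R"
                trials.append(t)
        with pytest.raises(ValueError, match="distinct"):
            fit_psychometric(trials)

    def test_threshold_shifts_psychometric_midpoint(self, trial_factory):
        """A rightward-categorization penalty (thresh > 0) shifts the fitted
        inflection to the right."""
        base = cd.ModelParams.symmetric(sigma2_s=1.5, bound_B=10.0, lapse=0.1)
        fits = []
        for th in (0.0, 2.0):
            sess = cd.generate_stimulus_session(2000, seed=63, motor_fraction=0.0)
            cd.simulate_session_choices(sess, base.replace(bias_thresh=th), seed=64)
            fits.append(fit_psychometric(sess))
        assert fits[1].x0 > fits[0].x0 + 0.5


class TestUnilateralBias:
    def test_identical_sessions_zero_bias(self, symmetric_params):
        sess = cd.generate_stimulus_session(400, seed=71, motor_fraction=0.0, inactivated_side="L")
        cd.simulate_session_choices(sess, symmetric_params, seed=72)
        ctrl = copy.deepcopy(sess)
        ctrl.session_role = "control"
        est = unilateral_bias(sess, ctrl, n_boot=200, seed=0)
        assert est.bias == 0.0
        np.testing.assert_allclose(est.per_bin, 0.0)
        # bootstrap resamples the two arms independently, so p is merely
        # "clearly not significant" rather than exactly 1
        assert est.p_value > 0.5
        assert est.ci95[0] <= 0.0 <= est.ci95[1]

    def test_constructed_flip_recovered(self, symmetric_params):
        """Flipping 20% of contra (right, for left-side inactivation)
        choices to ipsi produces a bias of about 20 x (mean contra
        fraction), within the bootstrap CI."""
        ctrl = cd.generate_stimulus_session(3000, seed=73, motor_fraction=0.0)
        cd.simulate_session_choices(ctrl, symmetric_params, seed=74)
        pert = copy.deepcopy(ctrl)
        pert.inactivated_side = "L"
        pert.session_role = "perturbation"
        for t in pert.trials:
            t.perturbation = "unilateral_L"
        rng = np.random.default_rng(75)
        contra_frac = np.mean([t.choice == "R" for t in ctrl.trials])
        for t in pert.trials:
            if t.choice == "R" and rng.random() < 0.2:
                t.choice = "L"
        est = unilateral_bias(pert, ctrl, seed=76)
        expect = 20.0 * contra_frac
        assert est.ci95[0] <= expect <= est.ci95[1]
        assert est.bias == pytest.approx(expect, abs=3.0)
        assert est.p_value < 0.01

    def test_antisymmetric_under_arm_swap(self, symmetric_params):
        a = cd.generate_stimulus_session(500, seed=77, motor_fraction=0.0, inactivated_side="L")
        cd.simulate_session_choices(a, symmetric_params, seed=78)
        b = cd.generate_stimulus_session(500, seed=79, motor_fraction=0.0)
        cd.simulate_session_choices(b, symmetric_params, seed=80)
        e1 = unilateral_bias(a, b, n_boot=50, seed=0)
        b2 = copy.deepcopy(b); b2.inactivated_side = "L"; a2 = copy.deepcopy(a); a2.inactivated_side = "none"
        for t in b2.trials:
            t.perturbation = "unilateral_L"
        for t in a2.trials:
            t.perturbation = "none"
        e2 = unilateral_bias(b2, a2, n_boot=50, seed=0)
        assert e1.bias == pytest.approx(-e2.bias, abs=1e-9)


class TestBilateralImpairment:
    def test_identical_sessions_zero(self, symmetric_params, small_session):
        est = bilateral_impairment(small_session, copy.deepcopy(small_session), n_boot=100, seed=0)
        assert est.bias == 0.0

    def test_added_noise_detected(self, symmetric_params):
        noisy = symmetric_params.replace(sigma2_a=50.0)
        ctrl = cd.generate_stimulus_session(2000, seed=81, motor_fraction=0.0)
        cd.simulate_session_choices(ctrl, symmetric_params, seed=82)
        pert = cd.generate_stimulus_session(2000, seed=83, motor_fraction=0.0)
        cd.simulate_session_choices(pert, noisy, seed=84)
        est = bilateral_impairment(pert, ctrl, seed=85)
        assert est.bias > 0
        assert est.p_value < 0.05

    def test_motor_control_trials_excluded(self, symmetric_params):
        sess = cd.generate_stimulus_session(600, seed=86, motor_fraction=0.3)
        cd.simulate_session_choices(sess, symmetric_params, seed=87)
        ctrl = copy.deepcopy(sess)
        # corrupt the motor trials only: result must be unaffected
        for t in ctrl.trials:
            if t.trial_type == "motor_control":
                t.choice = "L"
        est = bilateral_impairment(sess, ctrl, n_boot=50, seed=0)
        assert est.bias == 0.0


class TestEpochBias:
    def test_windowed_effect_isolated_to_stimulus_epochs(self, symmetric_params):
        sess = cd.generate_epoch_session(symmetric_params, 4000, epsilon=0.6,
                                         inactivated_side="L", seed=90)
        out = epoch_bias(sess, n_boot=300, seed=91)
        assert set(out) == {"pre", "first_half", "second_half", "post"}
        assert out["first_half"].bias > 0 and out["first_half"].p_value < 0.05
        assert out["second_half"].bias > 0 and out["second_half"].p_value < 0.05
        for ep in ("pre", "post"):
            assert out[ep].p_value > 0.05

    def test_missing_epoch_omitted_with_warning(self, symmetric_params, small_session):
        sess = copy.deepcopy(small_session)
        sess.inactivated_side = "none"
        with pytest.warns(UserWarning, match="epoch"):
            out = epoch_bias(sess, n_boot=20, seed=0)
        assert out == {}

    def test_paired_difference_of_identical_conditions(self, symmetric_params):
        a = cd.generate_stimulus_session(400, seed=92, motor_fraction=0.0, inactivated_side="L")
        cd.simulate_session_choices(a, symmetric_params, seed=93)
        c = cd.generate_stimulus_session(400, seed=94, motor_fraction=0.0)
        cd.simulate_session_choices(c, symmetric_params, seed=95)
        d = bias_difference((a, c), (copy.deepcopy(a), copy.deepcopy(c)), n_boot=100, seed=0)
        assert d.bias == pytest.approx(0.0, abs=1e-9)
        assert d.p_value > 0.5
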