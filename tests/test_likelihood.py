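"""Fokker-Planck propagation and trial likelihoods."""

import math

import numpy as np
import pytest

import clickddm as cd
from clickddm.likelihood import (
    GridConfig,
    choice_probability,
    gradient,
    log_likelihood,
    loglik_and_grad_internal,
    pack_sessions,
    propagate,
)

# grid whose bin width divides 1 click exactly (B=5, dx=0.2), so unit-click
# displacements of noise-free models land on bin centers
EXACT_GRID = GridConfig(dt=0.01, n_bins=49)


class TestPropagate:
    def test_noiseless_no_clicks_stays_delta(self, trial_factory):
        tr = trial_factory([], [], 0.5)
        d = propagate(tr, cd.ModelParams.ideal(bound_B=5.0), EXACT_GRID)
        d.check()
        assert d.mean == pytest.approx(0.0, abs=1e-12)
        assert d.var == pytest.approx(0.0, abs=1e-9)

    def test_single_click_unit_impulse(self, trial_factory):
        tr = trial_factory([], [0.25], 0.5)
        d = propagate(tr, cd.ModelParams.ideal(bound_B=5.0), EXACT_GRID)
        d.check()
        assert d.mean == pytest.approx(1.0, abs=1e-9)
        assert d.var == pytest.approx(0.0, abs=1e-9)
        assert d.mass[np.argmin(np.abs(d.grid - 1.0))] == pytest.approx(1.0, abs=1e-9)

    def test_mass_conserved_at_every_step(self, trial_factory, generic_params):
        tr = trial_factory([0.05, 0.3, 0.31], [0.1, 0.2, 0.4, 0.55], 0.6)
        _, rec = propagate(tr, generic_params, GridConfig(dt=0.01, n_bins=101),
                           return_evolution=True)
        sums = rec.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)
        # sticky bins only gain mass
        assert np.all(np.diff(rec[:, 0]) >= -1e-14)
        assert np.all(np.diff(rec[:, -1]) >= -1e-14)

    def test_ou_closed_forms_no_clicks(self, trial_factory):
        """No-click propagation matches the Ornstein-Uhlenbeck mean and
        variance closed forms to 1e-3 (relative)."""
        for lam in (-1.5, 0.0):
            tr = trial_factory([], [], 1.0)
            p = cd.ModelParams(lam=lam, sigma2_a=4.0, bound_B=10.0)
            d = propagate(tr, p, GridConfig(dt=0.01, n_bins=201))
            tvar = 4.0 * 1.0 if lam == 0 else 4.0 * (1 - math.exp(2 * lam)) / (-2 * lam)
            assert d.mean == pytest.approx(0.0, abs=1e-3)
            assert d.var == pytest.approx(tvar, rel=1e-3)

    def test_large_bound_reproduces_unbounded(self, trial_factory, symmetric_params):
        tr = trial_factory([0.1, 0.3], [0.2, 0.5], 0.6)  # |#R - #L| = 0 << B
        p = symmetric_params.replace(bound_B=25.0)
        d = propagate(tr, p, GridConfig(dt=0.01, n_bins=301))
        assert d.mass[0] + d.mass[-1] < 1e-6

    def test_grid_too_coarse_rejected(self, trial_factory, generic_params):
        with pytest.raises(ValueError, match="n_bins must be odd"):
            GridConfig(dt=0.01, n_bins=10)
        with pytest.raises(ValueError, match="too coarse"):
            GridConfig(dt=0.01, n_bins=17).validate_for(10.0)


class TestChoiceProbability:
    def test_full_symmetric_lapse_gives_half(self, trial_factory, generic_params):
        p = generic_params.replace(lapse_total=1.0, lapse_biased=0.0)
        for clicks in ([[0.1] * 6, []], [[], [0.05] * 9]):
            tr = trial_factory(clicks[0], clicks[1], 0.5)
            cp = choice_probability(tr, p, grid=EXACT_GRID)
            assert cp.p_right == pytest.approx(0.5, abs=1e-12)
            assert cp.p_right + cp.p_left == pytest.approx(1.0)

    def test_ideal_params_strong_trial(self, trial_factory):
        tr = trial_factory([0.4], [0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.45], 0.5)
        cp = choice_probability(tr, cd.ModelParams.ideal(bound_B=12.0),
                                grid=GridConfig(dt=0.01, n_bins=119))
        assert cp.p_right == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_lapse_mixing(self, trial_factory):
        """kappa_C=0.7, kappa_I=0.1 on a trial the model categorizes contra
        with certainty: p_contra = 1 - 0.7 = 0.3."""
        # inactivated side L => ipsi = left, contra = right; all-right trial
        tr = trial_factory([], [0.1, 0.2, 0.3], 0.5)
        p = cd.ModelParams.ideal(bound_B=5.0).replace(lapse_total=0.8, lapse_biased=0.6)
        cp = choice_probability(tr, p, side_mapping="L", grid=EXACT_GRID)
        assert cp.p_right == pytest.approx(0.3, abs=1e-9)

    def test_monotone_in_appended_right_clicks(self, trial_factory):
        p = cd.ModelParams.ideal(bound_B=8.0).replace(bias_thresh=0.3)
        grid = GridConfig(dt=0.01, n_bins=79)  # dx = 0.2
        prev = -1.0
        for n_right in range(6):
            tr = trial_factory([0.1, 0.2, 0.3], [0.5 + 0.01 * k for k in range(n_right)], 0.6)
            cp = choice_probability(tr, p, grid=grid)
            assert cp.p_right >= prev - 1e-12
            prev = cp.p_right


class TestLogLikelihood:
    def test_single_coin_flip_trial(self, trial_factory):
        tr = trial_factory([], [0.1] * 4, 0.5)
        tr.choice = "R"
        sess = cd.Session(trials=[tr])
        p = cd.ModelParams.ideal(bound_B=5.0).replace(lapse_total=1.0)
        assert log_likelihood(sess, p, EXACT_GRID) == pytest.approx(-math.log(2.0))

    def test_additivity_over_trials(self, small_session, generic_params, fast_grid):
        total = log_likelihood(small_session, generic_params, fast_grid)
        per_trial = sum(
            choice_probability(t, generic_params, grid=fast_grid).log_lik_choice
            for t in small_session.trials
        )
        assert total == pytest.approx(per_trial, rel=1e-12)

    def test_sessions_concatenate(self, small_session, generic_params, fast_grid):
        half1 = cd.Session(trials=small_session.trials[:30])
        half2 = cd.Session(trials=small_session.trials[30:])
        assert log_likelihood([half1, half2], generic_params, fast_grid) == pytest.approx(
            log_likelihood(small_session, generic_params, fast_grid)
        )

    def test_zero_probability_trial_gives_minus_inf(self, trial_factory):
        tr = trial_factory([0.1, 0.2, 0.3], [], 0.5)
        tr.choice = "R"  # impossible under a noise-free, lapse-free model
        sess = cd.Session(trials=[tr])
        with pytest.warns(UserWarning, match="zero probability"):
            ll = log_likelihood(sess, cd.ModelParams.ideal(bound_B=5.0), EXACT_GRID)
        assert ll == -np.inf

    def test_matches_monte_carlo_product(self, symmetric_params, fast_grid):
        sess = cd.generate_stimulus_session(30, seed=21, motor_fraction=0.0)
        cd.simulate_session_choices(sess, symmetric_params, seed=22)
        ll = log_likelihood(sess, symmetric_params, fast_grid)
        mc_ll = 0.0
        for i, tr in enumerate(sess.trials):
            a, _ = cd.simulate_a_end(tr, symmetric_params, 40_000, dt=0.004, seed=1000 + i)
            pr = np.mean(a > symmetric_params.bias_thresh)
            k = symmetric_params.lapse_total / 2
            pr = k + (1 - 2 * k) * pr
            mc_ll += math.log(pr if tr.choice == "R" else 1 - pr)
        assert ll == pytest.approx(mc_ll, abs=0.15 * math.sqrt(len(sess)))


class TestGradient:
    def test_matches_finite_differences(self, fast_grid):
        """All 11 partials agree with central finite differences (step 1e-5
        in the unbounded coordinates) to 1e-4 relative error."""
        # thresh/dx deliberately away from bin edges: exactly on an edge the
        # discretized p(thresh) has a kink where central differences average
        # the two one-sided slopes
        p = cd.ModelParams(lam=-0.4, sigma2_a=2.5, sigma2_s_ipsi=0.6, sigma2_s_contra=1.1,
                           bound_B=6.17, phi=0.35, tau_phi=0.08, bias_thresh=0.273,
                           lapse_total=0.2, lapse_biased=-0.04, input_gain=0.55)
        sess = cd.generate_stimulus_session(40, seed=31, motor_fraction=0.0, inactivated_side="R")
        cd.simulate_session_choices(sess, p, seed=32)
        packed = pack_sessions(sess, fast_grid)
        tfm = cd.ParamTransform()
        alpha = tfm.to_unbounded(p)

        def f(a):
            ll, _ = loglik_and_grad_internal(packed, tfm.forward(a), want_grad=False)
            return ll

        _, g = loglik_and_grad_internal(packed, tfm.forward(alpha), want_grad=True)
        g_alpha = g * tfm.jac(alpha)
        h = 1e-5
        for j in range(11):
            ap = alpha.copy(); ap[j] += h
            am = alpha.copy(); am[j] -= h
            fd = (f(ap) - f(am)) / (2 * h)
            assert g_alpha[j] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_symmetry_zeroes_asymmetric_partials(self, trial_factory, fast_grid):
        """Mirror-image trial pairs with mirrored choices: the partials
        w.r.t. the threshold and the biased lapse vanish at thresh=0."""
        p = cd.ModelParams.symmetric(lam=-0.3, sigma2_a=1.5, sigma2_s=0.8,
                                     bound_B=6.0, phi=0.6, tau_phi=0.1, lapse=0.2)
        left, right = [0.1, 0.32], [0.2, 0.4, 0.52]
        t1 = trial_factory(left, right, 0.6); t1.choice = "R"
        t2 = trial_factory(right, left, 0.6); t2.choice = "L"
        g = gradient(cd.Session(trials=[t1, t2]), p, fast_grid)
        assert g[7] == pytest.approx(0.0, abs=1e-8)   # bias_thresh
        assert g[9] == pytest.approx(0.0, abs=1e-10)  # lapse_biased

    def test_boundary_parameters_rejected(self, small_session, fast_grid):
        p = cd.ModelParams.symmetric(sigma2_a=1.0, bound_B=6.0, lapse=0.2)  # sigma2_s = 0
        with pytest.raises(ValueError, match="unbounded"):
            gradient(small_session, p, fast_grid)


def test_alternative_click_noise_scaling_consistent_with_oracle(trial_factory):
    """Under the variance-scales-with-amplitude reading, the propagated
    choice probability still matches Monte Carlo sampling built on the
    same convention."""
    import clickddm.likelihood as lk
    from clickddm.accumulator import click_kernel_moments
    from clickddm import _core

    p = cd.ModelParams.symmetric(lam=-0.3, sigma2_a=1.0, sigma2_s=0.8,
                                 bound_B=6.0, phi=0.4, tau_phi=0.06)
    tr = trial_factory([0.05, 0.3, 0.31], [0.1, 0.2, 0.33, 0.5], 0.6)
    old = lk.CLICK_NOISE_VARIANCE_MODE
    try:
        lk.CLICK_NOISE_VARIANCE_MODE = 1
        cp = lk.choice_probability(tr, p, grid=lk.GridConfig(dt=0.005, n_bins=121))
    finally:
        lk.CLICK_NOISE_VARIANCE_MODE = old
    t, mean, sd = click_kernel_moments(tr, p, variance_scales_with_C=True)
    a_end = np.empty(60_000)
    hit = np.empty(60_000, dtype=np.bool_)
    _core.sim_a_end(60_000, tr.duration, 0.002, p.lam, np.sqrt(p.sigma2_a), p.bound_B,
                    t, mean, sd, 0.0, 9, a_end, hit)
    p_mc = np.mean(a_end > p.bias_thresh)
    assert cp.p_right == pytest.approx(p_mc, abs=0.012)
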