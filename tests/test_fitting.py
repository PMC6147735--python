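"""Unbounded reparameterization, Laplace intervals, ridges, BIC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clickddm as cd
from clickddm.fitting import (
    FitResult,
    ParamTransform,
    bic_compare,
    fit_mle,
    laplace_ci,
    likelihood_landscape,
    tradeoff_ridge,
)
from clickddm.likelihood import GridConfig
from clickddm.params import DEFAULT_BOUNDS, INTERNAL_ORDER


class TestParamTransform:
    def test_midpoint_maps_to_zero(self):
        t = ParamTransform()
        mid = 0.5 * (t.lo + t.hi)
        np.testing.assert_allclose(t.inverse(mid), 0.0, atol=1e-12)
        np.testing.assert_allclose(t.forward(np.zeros(11)), mid, rtol=1e-14)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip(self, seed):
        t = ParamTransform()
        rng = np.random.default_rng(seed)
        # uniform draws strictly inside the bounds
        u = rng.uniform(0.01, 0.99, 11)
        theta = t.lo + (t.hi - t.lo) * u
        back = t.forward(t.inverse(theta))
        assert np.max(np.abs(theta - back)) < 1e-12

    def test_saturation_stays_within_bounds(self):
        t = ParamTransform()
        for big in (1e6, -1e6):
            theta = t.forward(np.full(11, big))
            assert np.all(theta >= t.lo) and np.all(theta <= t.hi)
            edge = t.hi if big > 0 else t.lo
            np.testing.assert_allclose(theta, edge, atol=1e-9)

    def test_boundary_value_rejected_by_name(self):
        t = ParamTransform()
        theta = 0.5 * (t.lo + t.hi)
        theta[INTERNAL_ORDER.index("sigma2_a")] = 0.0
        with pytest.raises(ValueError, match="sigma2_a"):
            t.inverse(theta)


class _Identity:
    """Identity coordinate map (quadratic-toy fits live in unbounded space)."""

    def forward(self, alpha):
        return np.asarray(alpha, dtype=float)

    def jac(self, alpha):
        return np.ones_like(np.asarray(alpha, dtype=float))


def _toy_fit(variances, level_names=None):
    """A FitResult whose Hessian is diagonal 1/variances (quadratic toy)."""
    n = len(variances)
    names = tuple(INTERNAL_ORDER[:n]) if level_names is None else level_names
    H = np.diag(1.0 / np.asarray(variances, dtype=float))
    t = _Identity()
    return FitResult(
        params=cd.ModelParams(),
        loglik=0.0,
        alpha_hat=np.zeros(n),
        free_names=names,
        transform=t,
        hessian=H,
        covariance=np.linalg.inv(H),
        ci95={},
        restarts=[],
        n_trials=100,
        n_free=n,
        fixed={},
    )


class TestLaplaceCI:
    def test_quadratic_toy_half_width(self):
        """-0.5 * sum(a_i^2 / v_i) has exact 95% half-width 1.96 sqrt(v_i)."""
        v = [4.0, 0.25]
        fit = _toy_fit(v, level_names=("lam", "sigma2_a"))
        cis, null = laplace_ci(fit, level=0.95)
        assert null == []
        z = 1.959963984540054
        for (name, (lo, hi)), vi in zip(cis.items(), v):
            assert hi - lo == pytest.approx(2 * z * math.sqrt(vi), rel=1e-6)

    def test_singular_hessian_reports_null_direction(self):
        fit = _toy_fit([1.0, 1.0], level_names=("lam", "sigma2_a"))
        fit.hessian = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank 1
        cis, null = laplace_ci(fit)
        assert cis is None and len(null) == 1
        np.testing.assert_allclose(np.abs(null[0]), [1, 1] / np.sqrt(2), atol=1e-9)

    def test_variance_pinned_at_zero_has_zero_lower_bound(self, small_session, fast_grid):
        """Data generated without accumulator noise: the fitted sigma2_a
        hugs 0 and its mapped CI lower bound is (numerically) 0."""
        p0 = cd.ModelParams.symmetric(sigma2_s=1.0, bound_B=7.0, lapse=0.2)  # sigma2_a = 0
        sess = cd.generate_stimulus_session(400, seed=41, motor_fraction=0.0)
        cd.simulate_session_choices(sess, p0, seed=42)
        fit = fit_mle(sess, n_restarts=1, seed=1, grid=fast_grid,
                      fixed={"lam": 0.0, "bound_B": 7.0, "phi": 1.0, "tau_phi": 0.05,
                             "bias_thresh": 0.0, "input_gain": 0.5},
                      ties={"kappa_I": "kappa_C", "sigma2_s_contra": "sigma2_s_ipsi"},
                      init_params=p0.replace(sigma2_a=1.0, sigma2_s_ipsi=0.8, sigma2_s_contra=0.8))
        lo, hi = fit.ci95["sigma2_a"]
        assert fit.params.sigma2_a < 0.5
        assert lo == pytest.approx(0.0, abs=1e-3)


class TestTradeoffRidge:
    def test_diagonal_covariance_picks_largest_axis(self):
        fit = _toy_fit([4.0, 1.0, 0.5], level_names=("sigma2_a", "sigma2_s_ipsi", "lam"))
        ridge = tradeoff_ridge(fit)
        assert ridge.eigenvalue == pytest.approx(4.0, rel=1e-6)
        np.testing.assert_allclose(np.abs(ridge.eigenvector), [1, 0, 0], atol=1e-8)
        w1, w2 = ridge.noise_weights
        assert (w1, w2) == pytest.approx((1.0, 0.0), abs=1e-8)

    def test_correlated_pair_ridge_along_diagonal(self):
        fit = _toy_fit([1.0, 1.0], level_names=("sigma2_a", "sigma2_s_ipsi"))
        rho = 0.99
        fit.covariance = np.array([[1.0, rho], [rho, 1.0]])
        fit.hessian = np.linalg.inv(fit.covariance)
        ridge = tradeoff_ridge(fit)
        ang = math.degrees(math.acos(abs(ridge.eigenvector @ ([1, 1] / np.sqrt(2)))))
        assert ang < 2.0
        assert ridge.eigenvalue == pytest.approx(1 + rho, rel=1e-9)

    def test_degenerate_leading_eigenvalue_flagged(self):
        fit = _toy_fit([2.0, 2.0], level_names=("lam", "sigma2_a"))
        ridge = tradeoff_ridge(fit)
        assert ridge.degenerate and ridge.basis is not None


class TestBIC:
    def test_equal_loglik_fewer_params_wins(self):
        f10 = _toy_fit([1.0] * 10, level_names=tuple(INTERNAL_ORDER[:10]))
        f11 = _toy_fit([1.0] * 11, level_names=INTERNAL_ORDER)
        f10.loglik = f11.loglik = -500.0
        df = bic_compare([f10, f11], labels=["k10", "k11"])
        assert df.loc[df.model == "k10", "winner"].item()
        assert df.loc[df.model == "k11", "bic"].item() - df.loc[df.model == "k10", "bic"].item() == pytest.approx(
            math.log(100)
        )

    def test_mismatched_trial_sets_rejected(self):
        a = _toy_fit([1.0])
        b = _toy_fit([1.0])
        b.n_trials = 99
        with pytest.raises(ValueError):
            bic_compare([a, b])


class TestFitMLE:
    @pytest.fixture(scope="class")
    def quick_fit(self, fast_grid):
        p = cd.ModelParams.symmetric(lam=-0.3, sigma2_a=2.0, sigma2_s=1.0, bound_B=7.0,
                                     phi=0.5, tau_phi=0.08, lapse=0.2)
        sess = cd.generate_stimulus_session(600, seed=51, motor_fraction=0.0)
        cd.simulate_session_choices(sess, p, seed=52)
        grid = GridConfig(dt=0.025, n_bins=31)
        fit = fit_mle(sess, n_restarts=2, seed=2, grid=grid, init_params="staged",
                      hessian_mode="forward")
        return p, sess, grid, fit

    def test_loglik_at_optimum_beats_truth(self, quick_fit):
        p, sess, grid, fit = quick_fit
        assert fit.loglik >= cd.log_likelihood(sess, p, grid) - 1e-6

    def test_hessian_psd_and_restart_diagnostics(self, quick_fit):
        _, _, _, fit = quick_fit
        ev = np.linalg.eigvalsh(fit.hessian)
        assert ev.min() >= 0
        assert any(r.within_final_region for r in fit.restarts)
        assert fit.loglik == max(r.loglik for r in fit.restarts if np.isfinite(r.loglik))

    def test_stationarity_at_accepted_optimum(self, quick_fit):
        """The projected gradient at the accepted optimum is small relative
        to the curvature scale (optimizer tolerance)."""
        p, sess, grid, fit = quick_fit
        from clickddm.likelihood import loglik_and_grad_internal, pack_sessions
        packed = pack_sessions(sess, grid)
        alpha = np.zeros(11)
        idx = [INTERNAL_ORDER.index(n) for n in fit.free_names]
        alpha[idx] = fit.alpha_hat
        ll0, g = loglik_and_grad_internal(packed, fit.transform.forward(alpha), want_grad=True)
        g_alpha = (g * fit.transform.jac(alpha))[idx]
        # kinks from the grid discretization leave a small residual gradient;
        # it must be at the line-search resolution, far below the data scale
        assert np.abs(g_alpha).max() < 5.0
        # and no uphill move of modest size exists along the gradient
        a2 = alpha.copy()
        a2[idx] += 0.01 * g_alpha / max(np.abs(g_alpha).max(), 1e-9)
        ll1, _ = loglik_and_grad_internal(packed, fit.transform.forward(a2), want_grad=False)
        assert ll1 <= ll0 + 0.05

    def test_landscape_contains_optimum_and_unit_mass(self, quick_fit):
        p, sess, grid, fit = quick_fit
        s2a_hat = fit.params.sigma2_a
        s2s_hat = fit.params.sigma2_s_ipsi
        ls = likelihood_landscape(
            sess, fit, ("sigma2_a", "sigma2_s_ipsi"),
            (max(0.05, s2a_hat / 3), s2a_hat * 3 + 1),
            (max(0.05, s2s_hat / 3), s2s_hat * 3 + 1),
            n=9, grid=grid,
        )
        assert ls.normalized_mass.sum() == pytest.approx(1.0, abs=1e-9)
        jy, jx = np.unravel_index(ls.normalized_mass.argmax(), ls.normalized_mass.shape)
        # the argmax cell is the one nearest the fitted optimum
        assert abs(ls.x[jx] - s2a_hat) <= (ls.x[1] - ls.x[0]) + 1e-9
        assert abs(ls.y[jy] - s2s_hat) <= (ls.y[1] - ls.y[0]) + 1e-9
        assert ls.mass_contours[0.5] >= ls.mass_contours[0.95]
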