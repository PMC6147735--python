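"""Maximum-likelihood fitting of the accumulator model.

All 11 parameters are fitted simultaneously.  Bounded parameters are
mapped to an unbounded space through a per-parameter tanh bijection,

    theta = lo + (hi - lo) * (1 + tanh(alpha)) / 2,

and optimization runs in the unbounded coordinates (gradient-based, with
the forward-mode likelihood gradient), which keeps the Hessian at the
optimum positive semidefinite even when a parameter's best value sits at a
range boundary (e.g. a noise variance at 0).  Fits are restarted from
several random seeds; the restart with the highest log-likelihood and a
PSD Hessian defines the optimum.  Under a flat prior the normalized
likelihood approximates the parameter posterior; its Laplace (Gaussian)
approximation -- covariance = inverse Hessian of the negative
log-likelihood -- yields confidence intervals (mapped back through the
tanh bijection, hence asymmetric and respecting the bounds) and
parameter trade-off ridges: the eigenvector of the covariance with the
largest eigenvalue describes the direction along which parameters can
trade off against each other with little likelihood cost.

Model comparison uses BIC = k ln(n) - 2 LL.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import DEFAULT_GRID, GridConfig, loglik_and_grad_internal, pack_sessions
from .params import DEFAULT_BOUNDS, INTERNAL_ORDER, ModelParams

__all__ = [
    "ParamTransform",
    "FitResult",
    "RestartRecord",
    "TradeoffRidge",
    "LikelihoodLandscape",
    "fit_mle",
    "laplace_ci",
    "likelihood_landscape",
    "tradeoff_ridge",
    "bic_compare",
]


@dataclass(frozen=True)
class ParamTransform:
    """Per-parameter tanh bijection between bounded and unbounded space."""

    names: tuple = INTERNAL_ORDER
    lo: np.ndarray = field(default_factory=lambda: np.array([DEFAULT_BOUNDS[n][0] for n in INTERNAL_ORDER]))
    hi: np.ndarray = field(default_factory=lambda: np.array([DEFAULT_BOUNDS[n][1] for n in INTERNAL_ORDER]))

    def forward(self, alpha: np.ndarray) -> np.ndarray:
        """Unbounded -> bounded; f(0) is the bound midpoint."""
        return self.lo + (self.hi - self.lo) * 0.5 * (1.0 + np.tanh(alpha))

    def inverse(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        z = 2.0 * (theta - self.lo) / (self.hi - self.lo) - 1.0
        if np.any(z <= -1.0) or np.any(z >= 1.0):
            bad = [self.names[i] for i in np.flatnonzero((z <= -1.0) | (z >= 1.0))]
            raise ValueError(f"parameter(s) {bad} on or outside the transform bounds")
        return np.arctanh(z)

    def jac(self, alpha: np.ndarray) -> np.ndarray:
        """d theta / d alpha (diagonal)."""
        return (self.hi - self.lo) * 0.5 / np.cosh(alpha) ** 2

    def to_unbounded(self, params: ModelParams) -> np.ndarray:
        return self.inverse(params.internal_vector())

    def from_unbounded(self, alpha: np.ndarray) -> ModelParams:
        return ModelParams.from_internal_vector(self.forward(np.asarray(alpha, dtype=float)))


@dataclass
class RestartRecord:
    seed_index: int
    loglik: float
    converged: bool
    alpha: np.ndarray
    within_final_region: bool | None = None


@dataclass
class FitResult:
    params: ModelParams
    loglik: float
    alpha_hat: np.ndarray  # unbounded coordinates of the free parameters
    free_names: tuple
    transform: ParamTransform
    hessian: np.ndarray  # of -LL, unbounded free coordinates
    covariance: np.ndarray
    ci95: dict  # name -> (lo, hi) in bounded coordinates
    restarts: list
    n_trials: int
    n_free: int
    fixed: dict
    success: bool = True

    def bic(self) -> float:
        return self.n_free * math.log(self.n_trials) - 2.0 * self.loglik


#: Restart seeds are drawn uniformly (in unbounded coordinates) from the
#: image of these plausible parameter ranges -- a configured box well inside
#: the transform bounds, covering the regimes 40 Hz click data can produce.
RESTART_RANGES = {
    "lam": (-3.0, 3.0),
    "sigma2_a": (0.5, 30.0),
    "sigma2_s_ipsi": (0.05, 5.0),
    "sigma2_s_contra": (0.05, 5.0),
    "bound_B": (2.0, 20.0),
    "phi": (0.1, 1.2),
    "tau_phi": (0.02, 0.5),
    "bias_thresh": (-1.0, 1.0),
    "kappa_C": (0.02, 0.5),
    "kappa_I": (0.02, 0.5),
    "input_gain": (0.2, 0.8),
}


def _subsample_sessions(sessions, max_n: int):
    """Deterministic strided subsample of trials (used by the cheap
    symmetric initialization stage)."""
    from .stimuli import Session

    if isinstance(sessions, Session):
        sessions = [sessions]
    total = sum(len(s.trials) for s in sessions)
    if total <= max_n:
        return sessions
    stride = int(np.ceil(total / max_n))
    out = []
    for s in sessions:
        sub = Session.__new__(Session)
        sub.trials = s.trials[::stride]
        sub.subject_id = s.subject_id
        sub.inactivated_side = s.inactivated_side
        sub.session_role = s.session_role
        out.append(sub)
    return out


class FitFailure(RuntimeError):
    """No restart converged with a PSD Hessian; carries the restart table."""

    def __init__(self, restarts):
        super().__init__("no restart converged with a positive semidefinite Hessian")
        self.restarts = restarts


def _fd_hessian(fun_grad, x, h=0.05, mode="central"):
    """Finite differences of the analytic gradient (symmetrized).

    The default step is deliberately large: it averages over the
    micro-kinks that grid discretization leaves in the likelihood surface,
    and stays far below the curvature scale of the peak.
    """
    n = x.size
    H = np.empty((n, n))
    if mode == "forward":
        _, g0 = fun_grad(x)
        for j in range(n):
            xp = x.copy()
            xp[j] += h
            _, gp = fun_grad(xp)
            H[:, j] = (gp - g0) / h
    else:
        for j in range(n):
            xp = x.copy()
            xp[j] += h
            _, gp = fun_grad(xp)
            xm = x.copy()
            xm[j] -= h
            _, gm = fun_grad(xm)
            H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _polish_to_maximum(obj, alpha, h, mode, minimize_opts, max_rounds=2):
    """Verify a candidate optimum; escape saddles if needed.

    The FD Hessian of the negative log-likelihood must be PSD at a maximum.
    Tiny negative eigenvalues -- FD noise in sloppy, nearly flat directions
    -- are clipped to a positive floor (mapping to very wide intervals
    there).  A clearly negative eigenvalue means the optimizer stalled on a
    saddle or ridge: step along the negative-curvature eigenvector (both
    signs, a few step sizes) and re-run the optimizer from the best point.

    Returns (alpha, loglik, psd_hessian) or (alpha, loglik, None).
    """
    f0, _ = obj(alpha)
    for _round in range(max_rounds):
        Hk = _fd_hessian(obj, alpha, h=h, mode=mode)
        ev, evec = np.linalg.eigh(Hk)
        top = max(abs(ev.max()), 1e-12)
        if mode == "forward":
            # forward differences are noisy exactly where it matters most:
            # along sloppy directions, where an error either flips the sign
            # (wrecking the PSD check) or misstates a wide interval.  Refine
            # each suspicious eigenvalue with a targeted central difference
            # of the gradient along its eigenvector (2 evaluations each).
            for j in np.flatnonzero(ev < 3e-2 * top):
                vj = evec[:, j]
                _, gp = obj(alpha + h * vj)
                _, gm = obj(alpha - h * vj)
                lam_ref = float(vj @ (gp - gm)) / (2.0 * h)
                Hk = Hk + (lam_ref - ev[j]) * np.outer(vj, vj)
            ev, evec = np.linalg.eigh(Hk)
            top = max(abs(ev.max()), 1e-12)
        if ev.min() >= -1e-3 * top:
            evc = np.clip(ev, 1e-9 * top, None)
            return alpha, -f0, (evec * evc) @ evec.T
        v = evec[:, int(ev.argmin())]
        best = (f0, alpha)
        for s in (0.05, 0.15, 0.4):
            for sgn in (1.0, -1.0):
                cand = alpha + sgn * s * v
                fc, _ = obj(cand)
                if fc < best[0]:
                    best = (fc, cand)
        if best[0] >= f0 - 1e-12:
            # no descent along the "negative" direction: the point is a local
            # maximum at practical scales, so the eigenvalue is FD noise from
            # surface kinks; re-estimate with a doubled step and accept
            if ev.min() < -1e-2 * top:
                Hk = _fd_hessian(obj, alpha, h=2.0 * h, mode="central")
                ev, evec = np.linalg.eigh(Hk)
                top = max(abs(ev.max()), 1e-12)
            if ev.min() >= -3e-2 * top:
                evc = np.clip(ev, 1e-9 * top, None)
                return alpha, -f0, (evec * evc) @ evec.T
            return alpha, -f0, None
        opts = dict(minimize_opts)
        opts["maxiter"] = min(40, opts.get("maxiter", 40))
        res = optimize.minimize(obj, best[1], jac=True, method="L-BFGS-B", options=opts)
        if res.fun >= f0 - 1e-12:
            return alpha, -f0, None
        alpha, f0 = res.x, float(res.fun)
    return alpha, -f0, None


def fit_mle(
    sessions,
    transform: ParamTransform | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    grid: GridConfig = DEFAULT_GRID,
    fixed: dict | None = None,
    tie_sensory_noise: bool = False,
    ties: dict | None = None,
    restart_ranges: dict | None = None,
    maxiter: int = 300,
    gtol: float = 1e-2,
    ftol: float = 1e-9,
    hessian_step: float = 0.05,
    hessian_mode: str = "central",
    compute_hessian: bool = True,
    init_params=None,
) -> FitResult:
    """Simultaneous MLE of the accumulator parameters.

    Parameters
    ----------
    fixed : dict, optional
        Internal-coordinate names pinned to given values (e.g.
        ``{"bound_B": 30.0}`` for the bound-free reduced model, or the
        symmetric-model constraints).  Fixed parameters do not count
        toward the BIC complexity ``k``.
    tie_sensory_noise : bool
        Fit a single sensory-noise variance for both sides (symmetric
        sigma2_s); the contralateral variance follows the ipsilateral one.
    restart_ranges : dict, optional
        Per-parameter (lo, hi) ranges whose unbounded image defines the
        restart box (default :data:`RESTART_RANGES`).
    ties : dict, optional
        Internal-coordinate equality constraints target -> source (the
        target parameter follows the source and is not free).
    init_params : ModelParams or "staged", optional
        Start restart 0 from these parameters instead of a random draw.
        ``"staged"`` first fits the left/right-symmetric reduced model
        (tied sensory noise and lapse, balanced gain) from a fixed neutral
        start and uses its solution -- a cheap, deterministic way to land
        the full fit in the global basin before the asymmetry parameters
        are released.
    """
    transform = transform or ParamTransform()
    fixed = dict(fixed or {})
    packed = pack_sessions(sessions, grid)
    if packed.n_trials == 0:
        raise ValueError("no accumulation trials with observed choices")
    name_to_idx = {n: i for i, n in enumerate(INTERNAL_ORDER)}
    fixed_vec = np.full(11, np.nan)
    fixed_idx = []
    for name, val in fixed.items():
        i = name_to_idx[name]
        fixed_vec[i] = float(val)
        fixed_idx.append(i)
    tie_pairs = []
    if tie_sensory_noise:
        tie_pairs.append((name_to_idx["sigma2_s_contra"], name_to_idx["sigma2_s_ipsi"]))
    for tgt, src in (ties or {}).items():
        tie_pairs.append((name_to_idx[tgt], name_to_idx[src]))
    free_idx = np.array(
        [i for i in range(11) if i not in fixed_idx and i not in [t for t, _ in tie_pairs]],
        dtype=int,
    )
    nfree = free_idx.size

    def negll_and_grad(alpha_free):
        # resolve ties by construction: build full theta with tied values
        alpha = np.zeros(11)
        theta = fixed_vec.copy()
        alpha[free_idx] = alpha_free
        th_full = transform.forward(alpha)
        theta[free_idx] = th_full[free_idx]
        for tgt, src in tie_pairs:
            theta[tgt] = theta[src]
        ll, g = loglik_and_grad_internal(packed, theta, want_grad=True, floor=1e-12)
        if not np.isfinite(ll):
            return 1e30, np.zeros(nfree)
        for tgt, src in tie_pairs:
            g[src] += g[tgt]
        jac = transform.jac(alpha)
        return -ll, -(g * jac)[free_idx]

    obj = negll_and_grad

    rr = {**RESTART_RANGES, **(restart_ranges or {})}
    alo = np.empty(nfree)
    ahi = np.empty(nfree)
    for j, i in enumerate(free_idx):
        name = INTERNAL_ORDER[i]
        lo_b, hi_b = transform.lo[i], transform.hi[i]
        a0_, a1_ = (
            math.atanh(2.0 * (v - lo_b) / (hi_b - lo_b) - 1.0) for v in rr[name]
        )
        alo[j], ahi[j] = min(a0_, a1_), max(a0_, a1_)

    if isinstance(init_params, str) and init_params == "staged":
        sym = fit_mle(
            _subsample_sessions(sessions, 2000),
            transform=transform,
            n_restarts=1,
            seed=seed,
            grid=grid,
            fixed={**fixed, "input_gain": 0.5},
            ties={"sigma2_s_contra": "sigma2_s_ipsi", "kappa_I": "kappa_C", **(ties or {})},
            restart_ranges=restart_ranges,
            maxiter=maxiter,
            gtol=gtol,
            ftol=ftol,
            compute_hessian=False,
            init_params=ModelParams.symmetric(
                lam=0.0, sigma2_a=4.0, sigma2_s=1.0, bound_B=8.0,
                phi=0.5, tau_phi=0.1, bias_thresh=0.0, lapse=0.2,
            ),
        )
        init_params = sym.params
    a_init = None
    if init_params is not None:
        th0 = np.clip(init_params.internal_vector(), transform.lo + 1e-9, transform.hi - 1e-9)
        a_init = transform.inverse(th0)[free_idx]

    rng = np.random.default_rng(seed)
    restarts: list[RestartRecord] = []
    for r in range(n_restarts):
        a0 = a_init if (r == 0 and a_init is not None) else rng.uniform(alo, ahi)
        res = optimize.minimize(
            obj,
            a0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol, "maxcor": 20},
        )
        restarts.append(
            RestartRecord(seed_index=r, loglik=-float(res.fun), converged=bool(res.success), alpha=res.x)
        )

    order = np.argsort([-r.loglik for r in restarts])
    best = None
    H = None
    if not compute_hessian:
        for k in order:
            if np.isfinite(restarts[k].loglik):
                best = restarts[k]
                break
        if best is None:
            raise FitFailure(restarts)
        H = np.eye(nfree)
        cov = np.eye(nfree)
    else:
        opts = {"maxiter": maxiter, "gtol": gtol, "ftol": ftol, "maxcor": 20}
        for k in order:
            rec = restarts[k]
            if not np.isfinite(rec.loglik):
                continue
            a_pol, ll_pol, Hk = _polish_to_maximum(
                obj, rec.alpha, hessian_step, hessian_mode, opts
            )
            rec.alpha, rec.loglik = a_pol, ll_pol
            if Hk is not None:
                best, H = rec, Hk
                break
        if best is None:
            raise FitFailure(restarts)
        # covariance: pseudo-inverse to tolerate flat (unidentified) directions
        cov = np.linalg.pinv(H, rcond=1e-10, hermitian=True)
    alpha_hat = np.zeros(11)
    theta = fixed_vec.copy()
    alpha_hat[free_idx] = best.alpha
    th_full = transform.forward(alpha_hat)
    theta[free_idx] = th_full[free_idx]
    for tgt, src in tie_pairs:
        theta[tgt] = theta[src]
    params_hat = ModelParams.from_internal_vector(theta)

    free_names = tuple(INTERNAL_ORDER[i] for i in free_idx)
    ci95 = _intervals(best.alpha, cov, transform, free_idx, level=0.95)
    for name, val in fixed.items():
        ci95[name] = (float(val), float(val))
    for tgt, src in tie_pairs:
        ci95[INTERNAL_ORDER[tgt]] = ci95[INTERNAL_ORDER[src]]

    # restart diagnostic: endpoint inside the final 95% confidence region?
    thr = stats.chi2.ppf(0.95, df=nfree)
    for rec in restarts:
        d = rec.alpha - best.alpha
        rec.within_final_region = bool(d @ H @ d <= thr)

    return FitResult(
        params=params_hat,
        loglik=best.loglik,
        alpha_hat=best.alpha.copy(),
        free_names=free_names,
        transform=transform,
        hessian=H,
        covariance=cov,
        ci95=ci95,
        restarts=restarts,
        n_trials=packed.n_trials,
        n_free=nfree,
        fixed=fixed,
    )


def _intervals(alpha, cov, transform, free_idx, level):
    z = stats.norm.ppf(0.5 * (1.0 + level))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    out = {}
    for j, i in enumerate(free_idx):
        a = np.zeros(11)
        lo_a = alpha[j] - z * se[j]
        hi_a = alpha[j] + z * se[j]
        a[i] = lo_a
        lo_t = transform.forward(a)[i]
        a[i] = hi_a
        hi_t = transform.forward(a)[i]
        out[INTERNAL_ORDER[i]] = (float(lo_t), float(hi_t))
    return out


def laplace_ci(fit: FitResult, level: float = 0.95):
    """Gaussian (Laplace) confidence intervals in unbounded coordinates,
    mapped through the tanh bijection to bounded coordinates.

    A singular Hessian yields no intervals; the null direction(s) are
    reported instead as ``(None, null_directions)``.
    """
    ev, evec = np.linalg.eigh(fit.hessian)
    tol = 1e-10 * max(1.0, abs(ev.max()))
    null = [evec[:, j] for j in np.flatnonzero(np.abs(ev) <= tol)]
    if null:
        return None, null
    cov = np.linalg.inv(fit.hessian)
    free_idx = np.array([INTERNAL_ORDER.index(n) for n in fit.free_names])
    return _intervals(fit.alpha_hat, cov, fit.transform, free_idx, level), []


@dataclass
class TradeoffRidge:
    eigenvector: np.ndarray  # unit norm, bounded coordinates of the free params
    eigenvalue: float
    noise_weights: tuple  # (w1, w2) loading on sigma2_a and sigma2_s
    names: tuple
    degenerate: bool = False
    basis: np.ndarray | None = None


def tradeoff_ridge(fit: FitResult) -> TradeoffRidge:
    """Leading eigen-pair of the parameter covariance (ridge of the
    likelihood peak), in bounded coordinates.

    ``noise_weights`` are the eigenvector components on sigma2_a and the
    (ipsilateral) sigma2_s, renormalized to unit norm over that pair: they
    define the reported weighted noise combination w1*sigma2_a + w2*sigma2_s.
    """
    J = fit.transform.jac(_full_alpha(fit))[_free_idx(fit)]
    C = J[:, None] * fit.covariance * J[None, :]
    ev, evec = np.linalg.eigh(C)
    lead = ev[-1]
    degenerate = ev.size > 1 and (lead - ev[-2]) <= 1e-8 * max(lead, 1e-300)
    vec = evec[:, -1]
    if vec.sum() < 0:
        vec = -vec
    w = np.zeros(2)
    for k, nm in enumerate(("sigma2_a", "sigma2_s_ipsi")):
        if nm in fit.free_names:
            w[k] = vec[fit.free_names.index(nm)]
    nrm = np.hypot(w[0], w[1])
    weights = (float(abs(w[0]) / nrm), float(abs(w[1]) / nrm)) if nrm > 0 else (float("nan"), float("nan"))
    return TradeoffRidge(
        eigenvector=vec,
        eigenvalue=float(lead),
        noise_weights=weights,
        names=fit.free_names,
        degenerate=bool(degenerate),
        basis=evec[:, ev >= lead - 1e-8 * max(lead, 1e-300)] if degenerate else None,
    )


def _free_idx(fit: FitResult) -> np.ndarray:
    return np.array([INTERNAL_ORDER.index(n) for n in fit.free_names])


def _full_alpha(fit: FitResult) -> np.ndarray:
    a = np.zeros(11)
    a[_free_idx(fit)] = fit.alpha_hat
    return a


@dataclass
class LikelihoodLandscape:
    param_x: str
    param_y: str
    x: np.ndarray
    y: np.ndarray
    normalized_mass: np.ndarray  # shape (len(y), len(x))
    mass_contours: dict  # cumulative level -> density threshold
    loglik: np.ndarray


def likelihood_landscape(
    sessions,
    fit: FitResult,
    param_pair: tuple,
    x_range,
    y_range,
    n: int = 25,
    grid: GridConfig = DEFAULT_GRID,
    levels=(0.5, 0.75, 0.95),
    profile: bool = False,
) -> LikelihoodLandscape:
    """Likelihood over a 2-D parameter grid; exp(LL) is normalized to unit
    mass over the grid (flat prior).

    By default the other 9 parameters are held at the fitted optimum (a
    slice through the peak, as in landscape figures).  With
    ``profile=True`` they are re-optimized at every grid cell (a profile
    likelihood) -- substantially slower.
    """
    packed = pack_sessions(sessions, grid)
    nx, ny = param_pair
    ix, iy = INTERNAL_ORDER.index(nx), INTERNAL_ORDER.index(ny)
    theta0 = fit.params.internal_vector()
    xs = np.linspace(*x_range, n)
    ys = np.linspace(*y_range, n)
    ll = np.empty((n, n))
    if profile:
        other = np.array([k for k in range(11) if k not in (ix, iy)])
        tfm = fit.transform
        alpha_full = np.clip(theta0, tfm.lo + 1e-9, tfm.hi - 1e-9)
        a0_other = tfm.inverse(alpha_full)[other]
    for j, yv in enumerate(ys):
        for i, xv in enumerate(xs):
            th = theta0.copy()
            th[ix] = xv
            th[iy] = yv
            if not profile:
                ll[j, i], _ = loglik_and_grad_internal(packed, th, want_grad=False)
                continue

            def negll(a_other, th=th):
                a = np.zeros(11)
                a[other] = a_other
                th2 = th.copy()
                th2[other] = fit.transform.forward(a)[other]
                v, g = loglik_and_grad_internal(packed, th2, want_grad=True, floor=1e-12)
                if not np.isfinite(v):
                    return 1e30, np.zeros(other.size)
                return -v, -(g * fit.transform.jac(a))[other]

            res = optimize.minimize(negll, a0_other, jac=True, method="L-BFGS-B",
                                    options={"maxiter": 30, "gtol": 1e-2})
            ll[j, i] = -float(res.fun)
    if not (xs[0] <= theta0[ix] <= xs[-1] and ys[0] <= theta0[iy] <= ys[-1]):
        warnings.warn("landscape grid does not contain the fitted optimum")
    m = np.exp(ll - ll.max())
    tot = m.sum()
    if tot <= 0:
        raise ValueError("zero total probability mass on the landscape grid")
    m /= tot
    order = np.sort(m.ravel())[::-1]
    csum = np.cumsum(order)
    contours = {}
    for lev in levels:
        k = int(np.searchsorted(csum, lev))
        contours[lev] = float(order[min(k, order.size - 1)])
    return LikelihoodLandscape(
        param_x=nx, param_y=ny, x=xs, y=ys, normalized_mass=m, mass_contours=contours, loglik=ll
    )


def bic_compare(fits: list, labels=None) -> pd.DataFrame:
    """BIC table (k ln n - 2 LL, lower is better) for fits of the same data."""
    n = {f.n_trials for f in fits}
    if len(n) != 1:
        raise ValueError("fits must be on identical trial sets")
    labels = labels or [f"model_{i}" for i in range(len(fits))]
    df = pd.DataFrame(
        {
            "model": labels,
            "k": [f.n_free for f in fits],
            "loglik": [f.loglik for f in fits],
            "bic": [f.bic() for f in fits],
        }
    )
    df["winner"] = df["bic"] == df["bic"].min()
    return df
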