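"""Exact trial likelihoods by Fokker-Planck propagation.

Instead of Monte Carlo, the probability distribution P(a, t) of the
accumulator is propagated directly on a discretized grid (see
:mod:`clickddm._core` for the numerical scheme).  The probability of a
rightward choice is the mass strictly above the decision borderline
bias_thresh, plus the proportional share of the bin containing it; lapse
mixing then gives

    p_contra = (1 - kappa_C) * p_contra_model + kappa_I * (1 - p_contra_model)

with ipsi/contra resolved by the session's perturbed hemisphere.  Trials
are independent, so the dataset log-likelihood is the sum of per-trial
log choice probabilities; sessions concatenate ("meta-rat" pooling).

The gradient with respect to all 11 parameters is computed by forward-mode
tangent propagation through the same recursion (exact to machine
precision for the discretized likelihood); the normative contract is
agreement with central finite differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _core
from .accumulator import ipsi_is_left, merged_clicks
from .params import DEFAULT_BOUNDS, INTERNAL_ORDER, ModelParams
from .stimuli import ClickTrial, Session

__all__ = [
    "GridConfig",
    "AccumulatorDistribution",
    "TrialLikelihood",
    "PackedDataset",
    "pack_sessions",
    "propagate",
    "choice_probability",
    "log_likelihood",
    "gradient",
    "loglik_and_grad_internal",
]


@dataclass(frozen=True)
class GridConfig:
    """Discretization of the likelihood propagation.

    ``n_bins`` interior bins (odd; center bin exactly at a = 0) of width
    2B/(n_bins+1) span (-B, B), with two sticky bins at +/-B.  ``dt`` is
    the time step; clicks are snapped to the nearest step boundary.
    """

    dt: float = 0.01
    n_bins: int = 201

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_bins < 3 or self.n_bins % 2 == 0:
            raise ValueError("n_bins must be odd and >= 3")

    def validate_for(self, bound_B: float) -> None:
        dx = 2.0 * bound_B / (self.n_bins + 1)
        if dx > bound_B / 10.0:
            raise ValueError(
                f"grid too coarse: bin width {dx:.3g} exceeds B/10 = {bound_B / 10:.3g}; "
                "increase n_bins"
            )

    def dx(self, bound_B: float) -> float:
        return 2.0 * bound_B / (self.n_bins + 1)

    def n_steps(self, duration: float) -> int:
        return max(1, int(round(duration / self.dt)))


DEFAULT_GRID = GridConfig()

#: Click-noise scaling mode: 0 (default) follows the displayed dynamics --
#: the click SD is magnitude * sigma_s; 1 follows the alternative reading in
#: which the click *variance* is magnitude * sigma_s^2.
CLICK_NOISE_VARIANCE_MODE = 0

#: Reduced-resolution preset for large fitting runs (coarser time step and
#: bins; the refinement-convergence test quantifies the induced error).
FAST_GRID = GridConfig(dt=0.02, n_bins=61)


@dataclass
class AccumulatorDistribution:
    """Probability mass over the accumulator grid at one time point."""

    grid: np.ndarray  # bin centers incl. the +/-B sticky bins
    mass: np.ndarray
    t: float

    def check(self, atol: float = 1e-10) -> None:
        if np.any(self.mass < -atol):
            raise AssertionError("negative probability mass")
        if abs(self.mass.sum() - 1.0) > atol:
            raise AssertionError("mass not normalized")

    @property
    def mean(self) -> float:
        return float(np.dot(self.grid, self.mass))

    @property
    def var(self) -> float:
        return float(np.dot(self.grid**2, self.mass) - self.mean**2)


@dataclass
class TrialLikelihood:
    p_right: float
    p_left: float
    log_lik_choice: float | None  # None when the trial has no observed choice


@dataclass
class PackedDataset:
    """Flattened trial arrays ready for the numba core."""

    n_steps: np.ndarray
    click_ptr: np.ndarray
    click_t: np.ndarray
    click_step: np.ndarray
    click_sign: np.ndarray
    click_ipsi: np.ndarray
    contra_is_right: np.ndarray
    choice_is_right: np.ndarray  # -1 none, 0 left, 1 right
    grid: GridConfig = field(default_factory=lambda: DEFAULT_GRID)

    @property
    def n_trials(self) -> int:
        return int(self.n_steps.size)


def _trial_clicks(trial: ClickTrial, ipsi_left: bool, grid: GridConfig):
    t, s = merged_clicks(trial)
    ns = grid.n_steps(trial.duration)
    step = np.clip(np.round(t / grid.dt), 0, ns).astype(np.int64)
    is_ipsi = ((s < 0) == ipsi_left).astype(np.int64)
    return t, s, step, is_ipsi, ns


def pack_sessions(
    sessions,
    grid: GridConfig = DEFAULT_GRID,
    accumulation_only: bool = True,
) -> PackedDataset:
    """Concatenate sessions into flat arrays (meta-rat pooling).

    Each session's ``inactivated_side`` fixes its trials' ipsi/contra
    mapping.  Motor-control trials are excluded when ``accumulation_only``.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    n_steps, ptr, ts, steps, signs, ipsis, cir, choice = [], [0], [], [], [], [], [], []
    for sess in sessions:
        il = ipsi_is_left(sess.inactivated_side)
        trials = sess.accumulation_trials() if accumulation_only else sess.trials
        for tr in trials:
            t, s, st, ii, ns = _trial_clicks(tr, il, grid)
            n_steps.append(ns)
            ts.append(t)
            steps.append(st)
            signs.append(s)
            ipsis.append(ii)
            ptr.append(ptr[-1] + t.size)
            cir.append(1 if il else 0)  # contra choice is right iff ipsi is left
            choice.append({"L": 0, "R": 1, "none": -1}[tr.choice])
    return PackedDataset(
        n_steps=np.asarray(n_steps, dtype=np.int64),
        click_ptr=np.asarray(ptr, dtype=np.int64),
        click_t=np.concatenate(ts) if ts else np.zeros(0),
        click_step=np.concatenate(steps).astype(np.int64) if steps else np.zeros(0, np.int64),
        click_sign=np.concatenate(signs) if signs else np.zeros(0),
        click_ipsi=np.concatenate(ipsis).astype(np.int64) if ipsis else np.zeros(0, np.int64),
        contra_is_right=np.asarray(cir, dtype=np.int64),
        choice_is_right=np.asarray(choice, dtype=np.int64),
        grid=grid,
    )


def _run_core(packed: PackedDataset, v: np.ndarray, want_grad: bool):
    """Model-side choice probabilities P(a(T) > thresh) and their partials
    in internal coordinates (kappa columns filled downstream)."""
    g = packed.grid
    g.validate_for(v[4])
    p = np.empty(packed.n_trials)
    gr = np.zeros((packed.n_trials, 11)) if want_grad else np.zeros((1, 11))
    _core.fp_dataset(
        g.n_bins,
        g.dt,
        v[0],
        v[1],
        v[2],
        v[3],
        v[4],
        v[5],
        v[6],
        v[10],
        v[7],
        packed.n_steps,
        packed.click_ptr,
        packed.click_t,
        packed.click_step,
        packed.click_sign,
        packed.click_ipsi,
        1 if want_grad else 0,
        p,
        gr,
        CLICK_NOISE_VARIANCE_MODE,
    )
    return p, gr


def _mix_lapse(packed: PackedDataset, v: np.ndarray, p_model: np.ndarray, g_model=None):
    """Lapse mixing of model-side P(right); optionally propagate tangents."""
    kC, kI = v[8], v[9]
    cir = packed.contra_is_right == 1
    p_cm = np.where(cir, p_model, 1.0 - p_model)
    p_contra = kI + (1.0 - kC - kI) * p_cm
    p_right = np.where(cir, p_contra, 1.0 - p_contra)
    if g_model is None:
        return p_right, None
    # chain p_model -> p_cm -> p_contra -> p_right: the two side flips use
    # the same sign and cancel, except in the kappa columns
    sgn_cm = np.where(cir, 1.0, -1.0)
    dp = g_model * (1.0 - kC - kI)
    dp[:, 8] = sgn_cm * (-p_cm)
    dp[:, 9] = sgn_cm * (1.0 - p_cm)
    return p_right, dp


def loglik_and_grad_internal(
    packed: PackedDataset, v: np.ndarray, want_grad: bool = True, floor: float = 0.0
):
    """Total log-likelihood (and gradient in internal coordinates) of the
    observed choices under internal parameter vector ``v``.

    ``floor`` adds a tiny constant inside the log (regularizing the
    objective against p = 0 regions during optimization); with the default
    0, a zero-probability trial yields -inf with a diagnostic.
    """
    obs = packed.choice_is_right
    if np.any(obs < 0):
        raise ValueError("every trial must have an observed choice; filter first")
    p_model, g_model = _run_core(packed, v, want_grad)
    p_model = np.clip(p_model, 0.0, 1.0)
    p_right, dp = _mix_lapse(packed, v, p_model, g_model if want_grad else None)
    y = obs == 1
    p_obs = np.where(y, p_right, 1.0 - p_right) + floor
    bad = p_obs <= 0.0
    if np.any(bad):
        idx = np.flatnonzero(bad)[:20]
        warnings.warn(
            f"zero probability for the observed choice on trial(s) {idx.tolist()}; "
            "log-likelihood is -inf"
        )
        return -np.inf, (np.full(11, np.nan) if want_grad else None)
    ll = float(np.log(p_obs).sum())
    if not want_grad:
        return ll, None
    sgn = np.where(y, 1.0, -1.0)
    grad = (dp * (sgn / p_obs)[:, None]).sum(axis=0)
    return ll, grad


# ----------------------------------------------------------------------
# public per-trial / per-dataset operations
# ----------------------------------------------------------------------

def propagate(
    trial: ClickTrial,
    params: ModelParams,
    grid: GridConfig = DEFAULT_GRID,
    side_mapping: str = "none",
    return_evolution: bool = False,
):
    """Forward-propagate P(a, t) for one trial.

    Returns the :class:`AccumulatorDistribution` at stimulus end, or, with
    ``return_evolution``, ``(dist_end, evolution)`` where ``evolution`` has
    shape (n_steps+1, n_bins+2) (columns: -B sticky, interior, +B sticky).
    """
    if not math.isfinite(params.bound_B):
        raise ValueError("propagation requires a finite bound_B")
    grid.validate_for(params.bound_B)
    il = ipsi_is_left(side_mapping)
    t, s, step, ii, ns = _trial_clicks(trial, il, grid)
    rec = np.zeros((ns + 1, grid.n_bins + 2))
    _core.fp_trial_record(
        grid.n_bins,
        grid.dt,
        ns,
        params.lam,
        params.sigma2_a,
        params.sigma2_s_ipsi,
        params.sigma2_s_contra,
        params.bound_B,
        params.phi,
        params.tau_phi,
        params.input_gain,
        params.bias_thresh,
        t,
        step,
        s,
        ii,
        rec,
        CLICK_NOISE_VARIANCE_MODE,
    )
    B = params.bound_B
    dx = grid.dx(B)
    h = (grid.n_bins - 1) // 2
    centers = (np.arange(grid.n_bins) - h) * dx
    axis = np.concatenate(([-B], centers, [B]))
    dist = AccumulatorDistribution(grid=axis, mass=rec[-1].copy(), t=ns * grid.dt)
    if return_evolution:
        return dist, rec
    return dist


def choice_probability(
    trial: ClickTrial,
    params: ModelParams,
    side_mapping: str = "none",
    grid: GridConfig = DEFAULT_GRID,
) -> TrialLikelihood:
    """P(right), P(left) and the log-probability of the observed choice."""
    sess = Session(trials=[], inactivated_side=side_mapping if side_mapping in ("L", "R") else "none")
    sess.trials = [trial]
    packed = pack_sessions([sess], grid, accumulation_only=False)
    v = params.internal_vector()
    p_model, _ = _run_core(packed, v, False)
    p_right, _ = _mix_lapse(packed, v, np.clip(p_model, 0.0, 1.0))
    pr = float(p_right[0])
    ll = None
    if trial.choice in ("L", "R"):
        p_obs = pr if trial.choice == "R" else 1.0 - pr
        ll = math.log(p_obs) if p_obs > 0 else -math.inf
    return TrialLikelihood(p_right=pr, p_left=1.0 - pr, log_lik_choice=ll)


def log_likelihood(sessions, params: ModelParams, grid: GridConfig = DEFAULT_GRID) -> float:
    """Sum of log choice probabilities over all accumulation trials of all
    sessions (trials are independent; sessions concatenate)."""
    packed = pack_sessions(sessions, grid)
    ll, _ = loglik_and_grad_internal(packed, params.internal_vector(), want_grad=False)
    return ll


def gradient(sessions, params: ModelParams, grid: GridConfig = DEFAULT_GRID) -> np.ndarray:
    """Gradient of the log-likelihood w.r.t. the 11 canonical parameters
    (CANONICAL_ORDER: ..., lapse_total, lapse_biased, ...).

    Parameters must be strictly inside the default fitting bounds; on a
    bound the likelihood is not interior-differentiable there -- optimize
    in the unbounded (tanh-transformed) parameterization instead.
    """
    v = params.internal_vector()
    for name, val in zip(INTERNAL_ORDER, v):
        lo, hi = DEFAULT_BOUNDS[name]
        if not (lo < val < hi):
            raise ValueError(
                f"parameter {name}={val} is on or outside its bound [{lo}, {hi}]; "
                "use the unbounded (tanh) parameterization for boundary regions"
            )
    packed = pack_sessions(sessions, grid)
    ll, g = loglik_and_grad_internal(packed, v, want_grad=True)
    if not np.isfinite(ll):
        raise FloatingPointError("log-likelihood is -inf at these parameters")
    out = np.empty(11)
    out[:8] = g[:8]
    out[8] = 0.5 * (g[8] + g[9])  # d/d lapse_total
    out[9] = 0.5 * (g[8] - g[9])  # d/d lapse_biased
    out[10] = g[10]
    return out
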