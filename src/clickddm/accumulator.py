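"""The 11-parameter bounded accumulator: dynamics and Monte Carlo simulation.

Within a trial the accumulator ``a(t)`` starts at 0 and evolves as

    da = lam * a * dt + sigma_a * dW + (click impulses),

with absorbing ("sticky") bounds at |a| = B: once a path reaches a bound it
stops integrating.  Each click displaces ``a`` by ``sign * 2*w * C * eta``
where ``w`` is the side's input-gain weight (g_w for ipsilateral clicks,
1 - g_w for contralateral; 0.5/0.5 is balanced and gives unit-magnitude
clicks), ``C`` is the sensory-adaptation amplitude at the click time and
``eta ~ N(1, sigma_s)`` is per-click multiplicative noise, so the click's
displacement has mean ``sign*2*w*C`` and SD ``2*w*C*sigma_s``.

Adaptation: ``C`` relaxes toward 1 with time constant tau_phi and is
multiplied by phi immediately after each click (depression phi < 1,
facilitation phi > 1); a click's own impact uses the pre-multiplication
amplitude, so the first click of a train always has unit amplitude.
Simultaneous left/right clicks are processed left-then-right (an arbitrary
but fixed convention).

At stimulus end the model chooses right when ``a > bias_thresh``; lapse
relabeling then flips a model-contralateral categorization to an
ipsilateral choice with probability kappa_C and a model-ipsilateral one
with probability kappa_I.

This module is the Monte Carlo counterpart (and oracle) of the exact
distribution propagation in :mod:`clickddm.likelihood`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _core
from .params import ModelParams
from .stimuli import ClickTrial, Session

__all__ = [
    "AdaptationTrajectory",
    "TrajectorySample",
    "merged_clicks",
    "ipsi_is_left",
    "adaptation_trajectory",
    "click_kernel_moments",
    "simulate_trajectories",
    "simulate_a_end",
    "simulate_choice",
    "simulate_session_choices",
    "ideal_observer",
]


def ipsi_is_left(inactivated_side: str) -> bool:
    """Map a session's perturbed hemisphere to the ipsi/contra convention.

    Choices (and clicks) toward the inactivated side are ipsilateral.  For
    unperturbed ('none') or bilateral sessions there is no lateral mapping;
    the canonical assignment ipsi='L' is used, which is inert whenever the
    lateralized parameters are at their symmetric values.
    """
    if inactivated_side == "R":
        return False
    return True


@dataclass
class AdaptationTrajectory:
    times: np.ndarray  # merged click times, s
    signs: np.ndarray  # +1 right, -1 left
    C_before: np.ndarray
    C_after: np.ndarray


@dataclass
class TrajectorySample:
    a_path: np.ndarray  # accumulator value at each step boundary
    times: np.ndarray
    hit_bound: bool

    @property
    def a_end(self) -> float:
        return float(self.a_path[-1])


def merged_clicks(trial: ClickTrial) -> tuple[np.ndarray, np.ndarray]:
    """Merged (times, signs) sorted by time, left before right at ties."""
    t = np.concatenate([trial.left_clicks, trial.right_clicks])
    s = np.concatenate([-np.ones(trial.n_left), np.ones(trial.n_right)])
    order = np.lexsort((s, t))
    return t[order], s[order]


def adaptation_trajectory(trial: ClickTrial, phi: float, tau_phi: float) -> AdaptationTrajectory:
    """Adaptation amplitude C at each click of a trial.

    Between clicks C relaxes in closed form, C(t) = 1 + (C0 - 1) e^{-dt/tau};
    immediately after each click C is multiplied by phi.  Both click streams
    share a single C.
    """
    if phi < 0:
        raise ValueError("phi must be nonnegative")
    if tau_phi <= 0:
        raise ValueError("tau_phi must be positive")
    if np.any(np.diff(trial.left_clicks) < 0) or np.any(np.diff(trial.right_clicks) < 0):
        raise ValueError("click times must be sorted ascending")
    t, s = merged_clicks(trial)
    nc = t.size
    Cb = np.empty(nc)
    dcp = np.empty(nc)
    dct = np.empty(nc)
    _core._adaptation(nc, t, phi, tau_phi, Cb, dcp, dct)
    return AdaptationTrajectory(times=t, signs=s, C_before=Cb, C_after=phi * Cb)


def click_kernel_moments(
    trial: ClickTrial,
    params: ModelParams,
    side_mapping: str = "none",
    gain_window=None,
    variance_scales_with_C: bool = False,
):
    """Per-click displacement mean and SD (clicks units).

    Returns ``(times, means, sds)`` with means signed (+ right).  The
    optional ``gain_window = (t0, t1, ipsi_factor, contra_factor)``
    multiplies the input-gain weight of clicks falling in [t0, t1) -- the
    stand-in mechanism for temporally windowed (optogenetic-style)
    perturbations, which the likelihood model does not represent.
    """
    adapt = adaptation_trajectory(trial, params.phi, params.tau_phi)
    t, s, C = adapt.times, adapt.signs, adapt.C_before
    ipsi_left = ipsi_is_left(side_mapping)
    is_ipsi = (s < 0) == ipsi_left
    w = np.where(is_ipsi, params.input_gain, 1.0 - params.input_gain)
    if gain_window is not None:
        t0, t1, fi, fc = gain_window
        inwin = (t >= t0) & (t < t1)
        w = w * np.where(inwin, np.where(is_ipsi, fi, fc), 1.0)
    mag = 2.0 * w * C
    s2 = np.where(is_ipsi, params.sigma2_s_ipsi, params.sigma2_s_contra)
    if variance_scales_with_C:
        # alternative reading: the click *variance* scales with the amplitude
        sd = np.sqrt(np.abs(mag) * s2)
    else:
        sd = mag * np.sqrt(s2)
    return t, s * mag, sd


def simulate_a_end(
    trial: ClickTrial,
    params: ModelParams,
    n_samples: int,
    dt: float = 0.001,
    seed: int = 0,
    side_mapping: str = "none",
    a0: float = 0.0,
    gain_window=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama samples of a(T).  Returns (a_end, hit_bound)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t, mean, sd = click_kernel_moments(trial, params, side_mapping, gain_window)
    a_end = np.empty(n_samples)
    hit = np.empty(n_samples, dtype=np.bool_)
    _core.sim_a_end(
        n_samples,
        trial.duration,
        dt,
        params.lam,
        math.sqrt(params.sigma2_a),
        params.bound_B,
        t,
        mean,
        sd,
        a0,
        _u32(seed),
        a_end,
        hit,
    )
    return a_end, hit


def simulate_trajectories(
    trial: ClickTrial,
    params: ModelParams,
    n_samples: int,
    dt: float = 0.001,
    seed: int = 0,
    side_mapping: str = "none",
    a0: float = 0.0,
    gain_window=None,
) -> list[TrajectorySample]:
    """Sample full accumulator paths recorded at every step boundary."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t, mean, sd = click_kernel_moments(trial, params, side_mapping, gain_window)
    n_steps = max(1, int(round(trial.duration / dt)))
    paths = np.empty((n_samples, n_steps + 1))
    hit = np.empty(n_samples, dtype=np.bool_)
    _core.sim_paths(
        n_samples,
        trial.duration,
        dt,
        params.lam,
        math.sqrt(params.sigma2_a),
        params.bound_B,
        t,
        mean,
        sd,
        a0,
        _u32(seed),
        paths,
        hit,
    )
    times = np.linspace(0.0, trial.duration, n_steps + 1)
    return [TrajectorySample(a_path=paths[i], times=times, hit_bound=bool(hit[i])) for i in range(n_samples)]


def _u32(seed) -> int:
    return int(np.uint32(seed))


def _lapse_flip(model_right: bool, params: ModelParams, ipsi_left: bool, u: float) -> str:
    """Apply lapse relabeling to a model categorization."""
    model_ipsi = (not model_right) if ipsi_left else model_right
    if model_ipsi:
        flipped = u < params.kappa_I
        ipsi = not flipped
    else:
        flipped = u < params.kappa_C
        ipsi = flipped
    if ipsi_left:
        return "L" if ipsi else "R"
    return "R" if ipsi else "L"


def simulate_choice(
    trial: ClickTrial,
    params: ModelParams,
    seed: int = 0,
    side_mapping: str = "none",
    dt: float = 0.001,
    gain_window=None,
) -> str:
    """One model choice: a single sampled trajectory, the threshold rule at
    bias_thresh, then lapse relabeling."""
    a_end, _ = simulate_a_end(trial, params, 1, dt, seed, side_mapping, gain_window=gain_window)
    rng = np.random.default_rng(np.random.SeedSequence([_u32(seed), 7]))
    return _lapse_flip(a_end[0] > params.bias_thresh, params, ipsi_is_left(side_mapping), rng.random())


def simulate_session_choices(
    session: Session,
    params: ModelParams,
    seed: int = 0,
    dt: float = 0.001,
    side_mapping: str | None = None,
    gain_window=None,
    record_paths: bool = False,
):
    """Fill every trial's choice in place by simulating the model.

    Motor-control trials (no clicks, cued side) follow the cue.  When
    ``record_paths`` is true, the same latent trajectory that produced each
    accumulation trial's choice is returned (one path per trial, on a
    ``dt``-step grid), so downstream spike generation is coupled to the
    choice through a single realization.
    """
    if side_mapping is None:
        side_mapping = session.inactivated_side
    ss = np.random.SeedSequence(_u32(seed))
    trial_seeds = ss.generate_state(2 * len(session.trials))
    paths: list[TrajectorySample | None] = []
    ipsi_left = ipsi_is_left(side_mapping)
    for i, trial in enumerate(session.trials):
        if trial.trial_type == "motor_control":
            trial.choice = trial.correct_side
            paths.append(None)
            continue
        samp = simulate_trajectories(
            trial, params, 1, dt, int(trial_seeds[2 * i] >> 1), side_mapping, gain_window=gain_window
        )[0]
        u = (trial_seeds[2 * i + 1] + 0.5) / 2.0**32
        trial.choice = _lapse_flip(samp.a_end > params.bias_thresh, params, ipsi_left, u)
        paths.append(samp)
    if record_paths:
        return paths
    return None


def ideal_observer(trial: ClickTrial, seed: int = 0) -> str:
    """sign(#right - #left); ties are broken by a seeded coin flip."""
    d = trial.click_diff
    if d > 0:
        return "R"
    if d < 0:
        return "L"
    return "R" if np.random.default_rng(seed).random() < 0.5 else "L"
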