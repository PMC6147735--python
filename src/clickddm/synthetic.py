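"""Ground-truth synthetic datasets: behavior and spikes.

Emulates the study's data structure without any recorded data: Poisson
click stimuli (40 Hz combined rate, ratio-controlled difficulty), choices
generated by the accumulator model, perturbation arms built either by
swapping in a perturbed parameter vector globally (pharmacology-style) or
by attenuating contralateral click gain inside a time window
(optogenetics-style; the fitted model has no temporally resolved
parameters, so this windowed mechanism is an explicitly labeled stand-in),
and spike trains generated from specified encodings of the accumulator.

Spikes and the trial's choice are coupled through a single latent
trajectory per trial: the same realization that crosses (or not) the
decision threshold drives every neuron's firing rate, shifted by the
neural latency ``lag``, rectified at 0 and passed through an inhomogeneous
Poisson process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .accumulator import simulate_session_choices
from .neural import NeuronRecording
from .params import ModelParams
from .stimuli import DEFAULT_LEVEL_SET, Session, generate_stimulus_session

__all__ = [
    "EncodingSpec",
    "GeneratorSpec",
    "generate_behavior",
    "generate_epoch_session",
    "generate_spikes",
]


@dataclass(frozen=True)
class EncodingSpec:
    """Mapping from accumulator value to firing rate (Hz), rectified at 0.

    kinds: 'linear' (k1*a + k2), 'step' (low below threshold, high at or
    above) and 'constant' (rate).
    """

    kind: str = "linear"
    k1: float = 2.0
    k2: float = 20.0
    threshold: float = 0.0
    low: float = 10.0
    high: float = 30.0
    rate: float = 10.0

    def __call__(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        if self.kind == "linear":
            r = self.k1 * a + self.k2
        elif self.kind == "step":
            r = np.where(a >= self.threshold, self.high, self.low)
        elif self.kind == "constant":
            r = np.full_like(a, self.rate)
        else:
            raise ValueError(f"unknown encoding kind {self.kind!r}")
        return np.clip(r, 0.0, np.inf)

    def base_rate_check(self):
        if self.kind == "linear":
            return [self.k2]
        if self.kind == "step":
            return [self.low, self.high]
        return [self.rate]


@dataclass
class GeneratorSpec:
    """Study-condition defaults for a complete synthetic dataset."""

    params_control: ModelParams = field(default_factory=lambda: ModelParams.symmetric(
        lam=-0.5, sigma2_a=4.0, sigma2_s=0.5, bound_B=8.0, phi=0.3, tau_phi=0.05, lapse=0.1))
    params_perturbed: ModelParams | None = None
    n_trials: int = 1000
    level_set: tuple = DEFAULT_LEVEL_SET
    duration_law: object = "uniform"  # 'uniform' = U(0.1, 1.2) s; or a fixed duration
    motor_fraction: float = 0.1
    inactivated_side: str = "L"
    epoch_window: tuple | None = None  # (t0, t1) for windowed perturbations
    epoch_gain_factor: float = 1.0  # contra-gain multiplier inside the window
    lag: float = 0.15
    seed: int = 0


def generate_behavior(spec: GeneratorSpec) -> tuple[Session, Session]:
    """(control, perturbed) sessions with model-generated choices.

    The perturbed arm applies ``spec.params_perturbed`` globally
    (pharmacology-style) or, if ``spec.epoch_window`` is set, keeps the
    control parameters but multiplies contralateral click gain by
    ``epoch_gain_factor`` inside the window (optogenetics-style).
    """
    ss = np.random.SeedSequence(spec.seed)
    s_ctrl, s_pert, s_cch, s_pch = ss.generate_state(4) >> np.uint32(1)
    control = generate_stimulus_session(
        spec.n_trials, spec.level_set, spec.duration_law, spec.motor_fraction,
        int(s_ctrl), subject_id="meta-rat", inactivated_side="none", session_role="control",
    )
    pert_label = f"unilateral_{spec.inactivated_side}" if spec.inactivated_side in ("L", "R") else "bilateral"
    perturbed = generate_stimulus_session(
        spec.n_trials, spec.level_set, spec.duration_law, spec.motor_fraction,
        int(s_pert), subject_id="meta-rat", inactivated_side=spec.inactivated_side,
        session_role="perturbation",
    )
    for t in perturbed.trials:
        t.perturbation = pert_label
    simulate_session_choices(control, spec.params_control, seed=int(s_cch),
                             side_mapping=spec.inactivated_side)
    gain_window = None
    params_p = spec.params_perturbed or spec.params_control
    if spec.epoch_window is not None:
        t0, t1 = spec.epoch_window
        gain_window = (t0, t1, 1.0, spec.epoch_gain_factor)
        params_p = spec.params_control
    simulate_session_choices(perturbed, params_p, seed=int(s_pch),
                             side_mapping=spec.inactivated_side, gain_window=gain_window)
    return control, perturbed


_EPOCH_WINDOWS = {
    "epoch_pre": (-0.5, 0.0),
    "epoch_first_half": (0.0, 0.5),
    "epoch_second_half": (0.5, 1.0),
    "epoch_post": (1.0, 1.5),
}


def generate_epoch_session(
    params: ModelParams,
    n_trials: int,
    epsilon: float,
    inactivated_side: str = "L",
    frac_perturbed: float = 0.5,
    seed: int = 0,
    level_set=DEFAULT_LEVEL_SET,
) -> Session:
    """One optogenetics-style session: fixed 1 s stimuli, a fraction of
    trials perturbed in one of four 500 ms epochs (randomly interleaved
    with control trials), contra click gain reduced by ``epsilon`` inside
    the window.  Epochs outside the stimulus (pre/post) cannot affect the
    clicks, mirroring a perturbation confined to that time period."""
    sess = generate_stimulus_session(
        n_trials, level_set, 1.0, 0.0, seed, subject_id="meta-rat",
        inactivated_side=inactivated_side, session_role="perturbation",
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    labels = list(_EPOCH_WINDOWS)
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 13])
    trial_seeds = ss.generate_state(n_trials) >> np.uint32(1)
    for i, t in enumerate(sess.trials):
        if rng.random() < frac_perturbed:
            t.perturbation = labels[rng.integers(4)]
    # choices: simulate each subset under its window
    for label in ["none"] + labels:
        idx = [i for i, t in enumerate(sess.trials) if t.perturbation == label]
        if not idx:
            continue
        sub = Session(trials=[sess.trials[i] for i in idx],
                      inactivated_side=inactivated_side, session_role="perturbation")
        window = None
        if label != "none":
            t0, t1 = _EPOCH_WINDOWS[label]
            window = (t0, t1, 1.0, 1.0 - epsilon)
        simulate_session_choices(sub, params, seed=int(trial_seeds[idx[0]]),
                                 side_mapping=inactivated_side, gain_window=window)
    return sess


def generate_spikes(
    session: Session,
    params: ModelParams,
    encoding_specs,
    lag: float = 0.15,
    seed: int = 0,
    dt: float = 0.002,
    path_dt: float = 0.001,
) -> tuple[list[NeuronRecording], list]:
    """Spike trains for every accumulation trial of ``session``.

    One latent trajectory is simulated per trial (and used to (re)set the
    trial's choice, coupling spikes and behavior); each neuron's rate is
    ``encoding(a(t - lag))`` (a = 0 before the stimulus reaches the
    latency), rectified, and sampled as an inhomogeneous Poisson process on
    a ``dt`` grid over [0, duration + lag].  Returns (recordings, paths).
    """
    if isinstance(encoding_specs, EncodingSpec):
        encoding_specs = [encoding_specs]
    for enc in encoding_specs:
        if np.any(np.asarray(enc.base_rate_check()) < 0):
            raise ValueError("encoding must yield nonnegative baseline rates")
    paths = simulate_session_choices(session, params, seed=seed, dt=path_dt,
                                     side_mapping=session.inactivated_side, record_paths=True)
    trials = session.trials
    n_trials = len(trials)
    t_stop = np.array([t.duration + lag for t in trials])
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 101]))
    recs = []
    for n_idx, enc in enumerate(encoding_specs):
        st_all = []
        id_all = []
        for i, tr in enumerate(trials):
            nb = int(np.ceil(t_stop[i] / dt))
            tgrid = (np.arange(nb) + 0.5) * dt
            tm = tgrid - lag
            if paths[i] is None:
                a_vals = np.zeros(nb)
            else:
                a_vals = np.where(tm <= 0, 0.0, np.interp(np.clip(tm, 0, tr.duration),
                                                          paths[i].times, paths[i].a_path))
            rate = enc(a_vals)
            counts = rng.poisson(rate * dt)
            for j in np.flatnonzero(counts):
                st_all.append(tgrid[j] - dt / 2 + rng.random(counts[j]) * dt)
                id_all.append(np.full(counts[j], i, dtype=np.int64))
        spike_t = np.concatenate(st_all) if st_all else np.zeros(0)
        spike_i = np.concatenate(id_all) if id_all else np.zeros(0, np.int64)
        order = np.lexsort((spike_t, spike_i))
        recs.append(
            NeuronRecording(spike_times=spike_t[order], trial_ids=spike_i[order],
                            n_trials=n_trials, t_stop=t_stop, neuron_id=f"syn{n_idx}")
        )
    return recs, paths
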