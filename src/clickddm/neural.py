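"""Spike-train analyses: PSTHs, side selectivity, click-triggered averages
and model-based accumulator tuning curves.

The click-triggered average (CTA) isolates the mean change in firing
associated with a single click: trials are grouped by their generative
Poisson rate pair, the group-mean response is subtracted from each trial
to form residuals, residual snippets are aligned to every click
(non-preferred-side snippets sign-inverted) and averaged.  Under a graded
linear encoding of accumulated evidence, r = k1*a(t) + k2, the prediction
(obtained by passing simulated accumulator trajectories through the same
pipeline) is a fixed-magnitude, sustained step, because each click shifts
the accumulator by a fixed expected amount that persists in the absence of
leak; under strong sticky bounds the sustained level attenuates.

Tuning curves relate firing to the model's moment-by-moment evidence
estimate: the trial-by-trial forward distribution P(a, t) (not conditioned
on the choice) is combined with the firing rate observed at t + lag
(neural latency, 150 ms by default) to form the joint distribution of
(a, rate), from which E[rate | a, t] is extracted per neuron; neurons are
pooled by inverse conditional variance and the pooled curve is averaged
over t in [0.15, 0.5] s.  A four-parameter sigmoid
r = k1 + k2/(1 + exp(-k3 (a - k4))) summarizes each neuron's curve; its
slope at the zero-crossing, k2*k3/4, separates graded (shallow) from
step-like (steep) encodings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import ranksums

from .likelihood import GridConfig, propagate
from .params import ModelParams
from .stimuli import ClickTrial

__all__ = [
    "NeuronRecording",
    "PSTH",
    "ClickTriggeredAverage",
    "TuningCurve",
    "TuningSigmoid",
    "compute_psth",
    "classify_side_selective",
    "estimate_latency",
    "click_triggered_average",
    "predict_cta_linear_encoding",
    "compute_tuning_curve",
    "fit_tuning_sigmoid",
    "tuning_sigmoid",
]

PSTH_DT = 0.01  # s


@dataclass
class NeuronRecording:
    """Per-neuron spikes: times (s from stimulus onset) with trial indices."""

    spike_times: np.ndarray
    trial_ids: np.ndarray
    n_trials: int
    t_stop: np.ndarray | None = None  # per-trial recorded window end (s)
    neuron_id: str = "n0"

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        if not np.all(np.isfinite(self.spike_times)):
            raise ValueError("spike times must be finite")
        if self.trial_ids.size and (self.trial_ids.min() < 0 or self.trial_ids.max() >= self.n_trials):
            raise ValueError("every spike must map to a known trial")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def _half_gauss_kernel(sigma: float, dt: float) -> np.ndarray:
    """Causal half-Gaussian filter (weights on the past only, truncated at
    4 SD, normalized to sum 1)."""
    n = int(np.ceil(4.0 * sigma / dt)) + 1
    lags = np.arange(n) * dt
    w = np.exp(-0.5 * (lags / sigma) ** 2)
    return w / w.sum()


def smoothed_rates(
    recording: NeuronRecording,
    trials,
    dt: float = PSTH_DT,
    sigma: float = 0.1,
    t_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(rates, time) matrix of causally smoothed firing rates, one row per
    trial; entries beyond a trial's recorded window are NaN."""
    stops = (
        np.asarray(recording.t_stop, dtype=float)
        if recording.t_stop is not None
        else np.array([t.duration for t in trials])
    )
    if t_max is None:
        t_max = float(stops.max())
    nb = int(np.ceil(t_max / dt))
    time = (np.arange(nb) + 0.5) * dt
    counts = np.zeros((recording.n_trials, nb))
    b = np.floor(recording.spike_times / dt).astype(np.int64)
    ok = (b >= 0) & (b < nb)
    np.add.at(counts, (recording.trial_ids[ok], b[ok]), 1.0)
    rates = counts / dt
    kern = _half_gauss_kernel(sigma, dt)
    sm = np.empty_like(rates)
    for i in range(rates.shape[0]):
        sm[i] = np.convolve(rates[i], kern)[:nb]
    # value at t must depend only on spikes at <= t: np.convolve with the
    # kernel's weight 0 at lag 0 achieves this by construction
    for i in range(rates.shape[0]):
        nlast = int(np.floor(stops[i] / dt))
        sm[i, nlast:] = np.nan
    return sm, time


@dataclass
class PSTH:
    time: np.ndarray
    rates: np.ndarray  # (n_groups, n_time), group-mean normalized rates
    group_edges: np.ndarray
    group_sizes: np.ndarray
    normalizer: float
    normalized: bool


def _strength_toward(trials, preferred_side: str) -> np.ndarray:
    """Signed generative rate difference toward the preferred side."""
    s = np.array([t.rate_right - t.rate_left for t in trials])
    return s if preferred_side == "R" else -s


def compute_psth(
    recording: NeuronRecording,
    trials,
    preferred_side: str = "R",
    n_groups: int = 4,
    dt: float = PSTH_DT,
    sigma: float = 0.1,
    normalize: bool = True,
) -> PSTH:
    """Group-averaged PSTH by stimulus strength.

    Trials are split into ``n_groups`` equal-count quantiles of the signed
    preferred-minus-nonpreferred generative click rate; rates are smoothed
    with a causal half-Gaussian (SD ``sigma``), normalized by the neuron's
    mean rate in a 50 ms window at stimulus onset, and averaged per group.
    """
    sm, time = smoothed_rates(recording, trials, dt, sigma)
    strength = _strength_toward(trials, preferred_side)
    edges = np.quantile(strength, np.linspace(0, 1, n_groups + 1))
    edges[-1] += 1e-9
    gid = np.clip(np.searchsorted(edges, strength, side="right") - 1, 0, n_groups - 1)
    norm = float(np.nanmean(sm[:, time <= 0.05])) if normalize else 1.0
    normalized = normalize
    if not norm > 0:
        warnings.warn("zero firing at stimulus onset; returning unnormalized PSTH")
        norm, normalized = 1.0, False
    out = np.full((n_groups, time.size), np.nan)
    sizes = np.zeros(n_groups, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for gidx in range(n_groups):
            rows = sm[gid == gidx]
            sizes[gidx] = rows.shape[0]
            if rows.size:
                out[gidx] = np.nanmean(rows, axis=0) / norm
    return PSTH(time=time, rates=out, group_edges=edges, group_sizes=sizes,
                normalizer=norm, normalized=normalized)


def classify_side_selective(
    recording: NeuronRecording,
    trials,
    window: tuple = (0.0, 0.5),
    alpha: float = 0.05,
    min_trials: int = 5,
):
    """Rank-sum test on fixation-window spike counts split by the upcoming
    choice.  Returns (is_selective, preferred_side, p); is_selective is
    None when undetermined (too few trials per class or a silent neuron)."""
    t0, t1 = window
    inwin = (recording.spike_times >= t0) & (recording.spike_times < t1)
    counts = np.bincount(recording.trial_ids[inwin], minlength=recording.n_trials).astype(float)
    choice = np.array([t.choice for t in trials])
    cL = counts[choice == "L"]
    cR = counts[choice == "R"]
    if cL.size < min_trials or cR.size < min_trials or recording.n_spikes == 0:
        return None, None, np.nan
    stat, p = ranksums(cR, cL)
    preferred = "R" if cR.mean() >= cL.mean() else "L"
    return bool(p < alpha), preferred, float(p)


def estimate_latency(
    recordings,
    trials,
    preferred_side: str = "R",
    alpha: float = 0.05,
    dt: float = PSTH_DT,
    sigma: float = 0.1,
    n_groups: int = 4,
) -> float:
    """Neural response latency from the PSTH: the first time bin whose
    rates are significantly modulated by stimulus strength.

    Per time bin, a Kruskal-Wallis test compares the across-neuron mean
    rates between stimulus-strength quantile groups; the latency is the
    left edge of the first bin with p < alpha (with all later bins also
    counted individually, no correction -- the onset definition).  Returns
    NaN if no bin is significant.  The fixed 0.15 s default used elsewhere
    can be replaced by this estimate when the data warrant it.
    """
    from scipy.stats import kruskal

    if isinstance(recordings, NeuronRecording):
        recordings = [recordings]
    strength = _strength_toward(trials, preferred_side)
    edges = np.quantile(strength, np.linspace(0, 1, n_groups + 1))
    edges[-1] += 1e-9
    gid = np.clip(np.searchsorted(edges, strength, side="right") - 1, 0, n_groups - 1)
    pooled = None
    for rec in recordings:
        sm, time = smoothed_rates(rec, trials, dt, sigma)
        pooled = sm if pooled is None else pooled + sm
    pooled = pooled / len(recordings)
    for j, t in enumerate(time):
        cols = [pooled[gid == g, j] for g in range(n_groups)]
        cols = [c[np.isfinite(c)] for c in cols]
        if any(c.size < 3 for c in cols):
            continue
        try:
            _, p = kruskal(*cols)
        except ValueError:  # all-identical values
            continue
        if p < alpha:
            return float(t - dt / 2)
    return float("nan")


@dataclass
class ClickTriggeredAverage:
    lags: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_clicks: int
    per_group: dict  # (rate_pref, rate_nonpref) -> group mean curve


def _cta_from_rates(
    rates: np.ndarray,
    time: np.ndarray,
    trials,
    preferred_side: str,
    lag_range: tuple = (-0.1, 0.3),
    dt: float = PSTH_DT,
    min_trials_per_group: int = 10,
) -> ClickTriggeredAverage:
    """Shared residual/alignment pipeline operating on rate matrices."""
    l0 = int(round(lag_range[0] / dt))
    l1 = int(round(lag_range[1] / dt))
    lags = np.arange(l0, l1 + 1) * dt
    nlag = lags.size
    keys = [(t.rate_right, t.rate_left) if preferred_side == "R" else (t.rate_left, t.rate_right)
            for t in trials]
    groups: dict = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    pref_sign = 1.0 if preferred_side == "R" else -1.0
    per_group = {}
    acc_sum = np.zeros(nlag)
    acc_sq = np.zeros(nlag)
    acc_n = np.zeros(nlag)
    nb = rates.shape[1]
    pad = nlag + max(-l0, 0) + 1
    offsets = np.arange(nlag)
    for key, idx in sorted(groups.items()):
        if len(idx) < min_trials_per_group:
            warnings.warn(f"rate group {key} has {len(idx)} trials (<{min_trials_per_group}); dropped")
            continue
        sub = rates[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            peth = np.nanmean(sub, axis=0)
        resid = np.full((len(idx), nb + 2 * pad), np.nan)
        resid[:, pad: pad + nb] = sub - peth[None, :]
        rows, centers, signs = [], [], []
        for row, i in enumerate(idx):
            tr = trials[i]
            for sgn, clicks in ((pref_sign, tr.right_clicks), (-pref_sign, tr.left_clicks)):
                for tc in clicks:
                    rows.append(row)
                    centers.append(int(np.floor(tc / dt)))
                    signs.append(sgn)
        if not rows:
            continue
        rows = np.asarray(rows)
        centers = np.asarray(centers)
        signs = np.asarray(signs, dtype=float)
        snip = resid[rows[:, None], centers[:, None] + l0 + pad + offsets[None, :]]
        ok = np.isfinite(snip)
        signed = np.where(ok, snip * signs[:, None], 0.0)
        gsum = signed.sum(axis=0)
        gn = ok.sum(axis=0).astype(float)
        acc_sum += gsum
        acc_sq += np.where(ok, snip**2, 0.0).sum(axis=0)
        acc_n += gn
        with np.errstate(invalid="ignore", divide="ignore"):
            per_group[key] = gsum / gn
    if not per_group:
        raise ValueError("no rate group has enough trials")
    mean = np.nanmean(np.stack(list(per_group.values())), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_mean = acc_sum / acc_n
        var = acc_sq / acc_n - pooled_mean**2
        se = np.sqrt(np.clip(var, 0, np.inf) / np.maximum(acc_n, 1))
    return ClickTriggeredAverage(lags=lags, mean=mean, se=se,
                                 n_clicks=int(acc_n.max()), per_group=per_group)


def click_triggered_average(
    recording: NeuronRecording,
    trials,
    preferred_side: str,
    lag_range: tuple = (-0.1, 0.3),
    dt: float = PSTH_DT,
    sigma: float = 0.1,
    min_trials_per_group: int = 10,
) -> ClickTriggeredAverage:
    """Click-triggered average of a neuron's smoothed firing rate."""
    sm, time = smoothed_rates(recording, trials, dt, sigma)
    return _cta_from_rates(sm, time, trials, preferred_side, lag_range, dt, min_trials_per_group)


def predict_cta_linear_encoding(
    params: ModelParams,
    k1: float,
    k2: float,
    n_trials: int = 5000,
    seed: int = 0,
    level_set=None,
    duration_law="uniform",
    lag: float = 0.0,
    lag_range: tuple = (-0.1, 0.3),
    dt: float = PSTH_DT,
    smooth_sigma: float | None = 0.1,
    preferred_side: str = "R",
) -> ClickTriggeredAverage:
    """Theoretical CTA under a graded linear encoding r = k1*a(t) + k2.

    Accumulator trajectories are simulated for ``n_trials`` trials drawn
    with the same difficulty range and duration law as the data, encoded
    linearly (rectified at 0) and passed through the identical CTA
    pipeline.  With k1 = 0 the prediction is identically zero; the step
    amplitude scales linearly with k1.
    """
    from .accumulator import simulate_trajectories
    from .stimuli import DEFAULT_LEVEL_SET, generate_click_trains, sample_difficulty, sample_duration

    if n_trials < 100:
        warnings.warn("n_trials < 100 gives a noisy CTA prediction")
    level_set = level_set or DEFAULT_LEVEL_SET
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        rl, rr = sample_difficulty(level_set, rng)
        trials.append(generate_click_trains(rl, rr, sample_duration(duration_law, rng), rng))
    t_max = max(t.duration for t in trials) + lag
    nb = int(np.ceil(t_max / dt))
    time = (np.arange(nb) + 0.5) * dt
    rates = np.full((n_trials, nb), np.nan)
    seeds = np.random.SeedSequence(seed).generate_state(n_trials)
    for i, tr in enumerate(trials):
        path = simulate_trajectories(tr, params, 1, dt=dt, seed=int(seeds[i] >> 1))[0]
        stop = tr.duration + lag
        nlast = int(np.floor(stop / dt))
        a_at = np.zeros(nb)
        for j in range(min(nlast, nb)):
            tm = time[j] - lag
            if tm <= 0:
                a_at[j] = 0.0
            else:
                a_at[j] = np.interp(tm, path.times, path.a_path)
        r = np.clip(k1 * a_at + k2, 0.0, np.inf)
        rates[i, : min(nlast, nb)] = r[: min(nlast, nb)]
    if smooth_sigma:
        kern = _half_gauss_kernel(smooth_sigma, dt)
        for i in range(n_trials):
            ok = np.isfinite(rates[i])
            row = np.where(ok, rates[i], 0.0)
            sm = np.convolve(row, kern)[:nb]
            rates[i] = np.where(ok, sm, np.nan)
    return _cta_from_rates(rates, time, trials, preferred_side, lag_range, dt)


# ----------------------------------------------------------------------
# model-based tuning curves
# ----------------------------------------------------------------------

@dataclass
class TuningCurve:
    a_centers: np.ndarray  # includes the +/-B sticky bins as end entries
    t_centers: np.ndarray  # model time (neural time - lag)
    neuron_mean: np.ndarray  # (n_neurons, n_t, n_a)
    neuron_var: np.ndarray
    pooled: np.ndarray  # (n_t, n_a) inverse-variance pooled across neurons
    summary: np.ndarray  # (n_a,) pooled curve averaged over the time window
    t_window: tuple
    lag: float


def model_joint_distributions(
    trials,
    params: ModelParams,
    grid: GridConfig,
    n_a_bins: int = 9,
    time_bin: float = 0.05,
    t_max: float = 0.7,
):
    """Per-trial P(a, t) on a coarse (time_bin x a_bin) grid.

    The forward distribution is purely stimulus-driven (not conditioned on
    the observed choice).  Interior a-bins are equal-width over (-B, B);
    the first/last bins hold the sticky bound masses.
    """
    B = params.bound_B
    ni = grid.n_bins
    h = (ni - 1) // 2
    dxf = grid.dx(B)
    fine_centers = (np.arange(ni) - h) * dxf
    a_edges = np.linspace(-B, B, n_a_bins + 1)
    abin = np.clip(np.searchsorted(a_edges, fine_centers, side="right") - 1, 0, n_a_bins - 1)
    a_centers = np.concatenate(([-B], 0.5 * (a_edges[:-1] + a_edges[1:]), [B]))
    nt_bins = int(np.round(t_max / time_bin))
    t_centers = (np.arange(nt_bins) + 0.5) * time_bin
    steps_per_bin = max(1, int(round(time_bin / grid.dt)))
    joints = []
    for tr in trials:
        _, rec = propagate(tr, params, grid, return_evolution=True)
        ns = rec.shape[0] - 1
        J = np.full((nt_bins, n_a_bins + 2), np.nan)
        for tb in range(nt_bins):
            s0 = tb * steps_per_bin + 1
            s1 = min((tb + 1) * steps_per_bin, ns) + 1
            if s0 >= ns + 1:
                break
            block = rec[s0:s1].mean(axis=0)
            row = np.zeros(n_a_bins + 2)
            row[0] = block[0]
            row[-1] = block[-1]
            np.add.at(row, 1 + abin, block[1:-1])
            J[tb] = row
        joints.append(J)
    return joints, a_centers, t_centers


def compute_tuning_curve(
    recordings,
    trials,
    params: ModelParams,
    lag: float = 0.15,
    grid: GridConfig | None = None,
    t_window: tuple = (0.15, 0.5),
    n_a_bins: int = 9,
    time_bin: float = 0.05,
    min_mass: float = 1e-3,
    joints=None,
) -> TuningCurve:
    """Firing rate conditioned on the model's accumulator value.

    For each model-time bin t, E[r | a, t] = sum_trials P(a, t) * r(t+lag)
    / sum_trials P(a, t), where r(t+lag) is the trial's spike count in the
    lagged window.  Neurons are pooled by inverse conditional variance; the
    summary curve averages pooled values over ``t_window``.  Precomputed
    ``joints`` (from :func:`model_joint_distributions`) may be passed to
    share the propagation across neurons.
    """
    if isinstance(recordings, NeuronRecording):
        recordings = [recordings]
    grid = grid or GridConfig(dt=0.01, n_bins=101)
    if joints is None:
        joints = model_joint_distributions(trials, params, grid, n_a_bins, time_bin)
    Js, a_centers, t_centers = joints
    na = a_centers.size
    ntb = t_centers.size
    nn = len(recordings)
    mean = np.full((nn, ntb, na), np.nan)
    var = np.full((nn, ntb, na), np.nan)
    for n_idx, rec in enumerate(recordings):
        stops = (
            np.asarray(rec.t_stop, dtype=float)
            if rec.t_stop is not None
            else np.array([t.duration for t in trials])
        )
        # spike counts per (trial, lagged model-time bin)
        tb_of_spike = np.floor((rec.spike_times - lag) / time_bin).astype(np.int64)
        ok = (tb_of_spike >= 0) & (tb_of_spike < ntb)
        counts = np.zeros((rec.n_trials, ntb))
        np.add.at(counts, (rec.trial_ids[ok], tb_of_spike[ok]), 1.0)
        r = counts / time_bin
        valid = np.zeros((rec.n_trials, ntb), dtype=bool)
        for i in range(rec.n_trials):
            nlast = int(np.floor((stops[i] - lag) / time_bin))
            valid[i, : max(nlast, 0)] = True
        J3 = np.stack(Js)  # (n_trials, ntb, na)
        ok3 = valid & np.isfinite(J3[:, :, 0])
        W = np.where(ok3[:, :, None], np.nan_to_num(J3), 0.0)
        num = np.einsum("itj,it->tj", W, r)
        sq = np.einsum("itj,it->tj", W, r**2)
        den = W.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(den >= min_mass, num / den, np.nan)
            v = np.where(den >= min_mass, sq / den - m**2, np.nan)
        mean[n_idx] = m
        var[n_idx] = v
    w = 1.0 / np.clip(var, 1e-6, np.inf)
    w = np.where(np.isfinite(mean), w, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.nansum(np.where(w > 0, mean, 0.0) * w, axis=0) / w.sum(axis=0)
    tw = (t_centers >= t_window[0]) & (t_centers <= t_window[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        summary = np.nanmean(pooled[tw], axis=0)
    return TuningCurve(a_centers=a_centers, t_centers=t_centers, neuron_mean=mean,
                       neuron_var=var, pooled=pooled, summary=summary,
                       t_window=t_window, lag=lag)


@dataclass
class TuningSigmoid:
    k1: float
    k2: float
    k3: float
    k4: float
    degenerate: bool = False

    @property
    def slope_at_zero(self) -> float:
        """Sigmoid slope at its zero-crossing, k2*k3/4."""
        return self.k2 * self.k3 / 4.0


def tuning_sigmoid(a, k1, k2, k3, k4):
    return k1 + k2 / (1.0 + np.exp(-k3 * (np.asarray(a, dtype=float) - k4)))


def fit_tuning_sigmoid(curve, r=None) -> TuningSigmoid:
    """Least-squares 4-parameter sigmoid fit of rate vs accumulator value.

    Accepts a :class:`TuningCurve` (fits its summary curve) or explicit
    (a, r) arrays.  A flat curve yields k2 ~ 0 with a degenerate flag.
    """
    if isinstance(curve, TuningCurve):
        a = curve.a_centers
        r = curve.summary
    else:
        a = np.asarray(curve, dtype=float)
        r = np.asarray(r, dtype=float)
    ok = np.isfinite(r)
    a, r = a[ok], r[ok]
    if a.size < 5:
        raise ValueError(f"need >= 5 defined accumulator bins, got {a.size}")
    rng_r = r.max() - r.min()
    scale = max(a.max() - a.min(), 1e-6)
    p0 = [float(r.min()), float(max(rng_r, 1e-6)), 4.0 / scale, 0.0]
    bounds = ([-np.inf, 0.0, 1e-4, a.min()], [np.inf, np.inf, 1e4, a.max()])
    try:
        popt, _ = curve_fit(tuning_sigmoid, a, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        popt = p0
    degenerate = popt[1] < 1e-3 * max(abs(r).max(), 1.0)
    return TuningSigmoid(k1=float(popt[0]), k2=float(popt[1]), k3=float(popt[2]),
                         k4=float(popt[3]), degenerate=bool(degenerate))
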