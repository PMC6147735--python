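"""Psychometric curves and perturbation-effect statistics.

Psychometric curves relate the played click difference x = #R - #L to the
fraction of rightward choices via the four-parameter sigmoid

    y = y0 + a / (1 + exp(-(x - x0) / b)),

with x0 the inflection point, b the slope scale and [y0, y0 + a] the
asymptote range.

Perturbation effects are quantified by binning trials into equal-count
stimulus-strength bins (10 by default) and averaging, across bins, the
difference between perturbed and control arms of either the fraction of
ipsilateral choices (unilateral bias; reported in percentage points,
positive = more ipsilateral choices under perturbation) or percent
correct (bilateral impairment; positive = worse performance under
perturbation).  Confidence intervals and p-values come from a
nonparametric bootstrap over trials (1000 iterations by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .accumulator import ipsi_is_left
from .stimuli import Session

__all__ = [
    "PsychometricFit",
    "BiasEstimate",
    "sigmoid4",
    "fit_psychometric",
    "unilateral_bias",
    "bilateral_impairment",
    "epoch_bias",
    "bias_difference",
]


def sigmoid4(x, x0, b, y0, a):
    return y0 + a / (1.0 + np.exp(-(x - x0) / b))


@dataclass
class PsychometricFit:
    x0: float
    b: float
    y0: float
    a: float
    residual_deviance: float
    degenerate: bool = False

    def predict(self, x):
        return sigmoid4(np.asarray(x, dtype=float), self.x0, self.b, self.y0, self.a)


@dataclass
class BiasEstimate:
    bias: float  # percentage points
    ci95: tuple
    p_value: float
    n_bins: int
    per_bin: np.ndarray | None = None  # per-bin deltas (fractions)
    n_boot: int = 0


def _trials_xy(trials):
    tr = [t for t in trials if t.trial_type == "accumulation" and t.choice in ("L", "R")]
    x = np.array([t.click_diff for t in tr], dtype=float)
    y = np.array([1.0 if t.choice == "R" else 0.0 for t in tr])
    return tr, x, y


def fit_psychometric(trials_or_session) -> PsychometricFit:
    """Weighted least-squares fit of the four-parameter sigmoid to the
    fraction of rightward choices per click difference.

    Deterministic: fixed initialization x0 = median(x), b = range(x)/8,
    y0 = min(y), a = max(y) - min(y); per-x fractions are weighted by
    trial counts.  Near-flat data (fitted a < 0.05) is flagged degenerate.
    """
    trials = trials_or_session.trials if isinstance(trials_or_session, Session) else trials_or_session
    _, x, y = _trials_xy(trials)
    xs = np.unique(x)
    if xs.size < 4:
        raise ValueError(f"need >= 4 distinct click differences, got {xs.size}")
    frac = np.array([y[x == v].mean() for v in xs])
    cnt = np.array([(x == v).sum() for v in xs], dtype=float)
    b0 = max((xs.max() - xs.min()) / 8.0, 0.5)
    p0 = [float(np.median(x)), b0, float(frac.min()), float(frac.max() - frac.min())]
    bounds = ([xs.min() - 10.0, 1e-3, 0.0, 0.0], [xs.max() + 10.0, 100.0, 1.0, 1.0])
    p0[3] = min(max(p0[3], 1e-3), 1.0)
    try:
        popt, _ = curve_fit(
            sigmoid4, xs, frac, p0=p0, sigma=1.0 / np.sqrt(cnt), bounds=bounds, maxfev=20000
        )
    except RuntimeError:
        popt = p0
    pred = np.clip(sigmoid4(xs, *popt), 1e-12, 1.0 - 1e-12)
    dev = -2.0 * np.sum(cnt * (frac * np.log(pred) + (1.0 - frac) * np.log(1.0 - pred)))
    dev0 = -2.0 * np.sum(
        cnt * (frac * np.log(np.clip(frac, 1e-12, 1)) + (1 - frac) * np.log(np.clip(1 - frac, 1e-12, 1)))
    )
    return PsychometricFit(
        x0=float(popt[0]),
        b=float(popt[1]),
        y0=float(popt[2]),
        a=float(popt[3]),
        residual_deviance=float(dev - dev0),
        degenerate=bool(popt[3] < 0.05),
    )


# ----------------------------------------------------------------------
# binned perturbation statistics
# ----------------------------------------------------------------------

def _quantile_bins(x_all, n_bins):
    edges = np.quantile(x_all, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)  # ties in discrete click differences collapse edges
    if edges.size - 1 < n_bins:
        warnings.warn(
            f"only {edges.size - 1} distinct stimulus-strength bins available "
            f"(requested {n_bins}); merged"
        )
    edges[0] -= 0.5
    edges[-1] += 0.5
    return edges


def _binned_mean_delta(xp, yp, xc, yc, edges):
    """Mean over bins of (mean yp in bin - mean yc in bin); empty bins are
    merged into their populated neighbors by nan-skipping."""
    nb = edges.size - 1
    bp = np.clip(np.searchsorted(edges, xp, side="right") - 1, 0, nb - 1)
    bc = np.clip(np.searchsorted(edges, xc, side="right") - 1, 0, nb - 1)
    sp = np.bincount(bp, weights=yp, minlength=nb)
    npb = np.bincount(bp, minlength=nb).astype(float)
    sc = np.bincount(bc, weights=yc, minlength=nb)
    ncb = np.bincount(bc, minlength=nb).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = sp / npb - sc / ncb
    return d  # nan where a bin is empty in either arm


def _bootstrap_stat(xp, yp, xc, yc, edges, n_boot, rng):
    out = np.empty(n_boot)
    n1, n2 = xp.size, xc.size
    for b in range(n_boot):
        i = rng.integers(0, n1, n1)
        j = rng.integers(0, n2, n2)
        d = _binned_mean_delta(xp[i], yp[i], xc[j], yc[j], edges)
        out[b] = np.nanmean(d)
    return out


def _bias_core(xp, yp, xc, yc, n_bins, n_boot, seed) -> BiasEstimate:
    edges = _quantile_bins(np.concatenate([xp, xc]), n_bins)
    d = _binned_mean_delta(xp, yp, xc, yc, edges)
    point = float(np.nanmean(d)) * 100.0
    rng = np.random.default_rng(seed)
    boot = _bootstrap_stat(xp, yp, xc, yc, edges, n_boot, rng) * 100.0
    lo, hi = np.percentile(boot, [2.5, 97.5])
    n_le = np.sum(boot <= 0.0)
    n_ge = np.sum(boot >= 0.0)
    p = 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1)
    return BiasEstimate(
        bias=point,
        ci95=(float(min(lo, point)), float(max(hi, point))),
        p_value=float(min(p, 1.0)),
        n_bins=int(edges.size - 1),
        per_bin=d,
        n_boot=n_boot,
    )


def _resolve_side(perturbed: Session, control: Session) -> str:
    sides = {s.inactivated_side for s in (perturbed, control)} - {"none"}
    if len(sides) > 1:
        raise ValueError("perturbed and control sessions disagree on the inactivated side")
    return sides.pop() if sides else "none"


def unilateral_bias(
    perturbed: Session,
    control: Session,
    n_bins: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> BiasEstimate:
    """Ipsilateral choice bias of a unilateral perturbation, in percentage
    points: trials are binned by signed (toward-ipsi) click difference into
    equal-count stimulus-strength bins; the per-bin difference in the
    fraction of ipsilateral choices (perturbed - control) is averaged over
    bins; CI/p by bootstrap over trials."""
    side = _resolve_side(perturbed, control)
    il = ipsi_is_left(side)

    def xy(sess):
        tr, x, yR = _trials_xy(sess.trials)
        y_ipsi = 1.0 - yR if il else yR
        x_ipsi = -x if il else x  # click difference signed toward ipsi
        return x_ipsi, y_ipsi

    xp, yp = xy(perturbed)
    xc, yc = xy(control)
    return _bias_core(xp, yp, xc, yc, n_bins, n_boot, seed)


def bilateral_impairment(
    perturbed: Session,
    control: Session,
    n_bins: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> BiasEstimate:
    """Performance impairment of a bilateral perturbation: mean over
    absolute-click-difference bins of (percent correct control - percent
    correct perturbed); positive = impaired.  Accumulation trials only."""

    def xy(sess):
        tr, x, yR = _trials_xy(sess.trials)
        correct = np.array([1.0 if t.choice == t.correct_side else 0.0 for t in tr])
        return np.abs(x), correct

    xp, yp = xy(perturbed)
    xc, yc = xy(control)
    est = _bias_core(xc, yc, xp, yp, n_bins, n_boot, seed)  # control minus perturbed
    return est


_EPOCHS = ("epoch_pre", "epoch_first_half", "epoch_second_half", "epoch_post")


def epoch_bias(
    session: Session,
    n_bins: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-epoch ipsilateral bias of time-resolved perturbation trials
    against the interleaved (perturbation='none') control trials of the
    same session.  Missing epochs are omitted with a warning."""
    controls = [t for t in session.trials if t.perturbation == "none"]
    out = {}
    for k, ep in enumerate(_EPOCHS):
        sub = [t for t in session.trials if t.perturbation == ep]
        if not sub:
            warnings.warn(f"no trials with epoch label {ep!r}; omitted")
            continue
        pert = Session(trials=sub, subject_id=session.subject_id,
                       inactivated_side=session.inactivated_side, session_role="perturbation")
        ctrl = Session(trials=controls, subject_id=session.subject_id,
                       inactivated_side=session.inactivated_side, session_role="control")
        out[ep.removeprefix("epoch_")] = unilateral_bias(pert, ctrl, n_bins, n_boot, seed + k)
    return out


def bias_difference(
    arm_a: tuple,
    arm_b: tuple,
    n_bins: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> BiasEstimate:
    """Paired bootstrap for the difference of two bias estimates, each arm a
    (perturbed, control) session pair; all four trial sets are resampled
    with replacement in every iteration."""
    def prep(pair):
        pert, ctrl = pair
        side = _resolve_side(pert, ctrl)
        il = ipsi_is_left(side)
        def xy(sess):
            tr, x, yR = _trials_xy(sess.trials)
            return (-x if il else x), (1.0 - yR if il else yR)
        xp, yp = xy(pert)
        xc, yc = xy(ctrl)
        edges = _quantile_bins(np.concatenate([xp, xc]), n_bins)
        return xp, yp, xc, yc, edges

    A = prep(arm_a)
    Bm = prep(arm_b)
    point = (np.nanmean(_binned_mean_delta(*A[:4], A[4])) - np.nanmean(_binned_mean_delta(*Bm[:4], Bm[4]))) * 100.0
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        vals = []
        for xp, yp, xc, yc, edges in (A, Bm):
            i = rng.integers(0, xp.size, xp.size)
            j = rng.integers(0, xc.size, xc.size)
            vals.append(np.nanmean(_binned_mean_delta(xp[i], yp[i], xc[j], yc[j], edges)))
        boot[b] = (vals[0] - vals[1]) * 100.0
    lo, hi = np.percentile(boot, [2.5, 97.5])
    n_le = np.sum(boot <= 0.0)
    n_ge = np.sum(boot >= 0.0)
    p = 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1)
    return BiasEstimate(bias=float(point), ci95=(float(min(lo, point)), float(max(hi, point))),
                        p_value=float(min(p, 1.0)), n_bins=n_bins, n_boot=n_boot)
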