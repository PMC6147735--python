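"""End-to-end demo pipeline: generate -> fit -> bias statistics -> neural
report, with machine-readable JSON outputs and figures.

Every stochastic stage derives its seed from the run configuration, so two
runs with the same configuration produce identical JSON outputs.  Each
output file embeds a provenance block (configuration hash and package
version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .behavior import fit_psychometric, unilateral_bias
from .fitting import fit_mle, tradeoff_ridge
from .likelihood import GridConfig
from .neural import (
    click_triggered_average,
    compute_psth,
    compute_tuning_curve,
    fit_tuning_sigmoid,
    model_joint_distributions,
    predict_cta_linear_encoding,
)
from .params import ModelParams
from .synthetic import EncodingSpec, GeneratorSpec, generate_behavior, generate_spikes

log = logging.getLogger("clickddm")

__all__ = ["RunConfig", "run_demo"]


@dataclass
class RunConfig:
    out_dir: str = "clickddm_demo"
    seed: int = 0
    n_trials: int = 800
    n_neurons_per_encoding: int = 4
    lapse_biased_shift: float = 0.3  # perturbation: extra ipsilateral lapse
    grid_dt: float = 0.025
    grid_bins: int = 31
    n_restarts: int = 2
    n_boot: int = 1000
    make_figures: bool = True
    control_params: dict = field(default_factory=lambda: asdict(
        ModelParams.symmetric(lam=-0.3, sigma2_a=2.0, sigma2_s=1.0, bound_B=7.0,
                              phi=0.5, tau_phi=0.08, lapse=0.2)))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "clickddm_version": __version__}


def _dump(cfg, out, name, payload):
    payload = {"provenance": _provenance(cfg), **payload}
    with open(Path(out) / name, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def run_demo(config: RunConfig | dict | None = None) -> Path:
    """Run the full synthetic pipeline; returns the report directory."""
    if config is None:
        config = RunConfig()
    elif isinstance(config, dict):
        config = RunConfig(**config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    log.info("run_demo: seed=%d out=%s hash=%s", config.seed, out, config.config_hash())

    grid = GridConfig(dt=config.grid_dt, n_bins=config.grid_bins)
    ctrl_params = ModelParams.from_dict(config.control_params)
    pert_params = ctrl_params.replace(
        lapse_total=ctrl_params.lapse_total + config.lapse_biased_shift,
        lapse_biased=ctrl_params.lapse_biased + config.lapse_biased_shift,
    )

    # ---- stage 1: behavior generation --------------------------------
    t0 = time.time()
    spec = GeneratorSpec(params_control=ctrl_params, params_perturbed=pert_params,
                         n_trials=config.n_trials, seed=config.seed)
    try:
        control, perturbed = generate_behavior(spec)
    except Exception as e:
        raise RuntimeError(f"stage 'generate_behavior' failed: {e}") from e
    log.info("generate_behavior: %.1fs", time.time() - t0)

    # ---- stage 2: psychometrics and bias -----------------------------
    t0 = time.time()
    try:
        psy_c = fit_psychometric(control)
        psy_p = fit_psychometric(perturbed)
        bias = unilateral_bias(perturbed, control, n_boot=config.n_boot, seed=config.seed + 1)
    except Exception as e:
        raise RuntimeError(f"stage 'behavior' failed: {e}") from e
    _dump(config, out, "behavior.json", {
        "psychometric_control": asdict(psy_c),
        "psychometric_perturbed": asdict(psy_p),
        "ipsilateral_bias_pct": bias.bias,
        "bias_ci95": list(bias.ci95),
        "bias_p": bias.p_value,
    })
    log.info("behavior: %.1fs (bias %.1f%%)", time.time() - t0, bias.bias)

    # ---- stage 3: model fit on the control arm -----------------------
    t0 = time.time()
    try:
        fit = fit_mle(control, n_restarts=config.n_restarts, seed=config.seed + 2,
                      grid=grid, init_params="staged", hessian_mode="forward")
        ridge = tradeoff_ridge(fit)
    except Exception as e:
        raise RuntimeError(f"stage 'fit' failed: {e}") from e
    _dump(config, out, "fit.json", {
        "params": fit.params.to_dict(),
        "loglik": fit.loglik,
        "ci95": fit.ci95,
        "bic": fit.bic(),
        "restarts": [{"seed": r.seed_index, "loglik": r.loglik,
                      "converged": r.converged,
                      "within_final_region": r.within_final_region} for r in fit.restarts],
        "tradeoff": {"eigenvalue": ridge.eigenvalue,
                     "noise_weights": list(ridge.noise_weights),
                     "eigenvector": dict(zip(ridge.names, ridge.eigenvector))},
    })
    log.info("fit: %.1fs (LL %.1f)", time.time() - t0, fit.loglik)

    # ---- stage 4: neural analyses ------------------------------------
    t0 = time.time()
    try:
        n_enc = config.n_neurons_per_encoding
        encodings = [EncodingSpec("linear", k1=3.0, k2=20.0) for _ in range(n_enc)]
        encodings += [EncodingSpec("step", threshold=0.0, low=10.0, high=30.0) for _ in range(n_enc)]
        recs, _ = generate_spikes(control, ctrl_params, encodings, seed=config.seed + 3)
        trials = control.trials
        psth = compute_psth(recs[0], trials)
        cta = click_triggered_average(recs[0], trials, preferred_side="R")
        pred = predict_cta_linear_encoding(ctrl_params, k1=3.0, k2=20.0, n_trials=1000,
                                           seed=config.seed + 4, lag=0.15)
        joints = model_joint_distributions(trials, ctrl_params, grid)
        slopes = {}
        for kind, subset in (("linear", recs[:n_enc]), ("step", recs[n_enc:])):
            vals = []
            for r in subset:
                curve = compute_tuning_curve(r, trials, ctrl_params, joints=joints)
                vals.append(fit_tuning_sigmoid(curve).slope_at_zero)
            slopes[kind] = vals
    except Exception as e:
        raise RuntimeError(f"stage 'neural' failed: {e}") from e
    _dump(config, out, "neural.json", {
        "cta_lags": cta.lags.tolist(),
        "cta_mean": np.nan_to_num(cta.mean).tolist(),
        "cta_se": np.nan_to_num(cta.se).tolist(),
        "cta_prediction": np.nan_to_num(pred.mean).tolist(),
        "tuning_slope_at_zero": slopes,
    })
    log.info("neural: %.1fs", time.time() - t0)

    if config.make_figures:
        _figures(out, control, perturbed, psy_c, psy_p, cta, pred, slopes, psth)

    _dump(config, out, "report.json", {
        "elapsed_s": time.time() - t_start,
        "stages": ["generate_behavior", "behavior", "fit", "neural"],
        "n_trials": config.n_trials,
    })
    log.info("run_demo finished in %.1fs", time.time() - t_start)
    return out


def _figures(out, control, perturbed, psy_c, psy_p, cta, pred, slopes, psth):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    ax = axes[0, 0]
    for sess, psy, color, label in ((control, psy_c, "k", "control"),
                                    (perturbed, psy_p, "m", "perturbed")):
        tr = [t for t in sess.accumulation_trials() if t.choice != "none"]
        x = np.array([t.click_diff for t in tr])
        y = np.array([t.choice == "R" for t in tr], dtype=float)
        xs = np.unique(x)
        ax.plot(xs, [y[x == v].mean() for v in xs], "o", ms=3, color=color, alpha=0.5)
        gx = np.linspace(x.min(), x.max(), 200)
        ax.plot(gx, psy.predict(gx), color=color, label=label)
    ax.set(xlabel="#R - #L clicks", ylabel="P(choose right)", title="psychometric")
    ax.legend(frameon=False, fontsize=8)

    ax = axes[0, 1]
    for g in range(psth.rates.shape[0]):
        ax.plot(psth.time, psth.rates[g], label=f"strength q{g + 1}")
    ax.set(xlabel="time (s)", ylabel="normalized rate", title="PSTH by stimulus strength")
    ax.legend(frameon=False, fontsize=7)

    ax = axes[1, 0]
    ax.fill_between(cta.lags, cta.mean - 2 * cta.se, cta.mean + 2 * cta.se, alpha=0.3)
    ax.plot(cta.lags, cta.mean, label="synthetic neuron")
    ax.plot(pred.lags, pred.mean, "r--", label="linear-encoding prediction")
    ax.axhline(0, color="gray", lw=0.5)
    ax.set(xlabel="lag from click (s)", ylabel="residual rate (Hz)", title="click-triggered average")
    ax.legend(frameon=False, fontsize=8)

    ax = axes[1, 1]
    ax.hist(slopes["linear"], bins=8, alpha=0.6, label="linear encoders")
    ax.hist(slopes["step"], bins=8, alpha=0.6, label="step encoders")
    ax.set(xlabel="tuning slope at zero (Hz/click)", ylabel="# neurons", title="graded vs step")
    ax.legend(frameon=False, fontsize=8)

    fig.tight_layout()
    fig.savefig(Path(out) / "report.png", dpi=110)
    plt.close(fig)
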