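"""Model-based neural analyses: click-triggered averages and tuning curves.

Generates spikes from synthetic neurons that encode the latent accumulator
either linearly (graded) or as a step, then shows that (i) the linear
encoders' click-triggered average matches the model's sustained-step
prediction, and (ii) the tuning-curve sigmoid slope at zero separates the
two encodings.
"""

import numpy as np

import clickddm as cd
from clickddm.likelihood import GridConfig
from clickddm.neural import (
    click_triggered_average,
    compute_tuning_curve,
    fit_tuning_sigmoid,
    model_joint_distributions,
    predict_cta_linear_encoding,
)
from clickddm.synthetic import EncodingSpec, generate_spikes

# low-noise regime: the model's moment-by-moment evidence estimate is sharp,
# so the tuning analysis can resolve the encoding's shape
params = cd.ModelParams.symmetric(
    lam=-0.1, sigma2_a=0.5, sigma2_s=0.25, bound_B=6.0, phi=0.8, tau_phi=0.1, lapse=0.05
)
K1, K2, LAG = 3.0, 20.0, 0.15

session = cd.generate_stimulus_session(300, seed=31, motor_fraction=0.0)
encodings = [EncodingSpec("linear", k1=K1, k2=K2)] * 8
encodings += [EncodingSpec("step", threshold=0.0, low=K2 - 10, high=K2 + 10)] * 8
recordings, _ = generate_spikes(session, params, encodings, lag=LAG, seed=32)

cta = click_triggered_average(recordings[0], session.trials, preferred_side="R")
pred = predict_cta_linear_encoding(params, k1=K1, k2=K2, n_trials=2000, seed=33,
                                   lag=LAG, duration_law="uniform")
pre = np.nanmean(cta.mean[cta.lags < LAG])
post = np.nanmean(cta.mean[cta.lags > LAG + 0.05])
post_pred = np.nanmean(pred.mean[pred.lags > LAG + 0.05])
print("click-triggered average of one linear-encoding neuron:")
print(f"  pre-latency mean residual  {pre:+.2f} Hz (should be ~0)")
print(f"  post-latency sustained step {post:+.2f} Hz   prediction {post_pred:+.2f} Hz")
print("a single click adds a fixed, persistent increment to the accumulator,")
print("so a graded encoder shows a sustained step after the neural latency.")

grid = GridConfig(dt=0.01, n_bins=101)
joints = model_joint_distributions(session.trials, params, grid)
slopes = {"linear": [], "step": []}
for kind, subset in (("linear", recordings[:8]), ("step", recordings[8:])):
    for rec in subset:
        curve = compute_tuning_curve(rec, session.trials, params, lag=LAG,
                                     grid=grid, joints=joints)
        slopes[kind].append(fit_tuning_sigmoid(curve).slope_at_zero)
print("\ntuning sigmoid slope at zero-crossing (k2*k3/4), Hz per click:")
for kind in ("linear", "step"):
    v = np.array(slopes[kind])
    print(f"  {kind:6s}: median {np.median(v):.2f}  range [{v.min():.2f}, {v.max():.2f}]")
print(f"linear encoders recover ~k1 = {K1}; step encoders are markedly steeper.")
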