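# Methods

## The behavioral model

`clickddm` models fixed-duration Poisson-clicks decisions with a bounded
drift-diffusion accumulator. Within a trial, the latent evidence variable
$a(t)$ starts at 0 and evolves as

$$
da \;=\; \lambda a\,dt \;+\; \sigma_a\,dW \;+\;
\big(\delta_{t,t_R}\,\eta_R\,C \;-\; \delta_{t,t_L}\,\eta_L\,C\big)\,dt ,
\qquad |a|\ge B \Rightarrow da = 0 ,
$$

with sticky (absorbing) bounds at $\pm B$. Each click delivers an impulse
whose amplitude $C$ is subject to shared sensory adaptation,

$$
\frac{dC}{dt} = \frac{1-C}{\tau_\phi} + (\phi - 1)\,C\,(\delta_{t,t_R}+\delta_{t,t_L}),
$$

i.e. $C$ relaxes to 1 with time constant $\tau_\phi$ and is multiplied by
$\phi$ immediately after each click ($\phi<1$ depression, $\phi>1$
facilitation). A click's own impact uses the pre-multiplication amplitude;
simultaneous left/right clicks are processed left-then-right (arbitrary but
fixed). Per-click multiplicative noise is $\eta \sim N(1, \sigma_s)$, so a
click's displacement has mean $\pm 2 w C$ and SD $2 w C \sigma_s$, where
$w$ is the input-gain weight ($g_w$ for ipsilateral clicks, $1-g_w$
contralateral; $g_w = 0.5$ gives unit-magnitude clicks on both sides).
An alternative reading in which the click *variance* (rather than the SD)
scales with $C$ is available behind the config switch used in the click
kernel, but the displayed-equation semantics above are the default.

At stimulus end the model chooses right when $a(T) > þ$ (the accumulator
threshold bias). Lapses are lateralized: a model-contralateral
categorization becomes an ipsilateral choice with probability $\kappa_C$,
a model-ipsilateral one flips with probability $\kappa_I$; the fitted
coordinates are $\kappa_C, \kappa_I \in [0,1]$, reported also as total
($\kappa_C+\kappa_I$) and biased ($\kappa_C-\kappa_I$) lapse.
"Ipsi/contra" is defined by the perturbed hemisphere recorded on the
session; unperturbed sessions use a fixed canonical mapping that is inert
at the symmetric parameter values.

The 11 parameters are $\lambda$ (1/s), $\sigma_a^2$ (clicks²/s),
$\sigma_{s,I}^2$, $\sigma_{s,C}^2$ (per-click, unitless), $B$ (clicks),
$\phi$, $\tau_\phi$ (s), $þ$ (clicks), $\kappa_C$, $\kappa_I$, $g_w$.
The noise-free limit ($\sigma_a^2=\sigma_s^2=0$, $\lambda=0$, $\phi=1$,
$þ=0$, no lapse) reproduces the ideal observer $a(T) = \#R - \#L$ exactly.

## Likelihood by distribution propagation

Per-trial choice probabilities are computed by propagating the probability
distribution $P(a,t)$ directly, not by Monte Carlo. The accumulator axis
uses `n_bins` interior bins (odd, width $dx = 2B/(n_\text{bins}+1)$, center
bin at $a=0$) plus two absorbing masses at $\pm B$; time advances in steps
of `dt` with clicks snapped to the nearest step boundary (adaptation
amplitudes use exact click times). Defaults: `dt = 0.01 s`, `n_bins = 201`.

Numerical scheme (all computed in bin units, so the bound $B$ enters only
through smooth scalar factors):

- **Drift** multiplies bin centers by the exact factor $e^{\lambda\,dt}$,
  with a mean-preserving two-bin split of each bin's mass.
- **Diffusion** convolves with a discrete Gaussian built from normal-CDF
  differences, with tails folded into the end taps so the kernel sums to
  exactly 1 (mass conservation is exact by construction).
- **Clicks** convolve with a Gaussian kernel of mean $\pm 2wC/dx$ and
  variance $(2wC\sigma_s/dx)^2$.
- Two corrections keep the first two moments essentially exact: the
  kernel's target variance is reduced by $1/12$ bin² (Sheppard's correction
  for binning), and the spurious variance injected by each two-bin split
  ($r(1-r)$ per unit mass) is subtracted from a running *pending variance*
  budget. Convolution is deferred until at least $\approx 0.33$ bin² of
  variance is pending, so narrow kernels are never built; per-step variance
  injection uses the exact Ornstein-Uhlenbeck increment
  $\sigma_a^2 (e^{2\lambda dt}-1)/(2\lambda)$.

With these corrections the no-click propagation matches OU closed forms to
about $10^{-4}$ relative, and halving `dt` and the bin width changes choice
probabilities by less than $10^{-3}$ (the refinement-convergence test).
P(right) reads out the mass strictly above $þ$ plus a proportional share of
the bin containing it, followed by the lapse mixing
$p_\text{contra} = \kappa_I + (1-\kappa_C-\kappa_I)\,p_\text{contra,model}$.
Trials are independent; sessions concatenate (meta-subject pooling). A
trial whose observed choice has probability 0 yields $-\infty$ with a
diagnostic naming the trial; the fitting objective instead adds a
$10^{-12}$ floor inside the log so that optimization remains well behaved
in degenerate corners.

**Gradients.** All 11 partials are propagated *forward-mode* through the
same recursion: eight tangent rows (for $\lambda$, $\sigma_a^2$, the two
$\sigma_s^2$, $B$, $\phi$, $\tau_\phi$, $g_w$) accompany the mass vector,
with kernel-derivative source terms; $þ$, $\kappa_C$, $\kappa_I$ enter
analytically at readout. The tangents are exact derivatives of the
discretized likelihood (machine precision); the normative check is
agreement with central finite differences to $10^{-4}$ relative. The
discretization leaves micro-kinks in the likelihood surface (bin-edge
crossings, deferred-convolution scheduling); derivatives at such measure-zero
points are one-sided.

## Fitting

All 11 parameters are fitted simultaneously by gradient-based maximization
in an unbounded space: each parameter is mapped through a tanh bijection
$\theta = \text{lo} + (\text{hi}-\text{lo})(1+\tanh\alpha)/2$ with generous
default boxes ($\lambda \in [-10,10]$, $\sigma_a^2 \in [0,200]$,
$\sigma_s^2 \in [0,20]$, $B \in [1,30]$, $\phi \in [0.01,1.5]$,
$\tau_\phi \in [0.005,1.5]$ s, $þ \in [-5,5]$, $\kappa \in [0,1]$,
$g_w \in [0,1]$). Restart seeds are drawn uniformly from the unbounded
image of a configured *plausible* box (e.g. $\sigma_a^2 \in [0.5, 30]$)
rather than the full transform box, which keeps starting points out of the
saturated tanh tails. An optional staged initialization first fits the
left/right-symmetric reduced model (tied sensory noise and lapse, balanced
gain, on a strided trial subsample) from a fixed neutral start and releases
the asymmetry parameters from there; it is cheap, deterministic, and lands
the full fit in the global basin far more reliably than random restarts of
the same budget.

The accepted optimum must have a positive semidefinite Hessian of the
negative log-likelihood. The Hessian is finite-differenced from the
analytic gradient with a deliberately large step (0.05 in unbounded
coordinates) that averages over the discretization's micro-kinks while
staying below the curvature scale of the peak. Small negative eigenvalues
(finite-difference noise in near-flat directions) are clipped to a tiny
positive floor — equivalent to reporting a very wide interval along that
direction; clearly negative eigenvalues trigger a saddle-escape step along
the offending eigenvector followed by re-optimization.

Under a flat prior, the normalized likelihood is treated as the parameter
posterior. Confidence intervals are Gaussian in the unbounded coordinates
(covariance = inverse Hessian) and mapped back through the tanh bijection,
hence asymmetric and bound-respecting — a noise variance fitted at 0 gets a
lower CI limit of exactly 0. Restart diagnostics record whether each
endpoint lies within the final 95% region (Mahalanobis distance vs.
$\chi^2_{k}(0.95)$). Trade-off ridges are the leading eigen-pair of the
bounded-coordinate covariance; the reported noise weights $(w_1, w_2)$ are
the eigenvector's $(\sigma_a^2, \sigma_s^2)$ components renormalized to
unit norm over that pair — one concrete reading of a weighted-noise summary
whose construction is otherwise underdetermined. 2-D likelihood landscapes
are slices through the optimum (the other nine parameters held fixed), with
cumulative flat-prior mass contours at 50/75/95%; a profile mode exists as
an option. Model comparison uses $\text{BIC} = k\ln n - 2\,\text{LL}$ with
$k$ the number of free parameters.

## Behavioral statistics

Psychometric curves fit
$y = y_0 + a/(1+e^{-(x-x_0)/b})$ to the per-click-difference fraction of
rightward choices by weighted least squares (weights = trial counts;
deterministic initialization $x_0 = \text{median}(x)$, $b = \text{range}/8$,
$y_0 = \min y$, $a = \max y - \min y$); near-flat data is flagged
degenerate.

Perturbation effects are averaged over 10 equal-count stimulus-strength
bins (quantiles of the signed toward-ipsi click difference for unilateral
bias; of the absolute difference for bilateral performance, where no
lateral mapping exists). The unilateral bias is the mean per-bin difference
in the fraction of ipsilateral choices (perturbed − control), in percentage
points; the bilateral impairment is the mean per-bin drop in percent
correct. Bin edges are computed once from the pooled arms and held fixed;
empty bins merge into neighbors with a warning. Confidence intervals and
p-values come from a nonparametric bootstrap over trials (1000 iterations,
percentile CIs; p is twice the smaller tail fraction with add-one
smoothing). Because the two arms are resampled independently, the p-value
for literally identical arms is "clearly non-significant" rather than
exactly 1. Epoch-resolved biases compare each 500-ms epoch's trials with
the interleaved controls of the same session; paired condition differences
resample all four trial sets per iteration.

## Neural analyses

Rate functions are spike trains binned at 10 ms and smoothed with a causal
half-Gaussian (SD 0.1 s, truncated at 4 SD, weights on the past only).
PSTHs normalize by the neuron's mean rate in a 50 ms window at stimulus
onset (falling back, flagged, to unnormalized for silent-onset neurons) and
average within four equal-count quantiles of the signed
preferred-minus-nonpreferred generative click rate. Side selectivity is a
rank-sum test on fixation-window spike counts split by upcoming choice
(undetermined below 5 trials per class or for silent neurons).

The click-triggered average groups trials by their generative rate pair,
subtracts each group's mean response to form residuals, aligns residual
snippets to every click (non-preferred-side snippets sign-inverted) and
averages over clicks, then over groups (lags −0.1 to +0.3 s; groups with
fewer than 10 trials are dropped with a warning). The linear-encoding
prediction simulates 5000 accumulator trajectories with the data's
difficulty range and duration law, encodes them as
$r = k_1 a(t) + k_2$ (rectified), and pushes the noise-free rates through
the identical pipeline — under leak-free accumulation each click produces a
fixed-magnitude, sustained step, which attenuates at long lags when sticky
bounds dominate.

Tuning curves relate firing to the model's moment-by-moment evidence
estimate: the forward distributions $P(a,t)$ (purely stimulus-driven, *not*
conditioned on the observed choice; a choice-conditioned mode would be a
straightforward reweighting) are rebinned onto a coarse grid (equal-width
interior bins plus dedicated $\pm B$ bins; 50-ms time bins), and combined
with each trial's spike counts at $t + \text{lag}$ (lag 0.15 s by default,
standing in for the neural response latency; it can also be re-estimated
from the first significantly stimulus-modulated PSTH bin). Per neuron,
$E[r \mid a, t]$ = P-weighted mean rate; cells with pooled mass below a
threshold are masked (undefined, not zero). Neurons pool by inverse
conditional variance, and the summary curve averages $t \in [0.15, 0.5]$ s.
A four-parameter sigmoid $r = k_1 + k_2/(1+e^{-k_3(a-k_4)})$ summarizes
each neuron; its zero-crossing slope $k_2 k_3 / 4$ separates graded from
step-like encodings. Note the separation is only as sharp as the model's
belief about $a$: under heavy accumulator/sensory noise the forward
distributions blur a step into an apparent slope comparable to a graded
encoder's, so the encoding-discrimination demonstrations use a low-noise
regime ($\sigma_a^2 = 0.5$, $\sigma_s^2 = 0.25$, mild adaptation) where the
estimate is sharp.

## Synthetic data

The generator reproduces the study conditions: two independent Poisson
click trains with combined mean rate 40 Hz; difficulty drawn uniformly from
rate ratios 39:1 (easiest) to 26:14 (hardest) — endpoints fixed by the
task, intermediate levels an evenly spaced interpolation (38, 32, 24, 18,
12 clicks/s differences); durations uniform on [0.1, 1.2] s
(electrophysiology/pharmacology style) or fixed at 1 s (optogenetics
style); ~10% motor-control trials with no clicks and a cued side. Choices
come from the accumulator model. Perturbed arms either swap in a perturbed
parameter vector globally (pharmacology style) or attenuate contralateral
click gain inside a 500-ms window (optogenetics style) — the fitted model
has no temporally resolved parameters, so the windowed mechanism is an
explicitly labeled stand-in; windowed extra noise or lapse would be equally
valid choices.

Spikes are inhomogeneous Poisson with rate $\text{enc}(a(t-\text{lag}))$
rectified at 0, where the latent trajectory is the *same single
realization* that produced the trial's choice (one path per trial, shared
across neurons — behavior and firing are coupled through one latent state,
and pre-latency firing reflects $a = 0$). Everything is deterministic given
the master seed.

What the generator does *not* emulate: electrode drift and sorting errors,
non-Poisson spiking history, within-session learning, reaction-time
structure, or any true temporally-windowed change in the accumulator's
parameters. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration on data that satisfy the model's assumptions,
not the adequacy of the model for any particular animal.

## Problem sizes and numerical defaults used by the test-suite demonstrations

- Oracle equivalence: 20 trials, $10^5$ Monte Carlo samples each (Euler
  step 5 ms), default likelihood grid; agreement to |Δp| < 0.01.
- Parameter recovery: 10 independent replications of 5000 trials fitted at
  a reduced grid (`dt = 0.025 s`, 31 bins) with staged initialization — the
  resolution/runtime trade-off chosen for batch fitting; the
  refinement-convergence test quantifies the discretization error.
- Bias calibration: 200 null replicates of 400 + 400 trials, 1000 bootstrap
  iterations each.
- Encoding discrimination: 64 linear + 64 step neurons over 500 shared
  trials, tuning grid `dt = 0.01`, 101 bins.

## Known limitations

- The likelihood surface has measure-zero kinks from the discretization;
  the optimizer and the large-step Hessian are built to tolerate them, but
  derivative checks exactly at a bin-edge coincidence will see one-sided
  slopes.
- Laplace intervals are quadratic approximations; for strongly ridged
  posteriors (e.g. the accumulator-vs-sensory noise trade-off) they are
  locally faithful but can under- or over-cover along curved ridges.
- The per-click noise SD scales with the gain-adapted magnitude (including
  the input gain), which is one of two defensible readings of the model's
  noise scaling.
- Epoch-specific (time-windowed) parameters are not fittable; the windowed
  generator mechanisms plus the descriptive epoch-bias statistic are the
  supported analyses.
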