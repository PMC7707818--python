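# Methods

## Generative model

The reward-sensitive Gaussian process (RSGP) treats the relative-error series
e^1..e^N of one task context as jointly Gaussian with covariance

K_RSGP = σ_SE²·K_SE + σ_RS²·K_RS + σ_0²·I,

where K_SE(r) = exp(−r²/2l_SE²) and K_RS(n, n−r) = exp(−r²/2l_RS²) if trial
n−r was rewarded and 0 otherwise. Generation is sequential: trial n is drawn
from the Gaussian conditional given all previous trials and their (binary)
reward outcomes, the reward rule is applied to the realised t_p, and the
reward-gated kernel is extended. Reward enters the kernel strictly as a
binary variable even when the schedule pays graded reward.

Assumptions worth making explicit:

* **Within-context unit lag.** Trials of one context are treated as
  consecutive samples regardless of interleaved trials of other contexts.
  Length scales are therefore in units of same-context trials, not wall-clock
  trials.
* **Constant mean.** The GP is fit on the mean-centred error of the context;
  the mean is restored on prediction. The slow component therefore models
  drift *around* the session mean, not a global bias.
* **K_RS diagonal = 1.** A trial's own reward is unknown at generation time,
  so the reward gate applies only to cross-covariances with past trials; the
  prior marginal variance is the constant σ_SE² + σ_RS² + σ_0².
* **Earlier-trial gating and positive-definiteness.** Gating the
  cross-covariance on the earlier trial's reward does not guarantee a PSD
  matrix for arbitrary reward patterns. At realistic hyperparameters the
  σ_0² ridge dominates; factorizations add an escalating diagonal jitter
  (starting at 1e−8 of the mean diagonal), and during hyperparameter search
  parameter regions whose covariance remains indefinite after jitter are
  rejected by a large finite penalty.

## Fitting

Hyperparameters (l_SE, σ_SE, l_RS, σ_RS, σ_0) maximize the Gaussian log
marginal likelihood. Direct five-parameter search from arbitrary starts is
poorly conditioned, so fitting is two-step:

1. (l_SE, σ_SE, σ_0) on the subsequence of *unrewarded* trials (where the
   reward kernel contributes nothing off-diagonal) with σ_RS clamped;
2. all five parameters on the full series, initialized from step 1.

Optimization is L-BFGS-B on log-parameters with analytic gradients
(dL/dθ = ½·tr[(ααᵀ − K⁻¹)·∂K/∂θ]), bounds l ∈ [0.5, 500] trials and
σ ∈ [1e−4, 1], and a configurable number of random restarts (default 3;
the gradient is unit-tested against finite differences). If nearly all
trials share one outcome the fit falls back to a single joint step with a
warning.

Identifiability note: when the true σ_RS is 0, its maximum-likelihood
estimate sits on the boundary and is biased upward at finite n (observed
ratio σ̂_RS/σ_0 ≈ 0.2–0.3 at n = 1000). "No reward sensitivity" should be
read from the variance share σ̂_RS²/total, not the raw value.

The slow component is the posterior mean of the SE part under the full
covariance, e_slow = mean(e) + σ_SE²·K_SE·K_RSGP⁻¹·(e − mean(e)); the fast
component is the residual.

## Task simulator

The Cue-Set-Go environment interleaves four contexts uniformly at random
(eye/hand × 800/1500 ms). Reward is a truncated triangular function of
error, maximum 0.5 ml at e = 0, zero at the acceptance window. The window
half-width follows a one-up-one-down staircase with fixed steps of 8 ms
(800 ms target) and 15 ms (1500 ms target), floor 1 ms, initial width 10% of
t_t; for any stationary agent this calibrates reward to ≈50%. The
probabilistic variant gives binary 'correct' feedback with probability
0.7/0.3 inside/outside a fixed window, which `calibrate_window` sets from
pilot variability (an |e| quantile) so the marginal correct rate is ~50%.
Inter-trial intervals default to a constant 3 s so the 7-s pair-exclusion
rule is exercisable; human-style sessions draw one t_t per session from
N(800, 80) ms clamped positive.

## Comparison models

**MCMC sampling.** One internal target t*; proposals t⁺ ~ N(t*, W_e·t_t);
production t_p ~ N(t⁺, W_p·t⁺) (scalar noise); the proposal's value is the
reward of the realised t_p (value and execution noise deliberately
conflated); acceptance follows the softmax rule e^{βV⁺}/(e^{βV⁺}+e^{βV*}).
Defaults W_e = 0.1, W_p = 0.05 (fractions of t_t), β = 100. The incumbent's
stored value is refreshed whenever a proposal is accepted; with an
ever-growing "best value" the chain would freeze and lose the positive
mean-error slope the model is meant to exhibit. Because the accepted-target
process is a gated random walk, the model produces genuine mid-lag partial
correlations; what separates it from the RSGP is the absence of the
U-shaped σ(e^n) profile, not the correlation range.

**Directed search.** t*ⁿ = t*ⁿ⁻¹ + α·(t*ⁿ⁻¹ − t*ⁿ⁻²)·(rⁿ⁻¹ − rⁿ⁻²) + n_e,
with n_e ~ N(0, W_e·t_t) and production noise W_p·t_t; the first two trials
start at t_t. Defaults α = 2.0 per (ml·ms), W_e = 0.02, W_p = 0.05 — scaled
so a full reward swing (0.5 ml) over a typical interval step moves the
target by ~2% of t_t; all three are config-exposed and the run-away analysis
should be read as a function of them, not at one point. Because reward is
evaluated at the noisy t_p, the reward gradient is noise-dominated away from
the reward peak; the internal target therefore diffuses, and run-away
episodes (window at t_t ± 0.3·t_t with > 20 consecutive misses) occur in a
parameter-dependent fraction of 2000-trial sessions. Statistics over
surviving simulations must be pooled with per-simulation normalization:
heterogeneous excursion levels otherwise manufacture a spurious positive
quadratic coefficient in edge bins.

## Behavioral statistics

Pairs (e^{n−1}, e^n) are consecutive completed trials no more than 7 s
apart, with trials beyond 3 SD of their context's t_p mean removed, grouped
as same-type / same-effector / different-effector. e^{n−1} is cut into 10
equal-count bins (merged below 20 pairs each; the bin count is
config-exposed and moving between 8 and 12 bins shifts s2 by less than its
CI half-width at n = 20000 pairs). The mean model μ(e^n) = m0 + m1·e^{n−1}
is fit on raw pairs by default (a binned mode exists); the SD model
σ(e^n) = s0 + s1·e^{n−1} + s2·(e^{n−1})² is fit on per-bin SDs weighted by
bin counts. Confidence intervals are two-sided at the 1%/99% t-quantiles.
Partial autocorrelation uses a successive autoregressive (Yule-Walker) fit
up to lag 60 with null bounds at 2.5 SD of shuffled-series coefficients;
cross-context correlations z-score t_p per session, pair trials at a fixed
session lag, and take 1%/99% bounds from 100 identity shuffles. When
heterogeneous sessions are pooled, errors are z-scored per session first.

## Synthetic neural data

The spike-count generator is a synthetic stand-in for population
recordings: 17 neurons (the scale of a typical simultaneously recorded
population), Poisson counts in a 250 ms pre-Set window, baseline ~10
counts. Log rates are modulated along a planted unit direction b by
gain·e_slow plus a shared latent noise; a second latent acts along an
orthogonal direction. In the `thalamus_like` profile the shared noise along
b is scaled by 0.5 after rewarded and 1.6 after unrewarded trials (variance
regulated along the drift direction); `cortex_like` applies the same scaling
to the orthogonal direction instead. The gain (5 per unit relative error)
and noise SD (0.35) were chosen once so that a single 1000-trial session
supports both reliable decoding and a detectable variance modulation, with
counts in the physiological 5–20 range. What the generator does *not*
emulate: tuning heterogeneity, count overdispersion beyond Poisson,
slow non-behavioral rate drift, and correlated noise beyond the two planted
latents — so passing tests show the pipeline's statistical machinery works,
not that real populations behave this way.

Decoding regresses e_slow on counts (plain least squares when trials ≥ 4 ×
neurons, else ridge with a held-in-CV penalty), using a random half of
trials for fitting and the other half for evaluation; significance of the
held-out Pearson correlation is judged against the 1%/99% quantiles of 100
target-shuffle refits. The projection z = rβ + β0 is then analyzed with the
same binning/regression machinery as behavior, with z replacing e^n.

## Problem sizes and numerical choices

Library defaults: 2000-trial sessions, 10 equal-count bins, 100 shuffles for
nulls, 3 fit restarts. The test suite runs the hyperparameter-recovery check
as 10 seeds × 500 trials with one restart (median of each parameter within a
factor of two of truth) and pools four 1500-trial sessions for the
behavioral and neural pattern checks; the acceptance script runs the single
2000-trial fit, four 1500-trial behavioral sessions, 4 × 5000 MCMC trials,
12 × 2000 DS sessions, and four 1000-trial × 17-neuron populations. All
randomness flows from explicit integer seeds; covariance factorizations use
escalating diagonal jitter from 1e−8 of the mean diagonal; conditional
variances are floored at 1e−12.

## Known limitations

* The literal RSGP at l_SE = 20 produces partial correlations that are
  *positive* over ~20 lags but *significant* (against a 2.5-SD shuffle null)
  over only ~11–13 lags; the population PACF of the generating process
  crosses zero near lag 18, so longer significance ranges require longer
  (or mixed) length scales, as real behavioral datasets exhibit.
* Earlier-trial reward gating can produce an indefinite covariance for
  adversarial reward patterns; jitter handles all realistic cases but exact
  PSD is not guaranteed.
* A directed-search regime combining a moderate mean-error slope with a
  slightly negative quadratic coefficient was not reachable anywhere in the
  (α, W_e) grid we scanned; with reward evaluated at the noisy produced
  interval the model is diffusive and its quadratic coefficient hovers near
  zero. Conclusions about it should remain qualitative.
* Fitting cost is O(n³) per likelihood evaluation; sessions beyond a few
  thousand trials per context call for subsampling or sparse approximations
  that are out of scope here.
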