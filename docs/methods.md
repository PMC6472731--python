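# Methods

## Generative model of the task

A trial presents N = 4 oriented stimuli at fixed locations. Target presence
T is Bernoulli(1/2); on present trials one location, uniform over the four,
holds a target. Target orientations are Normal(+μ_target, σ_external) and
distractor orientations Normal(−μ_target, σ_external), in degrees, clockwise
positive, vertical = 0; σ_external = 0 degenerates to fixed tilts of exactly
±μ_target. Each display's number of high-reliability items is uniform on
{0, …, 4}, with labels randomly permuted over locations. The observer's
measurement of item i is x_i = s_i + ε_i with ε_i ~ Normal(0, σ_i), where
σ_i ∈ {σ_low, σ_high} follows the item's reliability label. Orientations are
treated as plain (non-circular) degrees: all noise levels in play are well
below the scale at which wrapping matters, so a Gaussian noise model is an
excellent approximation to a circular one and much more convenient.

Two display regimes: *short* (sensory noise levels are properties of the
observer, fitted), and *unlimited* (sensory noise fixed by the condition to
0 or to an empirically calibrated 0.875°). Standard trial counts are 1500
(short) and 500 (unlimited) per condition.

## Observer models

All models compare a scalar decision variable d(x) against a threshold and
mix in a lapse rate λ (probability of a fair random guess, applied last:
p = λ/2 + (1−λ) p_core).

Bayesian family. The optimal ("flawless Bayesian") rule averages local
evidence ratios d_local(x_i) = exp[2 μ_target x_i / (σ_i² + σ_external²)]
and takes the log; threshold 0 is optimal by construction. The *ignorant
Bayesian* replaces the item-specific σ_i with a single fitted σ_single,
removing reliability weighting. *Imperfect* variants add late noise
η ~ Normal(μ_late, σ_late) to d; μ_late captures computational bias.

Heuristic family. Statistics of the observations with a fitted criterion c:
max x_i; min |x_i − μ_target|; the Minkowski distance
(Σ |x_i − μ_target|^β)^{1/β}; the mean; and the population variance (1/N
normalization, matching the statistic's printed definition). For the two
deviation-based statistics a *small* value is evidence for a target, so the
decision direction is inverted ("present" when d < c); the direction is
implicit in the statistic's meaning, and we fix it this way for
determinism. Imperfect heuristic variants add zero-mean late noise only
(bias is already absorbed by c).

Sampling read-out. The posterior p(T=1|x) = e^d/(1+e^d) is read out by n
Bernoulli samples; "present" wins if successes exceed failures, with even-n
ties resolved by a fair coin (ties are not covered by the verbal rule; a
fair coin is the symmetric choice). As n → ∞ this converges to the exact
Bayesian rule.

Ties d = threshold respond "absent" (measure-zero under noise; fixed for
reproducibility).

## Likelihood and fitting

The probability of a recorded response given the presented stimuli
marginalizes over x. In the short regime this is Monte Carlo: n_mc draws of
x per trial using one fixed block of standard-normal deviates reused at
every parameter value (common random numbers), which makes the likelihood
surface deterministic and optimizable with a derivative-free method. Late
noise and the sampling read-out are always integrated analytically
(Gaussian CDF; exact binomial tail), so the only sampled quantity is x. In
the unlimited regime with σ_i = 0 the observations equal the stimuli and
the likelihood is closed-form with no Monte Carlo. Per-trial probabilities
are floored at 10⁻⁶.

Fitting maximizes log-likelihood plus (optionally) log prior by Nelder-Mead
on a bounded reparameterization (scale parameters log-transformed), best of
multiple restarts drawn from the plausible boxes: σ ∈ [0.1, 30]°,
λ ∈ [0, 0.5] (constrained) or [0, 1] (unconstrained), μ_late ∈ [−5, 5],
σ_late ∈ (0, 10], β ∈ [0.25, 10], criterion within the observed range of
the heuristic statistic (±25% padding). The sampling model's integer n is
fitted by discrete search over a log-spaced grid {1, 2, 3, 5, …, 501},
optimizing the continuous parameters at each grid point. Any derivative-free
multi-start local optimizer would do here; the functional contract is "best
of several restarts on a CRN likelihood", and the default is 10 restarts.

Priors (constrained regime, Bayesian models; optionally extended to the
lapse of heuristic models as the "constrained Max" variant): Normal on
log σ_low and log σ_high centered at the subject's discrimination-task
estimates with SD 0.25 log-units, and Beta(1, 24) on λ (mean 0.04,
mode 0). The exact prior families are a design choice of this package —
they encode "sensory noise near the independently measured value, lapses
small" — and are configurable. AIC = 2k − 2 log L uses the pure
log-likelihood at the MAP point, so constrained and unconstrained fits are
comparable on one scale; k is the model's free-parameter count in the
fitted regime. Cross-validation uses a random equal k-partition (k = 5 by
default) with a recorded seed; each fold is scored at parameters fitted to
its complement and the held-out log-likelihoods are summed.

## Model comparison and recovery

ΔAIC is taken per dataset relative to the best model, with ΔAIC ≥ 10
annotated as "no support". In the unlimited no-noise regime the ignorant
models coincide with their reliability-weighted counterparts and should be
dropped from comparison grids. Model recovery draws generating parameters
from a multivariate Gaussian matched to reference fits (pooled over
datasets per model; rejection-resampled into the plausible boxes),
simulates datasets, fits all models to each, and reports mean ΔAIC per
(generator, fitted) pair; winner ties break toward the lower model id.

## Sensitivity and optimality

d′ = z(HR) − z(FAR), with extreme rates adjusted by the standard 1/(2n)
correction before the z-transform (the correction rule is a package
choice). The optimal benchmark d′ simulates the flawless Bayesian on fresh
trials from the condition — fresh rather than the subject's exact list, to
minimize variance at large n_sim — with λ set to the fitted value so the
benchmark guesses as often as the subject. The relative index keeps the
subject's sensory noise in the benchmark; the absolute index sets it to 0
(λ is kept in both, for consistency between the two recipes). With
I_abs ≤ I_rel, the loss shares are
100(I_rel − I_abs)/(1 − I_abs) (sensory) and
100(1 − I_rel)/(1 − I_abs) (computational); they sum to 100 exactly.

## Design calibration

The discrimination task models P(clockwise | s) = Φ(s/σ_rel), mean fixed at
vertical, no bias or lapse term. The adaptive placement rule refits the
running psychometric function after every trial from trial 21 on (the
refit cadence is our choice; the first 20 trials are uniform on ±5°) and
draws the next orientation uniformly from the symmetric orientation band
where the running fit predicts 55–95% correct.

The design solvers invert the optimal observer's accuracy with a
common-random-numbers simulator, so accuracy is a deterministic
monotone-in-expectation function of the design parameter and Brent's method
applies: μ_target solves accuracy = 85% at σ_external = 0, and σ_external
solves accuracy = baseline − 5/10/15 *percentage points*. The
percentage-point reading (85 → 80/75/70) is adjudicated empirically: the
published design rows round-trip through our simulator within ±1.5 points
under this reading (e.g. noise SDs 7.1/4.6 with tilt 8.0° give 85.8%;
σ_external = 5.6° costs 10.3 points), while a relative-drop reading would
not. The customization simulates a lapse-free optimal observer (λ = 0).

## Imperfection simulations

Four concrete imperfections are injected into the flawless rule and the
induced error Δd is characterized: Gaussian noise on the log local
evidences (SD 0.5), overestimation of σ_external (factor 1.5),
overestimation of both sensory SDs (factor 1.5), and item-by-item,
trial-by-trial log-normal jitter of the assumed sensory SDs (0.3
log-units). The magnitudes are unpublished, so these defaults are labeled
assumptions and the resulting μ/σ/accuracy-loss numbers are descriptive
only; what the simulations establish qualitatively is that Δd is roughly
Gaussian (small TV distance to a moment-matched Gaussian; the trialwise
jitter kind is the heaviest-tailed, excess kurtosis ≈ 9) and that
parameter-overestimation produces a *bias* (nonzero mean). Local-evidence
noise is applied on the log scale before the averaging, preserving
positivity of the evidence ratios.

## Numerical choices

- The global decision variable is evaluated with a hand-rolled
  log-mean-exp over the 4-item axis (overflow-safe; this sits in the
  innermost likelihood loop).
- Fully deterministic displays (σ_i = σ_external = 0) use the limit of the
  rule via a variance floor of 10⁻¹⁸: any positive observation is then
  conclusive evidence. `local_evidence` itself raises on zero variance.
- σ_late = 0 requested for an imperfect model falls back to the
  deterministic rule with a warning.
- Likelihood probability floor 10⁻⁶; psychometric σ capped at 0.05° with a
  flag when the data are perfectly separable.

## Synthetic data: what it does and does not emulate

The generator reproduces the task's design frequencies exactly (presence
rate, uniform high-count rule, 60% pop-out-filter retention) and the
stated stimulus and noise distributions. It does not emulate sequential
effects, learning or fatigue across blocks, location anisotropies, or any
deviation of real observers from the assumed response model — so passing
tests certify the machinery and its self-consistency, not claims about
human data. Conclusions about real subjects require fitting real trial
records (importable via the CSV + sidecar-JSON trial-set format).

## Problem sizes

Defaults are sized for final analyses: n_mc = 2000 per trial for fitting
(10⁵ for one-off probability reporting), 2×10⁵ trials for calibration
solvers, 10⁵–10⁶ for Δd and d′ simulations. The test suite exercises the
same code paths at reduced sizes chosen to keep the full suite fast —
e.g. parameter recovery at 800 trials × 5 seeds with n_mc = 500, and
recovery grids of three models × two replicates in the closed-form
regime — with tolerances stated per test. The paper-scale designs (1500
trials, 14-model grids, 10 replicates per generator) run with the same
functions by raising the size arguments.

## Known limitations

- The likelihood for short-display conditions is a CRN Monte-Carlo
  approximation; with small n_mc the lapse rate and σ_late can absorb
  simulation error. Raise n_mc for final fits.
- Nelder-Mead multi-start is a pragmatic stand-in for fancier global
  optimizers; multimodal likelihoods (notably the Minkowski β) may need
  more restarts.
- The sampling model's n-grid is log-spaced, so the fitted n is resolved
  only up to grid spacing for large n.
- Heuristic late noise is added to the decision variable with the
  direction-consistent sign; adding it to the criterion instead is
  observationally equivalent.
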