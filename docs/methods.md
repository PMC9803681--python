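# Methods

## Model

Perceived target duration is the weighted average t̂ = (t + d·w)/(1 + w):
the task-relevant target keeps unit weight, and the distractor weight w
encodes how much of its duration-channel activation leaks into the target
estimate. Two weight profiles are implemented.

**Leaking (exponential decay).** w = k^|d−t| with 0 ≤ k ≤ 1. Weights lie in
[0, 1], so t̂ always lies between t and d (central tendency by
construction). k = 1 is the full-averaging limit (w = 1 everywhere); k = 0
is the indicator of d = t, using the convention 0⁰ := 1 — harmless, since a
distractor identical to the target shifts nothing. The exponent |d−t| makes
the function **unit dependent**; all durations in this package are in
seconds, and the leaking factor is only meaningful under that convention.

**Ricker (lateral inhibition).** w = (1 − ((d−t)/k)²)·2^(−(d−t)²/k²) with
k > 0 in seconds. The profile is scale invariant in (d−t)/k: w = 1 at
d = t, crosses zero exactly at |d−t| = k, attains its minimum
−(1/ln 2)·2^(−1−1/ln 2) ≈ −0.2654 at |d−t| = k·√(1 + 1/ln 2) ≈ 1.55 k, and
decays to zero beyond. Negative weights push t̂ away from d (repulsion).
Since w ≥ −0.266 > −1, the weighted average is always defined.

**Decision rule.** A 2AFC response compares the two perceived targets under
zero-mean Gaussian noise with SD fixed at 1: P("second longer") =
Φ(t̂₂ − t̂₁). The argument is in seconds; the unit-SD convention leaves k as
the model's only free parameter. Whether that SD is "really" one second or
one normalized perceptual unit cannot be separated from the scale of t̂
within a fixed design; the choice affects absolute fit quality, not the
ordering or interpretability of k estimates. Probabilities are clamped to
[1e−9, 1 − 1e−9] before any logarithm.

## Leaking-factor estimation

Responses are aggregated per ordered distractor combination (d₁, d₂) into
counts (nᵢ, mᵢ) and k maximizes the binomial log-likelihood
Σᵢ [log C(nᵢ,mᵢ) + mᵢ log φᵢ(k) + (nᵢ−mᵢ) log(1−φᵢ(k))]. The combinatorial
term is constant in k: it is included in reported log-likelihoods so they
equal the true binomial value, and is irrelevant to the optimum. The
optimizer is deterministic: a 201-point grid (linear on [0, 1] for the
leaking variant; log-spaced on (0, 10] s for Ricker) followed by bounded
scalar refinement to ~1e−5 in k. Beyond ~10 s every design distractor falls
in the Ricker profile's flat attraction regime, which is why the search
stops there. A likelihood flat over the whole grid (uninformative counts)
is returned unconverged with the grid argmax.

Goodness of fit is a Pearson χ² over both response categories of every
combination with **df = S − 1** (11 for the 12-combination design). This
convention does not subtract the fitted parameter; it is retained
deliberately to match the reporting convention of the experimental
literature this package accompanies, and makes the test slightly
conservative (calibration simulations in the test suite sit near the
nominal 95% non-significance rate).

## Psychometric fitting

p(x) = λ + (1−2λ)/(1 + e^(−β(x−α))) is fitted to binned response
proportions by MLE; the lapse-free (λ ≡ 0) and lapse models are both fitted
and the lower-AIC model kept, ties to the fewer-parameter model. The lapse
is a single symmetric rate bounded to [0, 0.1] — the standard convention
for two-interval tasks with no guess asymmetry. The latent SD is derived
from the slope as π/(|β|√3), the SD of a logistic distribution with rate β.

Optimization is multi-start (5 PSE × 10 signed-slope coarse grid, top three
refined) with bounded L-BFGS-B using the analytic gradient; convergence
tolerance 1e−12 on the negative log-likelihood. PSE is bounded to the level
range extended by one span on each side, |β| ≤ 500 s⁻¹. Perfectly separated
data (a step) have an unbounded MLE; they are detected exactly and reported
at the slope bound with PSE at the step midpoint and a `slope_at_bound`
flag. Flat data are flagged `flat_data` and their SD is undefined (NaN).

Confidence intervals are a parametric bootstrap (default 500 resamples,
percentile 2.5/97.5): per level, m ~ Binomial(n, p̂(level)) from the fitted
curve, refit of the same model. Refits warm-start at the original solution
**and** at its reflection (2·mid − α, −β). The reflection matters: on
near-flat data the two solutions are nearly equivalent (a binomial offset
from 0.5 can be absorbed by a far-out PSE with a small slope of either
sign), and warm-starting only on one side pins every resampled slope to one
sign, collapsing the interval onto it and inflating the false-positive rate
of the tendency classification several-fold. With the reflection the
null-observer false-positive rate is near the nominal 5–7%. More than 10%
failed refits flags the interval `ci_unreliable`.

## Tendency classification and pipeline

A participant is *central* if the 95% bootstrap CI of the
distractors-condition slope lies entirely above 0, *repulsion* if entirely
below, else *null*. Central participants get a leaking-variant k fit;
repulsion participants are routed to the Ricker variant (the weighted
average with w ≥ 0 cannot produce repulsion); null participants get no leak
fit. The variance ratio σ²_control/σ²_ensemble uses the squared derived SDs
of the two psychometric fits; the cohort correlation between variance ratio
and k is Pearson over included central participants (df = n − 2), with
outlier removal only through an explicit exclusion list so the decision
stays auditable.

The ensemble condition's psychometric x-axis is the distractor-duration
difference, matching the distractors condition, even though the physical
whole-array difference max(t,d₂) − max(t,d₁) differs when a distractor is
shorter than the target; this keeps the two conditions' slopes directly
comparable but inflates the apparent ensemble SD relative to the latent
per-interval noise.

## Synthetic-data generator

The generator emulates the full design: both targets 1.0 s with homogeneous
distractors from {0.3, 0.7, 1.5, 3.0} s, always different between the two
sequences (12 ordered pairs × 30 repetitions); control targets from
{0.3, 0.7, 1.5} s (6 ordered pairs × 30); trial order shuffled per
condition. Distractors-condition responses are Bernoulli draws from the
model's response probability, mixed with lapses as λ + (1−2λ)p (λ defaults
to 0, matching the lapse-free leak model). Control and ensemble responses
compare physical interval durations — the target itself, or for the
ensemble the duration-centred array's onset-to-offset extent max(t, d) —
each perturbed by zero-mean Gaussian noise; lapses become fair coin flips.

Per-interval noise SDs default to 0.25 s (control) and 0.5 s (ensemble).
The control value puts the latent psychometric SD at 0.25·√2 ≈ 0.35 s,
typical of single-interval duration discrimination in this range; the
ensemble value was set (once, by forward simulation) so the apparent SD on
the distractor-difference axis lands near 1.1 s, the degradation expected
when intervals comprise multiple elements. The 22-observer cohort
preset uses 19 leaking observers (k ~ U(0.05, 0.95)) and 3 Ricker
observers at k = 0.3 s, a value that makes every design distractor
repulsive.

Cohort seeds are split into independent per-observer seeds (all < 2³¹) by a
fixed rule, so cohorts are byte-reproducible.

**What the generator does not emulate:** sequential/carryover dependence
between trials, reaction times, duration-dependent (Weber-like
multiplicative) noise, attention fluctuations, or any coupling between an
observer's k and their discrimination noise. Passing recovery tests
therefore show that the estimation machinery is correct and well calibrated
*under the model's own assumptions*, not that real observers satisfy them.

## Numerical and testing choices

- The likelihood implementation is verified against an independent
  per-trial Bernoulli oracle to 1e−9 on random small instances.
- Calibration facts the test suite establishes: fitted k tracks generating
  k across a 40-observer cohort (Pearson ≥ 0.8, median |error| ≤ 0.15);
  the χ² test on self-consistent observers is non-significant in ~95% of
  replicates; distractor-blind observers classify *null* in ≥ 90% of
  replicates.
- Simulation-heavy tests use 200 bootstrap resamples per CI (the library
  default stays 500); problem sizes (40-observer recovery, 100–200
  replicate calibrations) were chosen to make the suite's statistical
  checks stable at conventional thresholds.
- Repulsion detectability is genuinely weak under the model: with unit
  decision noise and Ricker k = 0.3 s the perceived-duration shifts are at
  most ±0.18 s and nonmonotone in d₂ − d₁, so the slope CI resolves
  repulsion in only a minority of simulated sessions. Deterministic tests
  of the repulsion path run at recorded seeds; rate-based claims are made
  only where the model actually supports them.

## Known limitations

- The leaking exponent's unit dependence means k values are comparable only
  across analyses done in the same time unit (seconds here).
- The fixed unit-SD decision noise cannot capture observers whose noise
  scales with duration; misfit from that source loads onto the χ² statistic.
- The 2-parameter logistic converts a pure response bias on near-flat data
  into a small spurious slope (see the reflection note above); slope CIs,
  not point estimates, should be used for any tendency claim.
- Heterogeneous (mixed-duration) distractor sets are out of scope: each
  sequence carries a single distractor duration, as in the design.
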