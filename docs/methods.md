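# Methods

This note records the modelling assumptions, default parameters and design
choices behind `nfpredict`, in the spirit of a statistical supplement.

## Synthetic cohort

The generator emulates the data structure of a two-arm neurofeedback
feasibility trial for binge-eating disorder: an EEG arm (n = 24) and an
fNIRS arm (n = 23), sociodemographics, nine outcome measures at baseline,
posttreatment and 6-month follow-up, and weekly binge counts over the
8-week treatment.

Three latent participant traits drive everything: *attention response*
(involuntary reactivity to food cues), *regulation ability* (success at
feedback-guided downregulation) and *control recruitment* (voluntary
prefrontal engagement). They are i.i.d. standard normal. Objective
binge-eating episode (OBE) counts at posttreatment and follow-up follow a
negative binomial (NB2, dispersion k = 2 by default) whose log-mean is
linear in z-scored baseline OBE and the traits:

    log mu_post = log 2.5 + 0.40 z(OBE_0) + a·attention + r·regulation + c·control

with default effects (a, r, c) = (−0.35, +0.30, −0.30), oriented as in the
trial's findings (stronger food-cue attention and better control
recruitment predict fewer binges). The intercepts are calibrated so the
marginal posttreatment abstinence rate is ≈ 23%, inside the 23–37%
remission range reported for standalone neurofeedback in this population;
baseline OBE counts (mean ≈ 13–14, SD ≈ 8–12) and all questionnaire,
anthropometric and neurophysiological magnitudes target the trial's
descriptive table. Continuous outcomes are Gaussian with partial
regression to the mean plus the same trait linear predictor. Weekly
counts are Poisson draws around a geometric decay from the baseline
weekly rate toward the posttreatment rate, which creates genuine rapid
responders. Generating coefficients are stored on the dataset so
parameter-recovery tests can compare posterior estimates against truth.

EEG sessions draw trial-wise high-beta power log-normally around
trait-linked means (passive ≈ 6, regulation ≈ 4.9, transfer ≈ 5.2 μV²;
log-SD 0.25; 3/12/6 trials). fNIRS sessions simulate two channels at
10 Hz: per-trial amplitudes are Gaussian around trait-linked means
(SD 0.35, tuned so oxygenation/deoxygenation percentages land in the
trial's 25–45% range), multiplied into boxcar⊗HRF responses, plus a
random linear drift and white noise (SD 0.2). The schedule is 12
regulation, 12 mirror (passive-viewing) and 12 transfer trials of 30 s
with a 20 s inter-trial interval — the trial duration/counts are as
reported; the sampling rate and ITI are typical continuous-wave fNIRS
values chosen here because they were not reported.

What the generator does **not** emulate: raw multichannel EEG (band power
is drawn directly), motion artifacts, physiological confounds
(Mayer waves, heart rate) in the fNIRS series, item-level questionnaire
structure, and informative dropout. Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed generating
families, not robustness to real-world preprocessing problems.

Missingness is injected only into posttreatment/follow-up outcome columns
(12 eligible columns); arm, baseline OBE, weekly counts and
neurophysiological predictors are never masked. MCAR masks cells
independently at the configured rate (default 0.10); MAR makes the
masking probability logistic in z-scored baseline OBE (slope 1.5) and arm,
with the intercept solved numerically so the expected masked fraction
equals the configured rate.

## Hemodynamic model and trial-wise GLM

The HRF is a difference of two gamma densities parameterised by mode:
shape = delay/dispersion + 1, scale = dispersion, so the positive lobe
peaks exactly at `peak_delay` (default 6 s) and the undershoot at 16 s
with relative amplitude 1/6; the kernel is peak-normalised to 1 over a
32 s support. Each trial's GLM is fit by OLS on the window
[onset − 5 s, onset + duration + 15 s] with four regressors: the trial's
boxcar⊗HRF, the lumped boxcar⊗HRF of all other trials, an intercept and a
linear drift. The lumped nuisance regressor absorbs hemodynamic bleed-in
from neighbouring trials (the response to a 30 s trial outlasts the 20 s
inter-trial gap); with it, a noiseless session is recovered exactly.
Whether the original analysis software included drift or
neighbouring-trial terms is not public; these defaults are declared and
config-overridable. Band power uses Welch's averaged periodogram (2 s
Hann segments, 50% overlap), integrating the PSD over 23–28 Hz.

## Rapid response

Week-4 OBE counts are taken as 28-day equivalents (4 × the week-4 weekly
count). Reductions are undefined (and excluded from ROC) when baseline is
0. The ROC candidate set is the attained reduction values; optimality is
Youden's J with ties broken toward the largest cutoff, and a maximum
J ≤ 0 flags the cutoff as non-informative. Classification is inclusive
(reduction ≥ cutoff).

## Missing-data handling

Little's test uses EM estimates of the mean and covariance of the numeric
block under a multivariate-normal working model (ridge 1e-10, tolerance
1e-6, ≤ 200 iterations); the statistic sums pattern-wise Mahalanobis
distances of observed-variable means, with df = Σ(observed variables per
pattern) − p. A single missingness pattern yields a not-applicable
result rather than an error.

MICE-PMM visits incomplete variables in ascending missingness order.
Each step regresses the target on all other analysis variables (current
completions, ridge 1e-6 for near-saturated designs), draws the residual
variance from its scaled inverse-chi-square and coefficients from their
normal posterior, computes type-1 PMM predictions (observed cases with
the mean fit, missing cases with the drawn coefficients), and imputes
each missing cell with a uniformly chosen donor among the k = 5 closest
predictions. Because PMM copies observed values, imputed counts stay
integers and ordinal codes stay valid levels. Each of the m imputations
runs on an independent, reproducible stream derived from the seed.
Columns named `eeg_*`/`fnirs_*`, `arm` and the participant id pass
through bit-identical.

## Bayesian models

Coding: metric predictors and Gaussian outcomes are z-scored with the
sample SD; counts for negative-binomial outcomes and 0/1 outcomes are
left on their natural scale; dichotomous predictors become −0.5/+0.5 and
K-level ordinals become K−1 cumulative −0.5/+0.5 contrasts.
Standardisation is computed within each imputed dataset, so every copy
has exact mean 0 / SD 1.

Priors: coefficient locations are the frequentist MLEs (OLS, Logit,
NB-MLE, beta regression via statsmodels; across imputations, MLEs and
SEs are averaged). A common scale per predictor family is
max(SD of the family's MLEs, mean of their SEs); single-member families
use their SE, and the intercept and each covariate form their own
"family" (hence receive their own SE) because the multiplicity argument
for a shared scale applies to the exchangeable predictor sets, not to
structural terms. Non-converged frequentist fits (e.g., separation in
small logistic models) fall back to a weak normal(0, 2.5) prior, logged
and recorded in the prior set. Auxiliary parameters (NB dispersion, beta
precision, Gaussian σ) get log-normal priors located at log(MLE) with
scale 1. Sensitivity multipliers scale every prior SD.

Sampling is fixed-length-leapfrog Hamiltonian Monte Carlo. The posterior
mode is found by L-BFGS and the diagonal Laplace curvature there supplies
the (inverse) mass matrix; step sizes are tuned per chain by dual
averaging during burn-in toward the target acceptance probability
(default 0.8), with the leapfrog length jittered uniformly on [5, 10].
Linear predictors and log-auxiliary parameters are clipped
(|η| ≤ 30, |log aux| ≤ 15) inside the likelihoods so early warmup
excursions cannot overflow; the clip is far outside any posterior mass
for the standardised designs used here. The production settings are 8000
iterations, 4000 burn-in, 8 chains, seed 42; the `fast` profile
(2000/1000/4) is used by the test suite and the acceptance script. A
maximum tree depth is part of the settings object for compatibility with
tree-based samplers and is recorded as not applicable in this sampler's
provenance. Imputation stacks are fitted in a single batched run
(m × chains chains, one per imputed dataset), which is numerically
identical to independent fits up to the shared jitter stream and roughly
m times faster.

Convergence requires ESS ≥ 1000 and R̂ < 1.1 for every parameter (arviz
rank-normalised versions). If every per-imputation fit passes, pooling
concatenates chains (m × chains × kept draws); otherwise Rubin's rule
pools posterior means and variances, with credible intervals from the t
reference using Barnard–Rubin degrees of freedom, and draw-based
quantities (R², ΔR²) are unavailable for that model.

Bayesian R² is computed draw-wise on the response scale:
Var(fitted means) / (Var(fitted means) + mean expected residual
variance), where the residual term is σ² (Gaussian), p(1−p) (Bernoulli),
μ + μ²/k (NB) or μ(1−μ)/(1+φ) (beta). ΔR² is the draw-wise difference
between the full and leave-one-term-out fits, clipped at 0 for reporting
(the unclipped summary is kept in diagnostics). Effect-size labels use
the 0.02/0.13/0.26 orientation cutoffs.

## Selection and robustness

The collinearity screen computes, on the correlation matrix of all model
columns, the plain VIF for single-column terms and GVIF^(1/(2·df))
squared for multi-column terms, removing the worst offender above 5 and
iterating; exact duplicates are removed first with an explicit log entry.
Covariates participate in the correlation structure but are never
removable.

Backward elimination: fit, flag predictors whose pooled 95% CrI includes
0 (a multi-column term is "excluding" only if all of its contrasts
exclude 0), remove the flagged predictor with posterior mean closest to
0, and compare pooled LOO-ELPDs. ELPD pooled across imputations is the
mean of the per-imputation PSIS-LOO values — the chain-concatenated
"pooled fit" scores data that differ across imputations, so a single LOO
on pooled draws is not well defined. A drop > 4 reinstates the predictor
permanently (it is never reconsidered, which guarantees termination).
Observations whose Pareto-k diagnostic exceeds 0.7 are re-scored by exact
leave-one-out refits when n ≤ 50; all such refits run as one batched HMC.

The sensitivity suite refits the final model at prior-scale multipliers
1, 2 and 0.5 with identical data and seed policy; a predictor is
influential only if its CrI excludes 0 in all three fits.

## Numerical choices and degenerate inputs

Classification at exactly β = ±0.2 is "neither" (strict inequalities).
A trial type absent from a schedule yields absent (NaN) percentages, not
0. Baseline-0 participants have undefined reductions and absent RR.
Constant outcomes, zero-variance metric columns, rank-deficient trial
designs, all-missing columns, single-class ROC labels and m < 2 Rubin
pooling are rejected with named errors. All randomness flows from
explicit seeds through `numpy.random.SeedSequence`; identical
configuration reproduces identical artifacts byte for byte.

## Problem sizes

The shipped tests and the acceptance script use the fast sampler profile
and moderate simulation sizes (e.g., 500 replicates for the MCAR
calibration, 50 replicates for interval coverage, 20 seeds for the
elimination study, n = 200–500 per replicate), chosen as the smallest
sizes at which the Monte-Carlo bands in the assertions are stable.

## Known limitations

* The HRF parameters, trial-GLM nuisance model and EEG spectral settings
  are canonical defaults, not the (unpublished) settings of the original
  acquisition software; all are config-overridable.
* The exact estimator behind the original "common prior scale" is not
  public; max(MLE spread, mean SE) is this package's declared choice, as
  is Youden's J for the ROC cutoff and the 28-day scaling of week-4
  counts.
* Fixed-length HMC with a diagonal Laplace mass matrix is well suited to
  the small, near-Gaussian posteriors here but is not a general
  replacement for adaptive tree-based samplers on strongly correlated or
  high-dimensional posteriors.
* With ~20 participants per arm, separation in logistic models is
  common; the weak-prior fallback keeps fits proper but such models
  should be read with the width of their intervals in mind.
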