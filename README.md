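# nfpredict

Outcome-prediction analysis for EEG- and fNIRS-neurofeedback treatment of
binge-eating disorder (BED), packaged as a tested, reusable pipeline.

Neurofeedback (NF) trains patients with BED to self-regulate the neural
signatures of food-cue reactivity: fronto-central high-beta EEG power
(23–28 Hz, heightened food-related attention) or prefrontal oxyhemoglobin
measured by functional near-infrared spectroscopy (fNIRS, food-related
cognitive control). A natural clinical question is *who benefits*: can
pretreatment neurophysiological activity, or an early "rapid response" in
binge frequency, predict treatment outcomes? This package implements the
full statistical workflow for that question — and, because clinical trial
data of this kind cannot be shared, ships a synthetic-cohort generator that
reproduces the trial's data structure (two arms of n = 24 and n = 23,
weekly binge counts, three assessment waves, realistic missingness) with
known ground truth, so every stage is testable end to end.

It is aimed at biostatisticians and methods-oriented clinical researchers
who want a transparent, fully seeded reference implementation of this
style of small-sample Bayesian prediction analysis.

## What the pipeline computes

1. **Neurophysiological predictors.** From each fNIRS session, a
   trial-wise GLM regresses the two-channel oxyhemoglobin series on the
   trial's boxcar convolved with a canonical two-gamma hemodynamic
   response function $h(t)$ (plus intercept, linear drift, and the lumped
   remaining trials). The channel-averaged coefficient β is the trial-wise
   oxyhemoglobin change; per trial type, the predictors are the
   percentages of trials with β > 0.2 (oxygenation) and β < −0.2
   (deoxygenation). EEG predictors are mean high-beta band power (Welch,
   2 s Hann segments) during passive-viewing, regulation and transfer
   trials.
2. **Rapid response (RR).** Percent reduction in objective binge-eating
   episodes (OBEs) by treatment week 4,
   $100\,(\text{OBE}_0 - \text{OBE}_{w4})/\text{OBE}_0$, dichotomised at a
   cutoff chosen by ROC analysis against posttreatment abstinence
   (maximum Youden J = sensitivity + specificity − 1), with ≥ 65% as the
   literature comparison rule.
3. **Missing data.** Little's MCAR test (EM-based), then multiple
   imputation by chained equations with predictive mean matching
   (m = 5 imputations, 10 iterations, seed 42, 5 donors).
   Neurophysiological predictors are never imputed.
4. **Bayesian GLMs.** Per outcome: negative binomial (log link) for OBE
   counts, Bernoulli-logit for abstinence, Gaussian and beta families for
   secondary scores. Metric variables are z-standardised; dichotomous and
   ordinal predictors are effect coded (−0.5, 0.5) with cumulative
   contrasts. Priors are empirical-Bayes: normal, centred on frequentist
   MLEs, with a common scale per predictor family
   (max of the family's MLE spread and mean standard error); log-normal
   priors for the NB dispersion and beta precision. Sampling is
   Hamiltonian Monte Carlo (Laplace-preconditioned, dual-averaged step
   size, target acceptance 0.8; 8000 iterations, 4000 burn-in, 8 chains,
   seed 42 by default), with ESS ≥ 1000 and $\hat R < 1.1$ convergence
   gates, chain-concatenation pooling across imputations (Rubin's rule as
   the fallback), and Bayesian $R^2$ / ΔR² effect sizes.
5. **Selection and robustness.** Predictors with adjusted GVIF > 5 are
   screened out; backward elimination removes predictors whose 95%
   credible interval includes 0 (closest-to-zero first, covariates never
   removed), guarded by PSIS-LOO ELPD — a drop > 4 reinstates the
   predictor. The final model is refit with doubled and halved prior
   scales; a predictor is **influential** only if its CrI excludes 0 in
   the main and both sensitivity fits.

## Worked example

```python
from nfpredict.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(mcmc_profile="fast", outdir="out",
                     roster=(("obe", "post", "eeg"),
                             ("abstinence", "post", "eeg")))
res = run_pipeline(cfg)
print(f"RR cutoff: {res.rr_cutoff:.2f}%  (Youden J = {res.roc.youden_j:.2f})")
print(res.results_table.to_string(index=False))
```

prints (seed 42, fast sampler profile):

```
RR cutoff: 86.21%  (Youden J = 0.64)
              model  n         term  coef_mean  coef_sd  cri_lower  cri_upper  r2_mean effect_size           robust
       eeg_obe_post 24      (model)                                               0.41       large
       eeg_obe_post 24    intercept       0.98     0.14       0.71       1.26
       eeg_obe_post 24 obe_baseline       0.22     0.15      -0.08       0.50     0.09       small
       eeg_obe_post 24 eeg_transfer       0.60     0.20       0.20       1.00     0.25      medium      influential
eeg_abstinence_post 24      (model)                                               0.44       large
eeg_abstinence_post 24    intercept      -4.03     1.23      -6.73      -1.92
eeg_abstinence_post 24 obe_baseline      -0.20     1.02      -2.29       1.69     0.10       small
eeg_abstinence_post 24  eeg_passive       2.17     0.86       0.63       3.98     0.27       large      influential
eeg_abstinence_post 24 eeg_transfer      -2.04     1.09      -4.31      -0.03     0.16      medium includes0_halved
```

Reading the abstinence model: after controlling for baseline OBE
frequency, higher pretreatment passive-viewing high-beta power predicts
higher odds of posttreatment abstinence (β = 2.17 per SD, 95% CrI
[0.63, 3.98], ΔR² = 0.27, robust across all prior-sensitivity fits), while
the transfer-trial coefficient excludes 0 in the main fit but not with
halved prior scales, so it is not declared influential. The row-level
`r2_mean` is the model's Bayesian R² on the `(model)` row and the
leave-one-term-out ΔR² elsewhere, labelled small/medium/large at the
0.02 / 0.13 / 0.26 cutoffs. In the synthetic cohort these effects stem
from the generator's latent attention/regulation/control traits, whose
true coefficients are retained for recovery tests.

The same run is available from the shell:

```bash
nfpredict run-all --mcmc-profile fast --outdir out
nfpredict simulate --seed 7 --outdir out   # cohort + predictors only
```

## Layout

```
src/nfpredict/
  cohort.py          synthetic trial cohorts, sessions, missingness
  neurophys.py       HRF, trial-wise GLM, band power, predictor table
  rapid_response.py  percent reduction, ROC cutoff, RR classification
  missingness.py     Little's MCAR test, MICE-PMM, Rubin's rule
  families.py        NB / Bernoulli / beta / Gaussian likelihoods + gradients
  sampler.py         preconditioned Hamiltonian Monte Carlo
  bayes.py           standardisation, EB priors, fitting, pooling, R²
  selection.py       GVIF screen, LOO-ELPD, backward elimination, robustness
  pipeline.py        staged end-to-end pipeline and results tables
  cli.py             `nfpredict` command-line interface
docs/methods.md      modelling assumptions, defaults, limitations
```
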