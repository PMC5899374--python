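# Methods

## The problem

Gastric ulceration (equine gastric ulcer syndrome, EGUS) is common in
weanling foals and frequently silent. Gastroscopy is the only definitive
ante-mortem diagnosis but is too expensive for herd screening. The blood
sucrose permeability test — an oral sucrose dose followed by blood sucrose
measurement at 45 and 90 min — is a candidate screening test: a compromised
gastric mucosal barrier lets more sucrose through. This package implements
the full statistical evaluation of that test in a repeated-measures cohort
(the same foals tested shortly before and two weeks after weaning), in two
frameworks:

1. a **frequentist** analysis treating gastroscopy as a gold standard
   (ROC curves, Mann–Whitney AUC, cutoff selection, Se/Sp, prevalence), and
2. a **Bayesian latent class** analysis treating gastroscopy as imperfect
   (the Hui–Walter two-population, three-test model with conditional
   dependence between the two sucrose measurements).

## Synthetic cohort generator

The original foal-level data are not public, so `sucroscreen.simulate`
generates cohorts with the structure the analysis assumes. Defaults encode
the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_foals` | 45 | foals, each tested on two occasions |
| `prev_pre`, `prev_post` | 0.21, 0.98 | latent gastric-lesion prevalence per occasion |
| `mean_sd_normal_45` | (23.99, 17.91) µmol/L | sucrose mean ± SD, lesion-free foals, 45 min |
| `mean_sd_normal_90` | (23.83, 13.26) µmol/L | … 90 min |
| `mean_sd_diseased_45` | (57.56, 41.30) µmol/L | lesioned foals, 45 min |
| `mean_sd_diseased_90` | (54.84, 36.58) µmol/L | … 90 min |
| `log_corr` | 0.94 | log-scale correlation of the 45/90-min pair |
| `endo_se`, `endo_sp` | 0.81, 0.99 | gastroscopy sensitivity/specificity |
| `subtype_probs` | sql 0.95, gdl 0.60, csl 0.83 | P(subtype call \| positive gastroscopy) |

Design choices, in the generator's own terms:

* **Monotone progression.** A foal diseased pre-weaning stays diseased;
  a healthy foal converts with probability
  `(prev_post − prev_pre)/(1 − prev_pre)`, giving marginal prevalence
  `prev_post` after weaning. Weaning is a strong, fast risk factor; over
  a three-week window spontaneous healing is neglected.
* **Bivariate lognormal concentrations.** Concentrations are positive and
  right-skewed; the printed mean ± SD per group is moment-matched exactly
  on the log scale (`moment_match_lognormal`). The two time points share a
  log-scale correlation of 0.94, which yields an observed Spearman
  correlation of ≈0.94–0.96 in the mixed cohort. Concentrations are *drawn*,
  not produced by any pharmacokinetic model.
* **Truth is latent.** Sucrose depends on the latent state, and gastroscopy
  is an imperfect Bernoulli reading of it. Keying concentrations on the
  gastroscopy call instead would build the gold-standard assumption into
  the data and make the latent class analysis untestable.
* **Subtypes.** The published group means for glandular/squamous/clinically
  significant lesions overlap heavily with the any-lesion group, so the
  generator keys concentrations on the single latent any-lesion state and
  draws subtype calls independently given a positive gastroscopy call, with
  probabilities chosen to reproduce the relative post-weaning subtype
  frequencies. This reproduces the marginal subtype prevalences, not any
  subtype-specific concentration shift.

What the generator does **not** emulate: litter/farm clustering beyond the
foal level, seasonal or age trends, assay measurement error as a separate
component (it is folded into the group SDs), and lesion severity grades.
Passing tests therefore show the *methods* behave correctly under the
assumed data-generating process, not that the test performs identically in
any real population.

## Frequentist accuracy analysis

* **Positivity convention:** concentration ≥ cutoff is positive (the
  default cutoff, 24 µmol/L, classifies a foal at 35.4 µmol/L positive).
* **AUC** is the Mann–Whitney estimator (ties ½), which equals the
  trapezoidal area under the empirical ROC; the test suite asserts this
  equivalence against brute-force pair enumeration.
* **Repeated measures.** Confidence intervals come from a **cluster
  bootstrap**: foals (not records) are resampled with replacement, each
  carrying both occasions, 2000 replicates by default, percentile 95% CIs.
  The point estimate is always the statistic on the original sample. The
  45- vs 90-min AUC comparison feeds the *same* resampled foals to both
  time points; its p-value is the doubled smaller tail fraction of the
  replicate deltas around zero, floored at `2/n_boot` (the resolution of a
  finite bootstrap). Replicates that lose a class are redrawn (up to 100
  attempts, then an error), since the AUC is undefined on one class.
  Whether to resample foals or foal-occasions was an open design choice;
  foal-level resampling is the one that respects the dependence structure.
* The original analysis adjusted Se/Sp/prevalence CIs with mixed-effects
  logistic regression in commercial software; this package substitutes the
  cluster bootstrap for interval estimation and an **exact McNemar test**
  (binomial on discordant pairs) for the pre/post prevalence comparison —
  dependency-free procedures that respect the paired design.
* **Cutoff selection** maximizes Youden's index `Se + Sp − 1`, a
  sensitivity-weighted variant `1.33·Se + 0.67·Sp − 1` (sensitivity twice
  as important — appropriate for a screening test where a missed case is
  the costly error), or maximal Se subject to Sp > 0 ("manual"). Ties go to
  the lower threshold, i.e. the more sensitive cutoff.
* **Agreement** between two raters is percent agreement plus Cohen's kappa;
  when both raters are constant the chance-agreement probability is 1 and
  kappa is undefined — this raises rather than returning 0.

## Priors

Beta priors per parameter: Beta(2,8) and Beta(6,4) for pre-/post-weaning
prevalence, Beta(8,2) and Beta(99,1) for gastroscopy Se/Sp, Beta(1,1) for
the four sucrose parameters. `beta_summary` reports mean, median and the
central equal-tailed interval (for mass 0.90, the 5th–95th percentiles) by
inverting the regularized incomplete beta function; the equal-tailed
reading is confirmed by the printed bounds of the Beta(6,4), Beta(8,2) and
Beta(99,1) rows. Two display discrepancies in the published prior table are
documented and excluded from testing: the Beta(2,8) upper bound prints as
0.388 where the 95th percentile computes to ≈0.429 (the table's own
Beta(8,2) row implies 1 − 0.571 = 0.429 by reflection symmetry), and the
Beta(1,1) rows print 95% bounds (0.025, 0.975) under the 90% heading.
Reported table values are rounded half-up to the display precision
(2 decimals for moments, 3 for interval bounds); full precision is always
retained on the underlying objects.

## Latent class model

Cell probabilities, likelihood and priors are given in the module
docstring of `sucroscreen.latent_class`. Choices that were genuinely open:

* **Dependence parametrization.** One covariance between the two sucrose
  tests among the diseased (`cov_se`) and one among the non-diseased
  (`cov_sp`); gastroscopy is conditionally independent of the pair. The
  covariances are constrained to the rectangle where all joint cells are
  non-negative, and get **uniform priors over that (parameter-dependent)
  range** — a standard weakly informative choice; no prior information on
  the dependence terms existed.
* **Identifiability.** Latent class mixtures are invariant to label
  switching; the prior truncation `se_endo + sp_endo > 1` anchors the class
  labelled "diseased" to the one gastroscopy detects better than chance.
  With the informative gastroscopy priors this truncation is nearly never
  active, but it guarantees the anchor in small samples.
* **Sampler.** Random-walk Metropolis-within-Gibbs over the 10 parameters:
  probabilities on the logit scale (with the change-of-variable Jacobian),
  covariances on the natural scale with out-of-range proposals rejected
  through the prior support. Proposal scales adapt toward ≈44% acceptance
  during burn-in only and are frozen afterwards, so the sampling-phase
  kernel satisfies detailed balance. The contract is the target density,
  not the kernel: correctness is anchored by a reduced-model test in which
  the prevalence posterior from MCMC is compared with dense numerical
  integration (agreement within 0.01; observed ≈2·10⁻⁴).
* **Schedules.** The full-length profile discards 200,000 burn-in
  iterations, retains every 10th iterate and keeps 40,000 post-thinning
  iterates per chain. "Retained iterates" is read as post-thinning counts.
  The desk profile (burn-in 20,000, thin 10, 4,000 retained, 3 chains) is
  the default for routine runs and testing; at these chain lengths the
  Gelman–Rubin statistic is ≈1.000 and posterior medians recover generating
  values within ±0.07 at 1,000 observations per population.
* **Summaries.** Posterior medians as point estimates; 95% probability
  intervals as the 2.5th–97.5th percentiles of the pooled retained
  iterates, with linear interpolation between order statistics. The classic
  Gelman–Rubin potential scale reduction factor (between/within variance,
  no rank-normalization or chain splitting) is attached per parameter.
* **Independence across populations.** The two populations are modelled as
  independent multinomials although the same foals appear in both — the
  same simplification the original analysis made; reports flag it. The
  cross-classified table is built by dichotomizing both sucrose columns at
  the configured cutoff (default 24 µmol/L) against the chosen gastroscopy
  outcome.
* Empty populations are accepted by the sampler (the likelihood term is
  then zero), which is what makes prior-recovery checks possible.

## Numerical notes

* Beta quantiles: scipy's `beta.ppf` (absolute error well below 1e-6;
  verified against the closed-form binomial-tail CDF for integer
  parameters and a Monte-Carlo oracle).
* The sampler evaluates the joint log-posterior directly with precomputed
  pattern masks; a desk-profile fit (1.8M density evaluations) takes about
  a minute on one CPU.
* Degenerate inputs raise: non-positive concentrations, single-class
  labels, constant vectors for correlation, both-raters-constant kappa,
  boundary probabilities in `cov_bounds`, uninformative gastroscopy
  parameters.

## Problem sizes used in tests

Synthetic-cohort fidelity is checked at 2,000 foals, marginal moment
recovery at 50,000, latent class recovery at 1,000 observations per
population under the desk schedule, oracle equivalence on a 3-chain
reduced-model run, and interval coverage over 8 replicate fits at 600 per
population with a shortened schedule. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping the default suite
around two minutes.

## Known limitations

* No smooth/parametric ROC fitting; curves are empirical.
* No multi-rater (Fleiss) agreement; kappa is pairwise.
* The latent class model is fixed at 2 populations × 3 tests with pairwise
  dependence between the two sucrose tests only; generalizing is an
  extension point, not a feature.
* No model comparison (DIC/WAIC) or covariate extensions.
* The sucrose-test dependence posteriors have no external numeric anchor;
  they are reported but only sanity-checked by simulation recovery.
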