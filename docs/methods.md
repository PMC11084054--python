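# Methods

This note documents the statistical models in `lvddlink`, the design of
the synthetic cohort generator, and the numerical choices made where the
underlying methods literature leaves room.

## Analysis sets

The pipeline runs each stage on its own analysis set, mirroring the
multi-visit design it implements: species discovery on a *discovery* set
(default 75.5% of samples) with replication in the *validation*
remainder; metabolome-wide association on the *concurrent* subset that
has both microbiome and metabolome data (default 40%); the prevalent
metabolite models on a *baseline* subset (default 70%); and the incident
analyses on baseline-negative subjects with follow-up. Because these
sets overlap, membership is carried as one discovery/validation label
plus boolean flags (`has_metabolome`, `in_baseline_v1`, `has_followup`)
rather than a single mutually exclusive category. Every stage's n is
recorded in the run manifest.

## Preprocessing

* **Prevalence filter** (species, KOs): a feature is kept when it is
  nonzero in strictly more than 20% of the samples *of the analysis set
  in use* — the discovery-stage filter is recomputed on the discovery
  set. KOs additionally require the relative abundance to reach 0.001%
  (1e-5) for a sample to count toward prevalence.
* **Detection filter** (metabolites): kept when detected (non-missing)
  in strictly more than 75% of samples. Below-detection values are
  carried as NaN from the reader onward — never as zero — so censoring
  decisions stay explicit.
* **CLR**: log(x + c) centered per sample over the *retained* features
  (filter first, transform second). The pseudocount c defaults to 0.5
  on counts; with zero-free input and c = 0 the transform is exactly
  scale-invariant. CLR rows sum to zero by construction.
* **INT**: below-detection values are imputed at half the minimum
  detected value per metabolite, then average ranks are mapped through
  Φ⁻¹ with the Blom offset (r − 3/8)/(n + 1/4) — the most common
  convention in omics. Imputation values and the rule are recorded in
  the transform report.

## ANCOM-II

Zeros are classified before testing. A (taxon, group) pair is a
**structural zero** when the taxon is zero in ≥ 99% of that group's
samples (configurable); taxa structurally absent from exactly one
outcome group are reported as detected without a W statistic and are
excluded from the pairwise pool. A zero is an **outlier zero** when the
taxon's within-group nonzero log-abundance distribution places
log(pseudocount) below quantile(0.10) − 3 · SD — i.e. a zero in a taxon
otherwise abundant and tight in that group; such cells are treated as
missing in that taxon's regressions rather than imputed, so technical
zeros cannot drive effects. Remaining zeros are **sampling zeros** and
are imputed by the shared pseudocount inside log-ratios.

For the pool of m taxa, the outcome coefficient of
log(xᵢ/xⱼ) ~ outcome + covariates is computed for all ordered pairs.
Because OLS is linear in the response, the pair coefficient equals the
difference of per-taxon coefficients from regressing each log-abundance
on the same design, and the pair residual sum of squares is
RSSᵢ + RSSⱼ − 2(RᵀR)ᵢⱼ from the residual Gram matrix; one least-squares
solve therefore yields all m(m−1)/2 regressions exactly (verified
against a per-pair statsmodels loop in the tests). Taxa with missing
(outlier-zero) cells fall back to per-pair complete-case fits.

Wᵢ counts the comparisons surviving a within-taxon BH correction at
α = 0.05 (Bonferroni available); detection at W ≥ 0.7 (m − 1), the
reference-implementation convention. Neither the cutoff nor the zero
thresholds are printed by typical study reports, so all are exposed as
configuration with these defaults.

## Association layer

* **Logistic models** are maximum-likelihood fits; non-convergence and
  separation are flagged (`converged=False`) rather than silently
  returned. The covariate registry enforces the model nesting: Model 2 =
  Model 1 + BMI + SBP, Model 3 = Model 2 + three medication flags.
* **Modified Poisson**: Poisson GLM with log link on the binary incident
  outcome; standard errors from the HC0 sandwich (the original
  proposal's flavour; HC1 by flag). exp(β) is the relative risk per
  1 SD of the metabolite. The 2×2 saturated closed forms (RR as ratio of
  proportions, var(log RR) = 1/x₁ − 1/n₁ + 1/x₀ − 1/n₀) hold exactly and
  are asserted in the tests; simulated 95% CI coverage at n = 594 falls
  in (0.93, 0.97).
* **Exposure scaling**: metabolites per 1 SD computed on the analysis
  set in use; species per CLR unit.
* **Meta-analysis**: DerSimonian–Laird, non-iterative, τ² floored at 0;
  retention needs pooled p < 0.05 and sign-concordant set-level
  estimates. Cross-checked against `statsmodels`' DL implementation.
* **BH FDR** is applied one family per analysis: per species across the
  metabolome in the MWAA; across the species-associated set in the
  prevalent analysis; across the prevalent-associated set in the
  incident analysis; per exposure in the KO analyses. The incident
  significance rule defaults to FDR < 0.1, consistent with the other
  metabolite analyses.
* **Partial correlation**: Pearson correlation of covariate residuals,
  p from t with n − k − 2 df (k = encoded covariate columns);
  cross-checked against `pingouin`.
* **Grade trend**: OLS of CLR abundance on the ordinal grade scored
  0–3 with Model 1 covariates.
* Wald inference throughout; likelihood-ratio alternatives are out of
  scope.

## Proxy association

Z = β/SE on both sides, Spearman correlation with average ranks over the
incident-associated metabolites (all of them enter every species' test,
not only the metabolites significant for that species). The p-value is
an exhaustive permutation enumeration for k ≤ 9 and the usual
t approximation otherwise — reported proxy p-values of order 10⁻⁷ at
k ≈ 21 are only reachable with the asymptotic formula, which is why it
is the default at that k.

## Prediction

Elastic-net logistic regression (scikit-learn saga) inside nested
stratified CV: the inner loop (default 10-fold) grid-searches
C ∈ {0.01 … 10} × l1_ratio ∈ {0.1 … 0.9} by mean validation AUC on each
outer training set; outer folds (default 10) produce out-of-fold
predicted probabilities, which give the primary (honest) AUC; the
reported feature set comes from a refit on all data at the consensus
(modal) hyper-parameters, with the in-sample AUC reported secondarily.
"10 × 10" is read as 10 outer × 10 inner folds; a `repeats` option
covers the alternative reading (10 repeats of 10-fold). Features are
standardized inside every training fold. SHAP values for the linear
model are exact, φᵢⱼ = βⱼ(xᵢⱼ − x̄ⱼ), and satisfy the efficiency
property (row sums equal the centred linear predictor) to 1e-10; feature
importance is mean |φ|. The AUC is the Mann–Whitney statistic with
midrank tie handling (equal to exhaustive pairwise concordance counting,
asserted for n ≤ 50); its CI is a percentile bootstrap over resampled
(prediction, label) pairs; AUC change is tested with DeLong's method for
correlated ROC curves (a bootstrap difference test would be the natural
alternative).

## Synthetic cohort generator

What it emulates: compositional species counts via log-normal latent
abundances and per-sample multinomial draws (zero inflation and
compositional coupling arise naturally; a Dirichlet-multinomial was
rejected because per-feature effect planting is awkward there); seven
differential species acting on the prevalent outcome through a logistic
model on covariates plus their latent CLR values (default |log OR|
0.8–1.2 per CLR SD — chosen for testability, since study reports rarely
print effect sizes on this scale); three additional species hard-zeroed
in the case stratum (structural zeros); metabolites as linear
combinations of planted species CLR values, covariate effects, and unit
Gaussian noise, left-censored at the 10th percentile (a random 8% of
metabolites at the 30th percentile, so the detection filter has work);
an incident outcome among baseline-negative subjects from a log-link
Bernoulli model, so the planted per-SD relative risk is exp(γ) exactly
(probabilities clipped at 0.95); and KO blocks whose log-abundances
track their parent species before a second multinomial.

The proxy wiring sets the metabolite loadings of the two protective
species to −1.5 γ (plus noise) and of one risk-raising species to
+1.5 γ, so the expected proxy correlations are negative, negative, and
positive. Planted incident effects |γ| ∈ [0.08, 0.16] per SD look small,
but the shared species factors correlate the 21 outcome metabolites and
amplify each one's *marginal* association — the measured relative risks
come out near 0.8–1.3 per SD, the plausible range for circulating
metabolites. Intercepts for both outcomes are calibrated by root-finding
so the expected prevalent fraction is 0.459 and the expected incident
fraction among baseline-negative subjects is 0.357.

Traditional risk factors (age, BMI, SBP, diabetes, LDL-C, alcohol) carry
real incident signal so the reference prediction model is informative on
its own (cross-validated AUC ≈ 0.62–0.67 at the default scale) and the
metabolite-augmented model's improvement is a genuine added-value test.

`effect_scale = 0` switches off every planted effect including the
structural zeros, giving fully null cohorts for calibration testing.

What it does **not** emulate: real taxonomies and phylogeny, survey
weighting, batch effects, longitudinal microbiome drift, realistic
inter-covariate correlation structure, or the true correlation structure
of any particular cohort. Passing tests therefore demonstrate that the
chain recovers planted structure under its own model assumptions and is
calibrated under the null — not that it would reproduce any specific
cohort's findings.

## Problem sizes used in testing

Unit tests run on reduced cohorts (n ≈ 300–600, tens of features).
The calibration suites use: ANCOM-II null — 100 replicates at n = 200,
m = 50; modified-Poisson coverage — 1,000 replicates at n = 594 per
design; MWAA FDR — 200 replicates at n = 300, 200 metabolites; proxy
sign recovery — 30 seeds at n = 594, k = 21; prediction added-value —
10 seeds at n = 594 with reduced CV grids. The end-to-end test and the
acceptance script run one full-scale cohort (n = 2,000, 550 species,
700 metabolites, 2,100 KOs) through the complete pipeline, which takes
about one to two minutes on a single CPU. Monte-Carlo assertions use
tolerances of 2–3 binomial/MC standard errors around the nominal value.

## Known limitations

* The ANCOM-II covariate formulation is log-ratio-on-outcome regression;
  group-comparison variants of the original implementation are not
  provided.
* Outlier-zero handling uses a simple within-group log-abundance fence;
  heavy-tailed abundance distributions may flag conservative.
* The nested-CV consensus hyper-parameter rule (modal pair, ties toward
  the stronger penalty) is one of several defensible choices; the
  out-of-fold AUC does not depend on it, only the reported feature set
  does.
* No survey weighting, mixed models, or time-to-event analysis; the
  incident outcome is binary by design.
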