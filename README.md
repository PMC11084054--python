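# lvddlink

Multi-omics inference chain linking gut bacterial species, circulating
metabolites, and left ventricular diastolic dysfunction (LVDD): a tested,
reusable implementation of the analysis pipeline used in prospective
cardio-metabolic microbiome studies, exercised end to end on a synthetic
cohort generator with planted ground truth.

## Who this is for

Epidemiologists and computational microbiologists who have
sample-by-feature tables — shotgun-metagenomic species abundances,
untargeted serum metabolite intensities, KO gene-family relative
abundances — plus a covariate/outcome table, and want to run the full
discovery chain: which species differ by disease status, which
metabolites track those species, which of those metabolites predict
incident disease, and whether the species themselves are linked to
incident disease through their metabolite signatures.

## The analysis chain

1. **Preprocessing.** Species present in > 20% of samples are kept and
   centered log-ratio transformed, clr(x)ₖ = log(xₖ + c) − (1/m) Σⱼ
   log(xⱼ + c). Metabolites detected in > 75% of samples are kept;
   below-detection values are replaced by half the minimum detected value
   and every metabolite is rank-based inverse-normal transformed with the
   Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)). KOs need > 20% prevalence at a
   relative-abundance floor of 0.001%.
2. **ANCOM-II differential abundance.** After classifying zeros as
   structural / outlier / sampling, every pairwise log-ratio
   log(xᵢ/xⱼ) is regressed on the outcome plus covariates; the W
   statistic counts, per taxon, how many of its m − 1 comparisons survive
   a within-taxon BH correction; detection at W ≥ 0.7 (m − 1). Taxa
   structurally absent from one outcome group are auto-detected.
3. **Quantification and replication.** Detected species are fit by
   binary logistic regression in discovery and validation sets; estimates
   are pooled by DerSimonian–Laird random-effects meta-analysis and a
   species is retained when the pooled p < 0.05 with directionally
   concordant set-level estimates. Three nested covariate models
   (Model 1: demographics/lifestyle; Model 2: + BMI, SBP; Model 3:
   + medication use) quantify the final associations, with a linear
   trend test across disease grades 0–3.
4. **Metabolome-wide association.** One covariate-adjusted linear model
   per (species, metabolite) pair, BH FDR < 0.1 per species.
5. **Prevalent and incident metabolite signatures.** Species-associated
   metabolites are tested against prevalent disease (logistic, per 1 SD)
   and the survivors against incident disease with **modified Poisson
   regression** — a log-link Poisson GLM on the binary outcome with HC0
   sandwich standard errors, whose exp(β) estimates the relative risk for
   common outcomes.
6. **Proxy association.** Per species, metabolite effects are
   standardized to Z = β/SE on the species side (MWAA) and the outcome
   side (modified Poisson), and the two Z vectors are Spearman-correlated
   over the incident-associated metabolites; p < 0.05 marks a proxy
   association between the species and incident disease. The Spearman p
   is an exact permutation enumeration for k ≤ 9 and the t approximation
   otherwise.
7. **Risk prediction.** Elastic-net logistic regression with nested
   (default 10 × 10-fold) cross-validation; honest out-of-fold AUC with a
   percentile-bootstrap CI (default 10,000 draws); exact linear-model
   SHAP attributions φᵢⱼ = βⱼ (xᵢⱼ − x̄ⱼ); DeLong test for the AUC change
   over the traditional-risk-factor model (age, BMI, SBP, smoking,
   drinking, LDL-C, diabetes).
8. **KO triangle.** Species–KO and KO–metabolite linear associations
   (FDR < 0.1) plus KO–prevalent-disease logistic flags (nominal
   p < 0.05), assembled into sign-concordant species–KO–metabolite edges
   with covariate-adjusted partial correlations.

Because real cohorts of this design are access-restricted, the package
ships a first-class synthetic cohort generator
(`lvddlink.synthesize`): log-normal latent abundances → multinomial
species counts with planted differential species and structural zeros, a
logistic prevalent outcome, species-driven metabolites with
left-censoring, a log-link incident outcome (true RR = exp(planted γ)),
and species-tracking KO blocks — all recorded in a `GroundTruth` object
for recovery testing.

## Worked example

```python
from lvddlink import CohortConfig, RunConfig, LVDDStudy, generate_cohort

cfg = CohortConfig(n=800, n_species=120, n_metabolites=150, n_kos=300,
                   n_extra_assoc_metabolites=60, kos_per_proxy_species=15)
species, metabolites, kos, meta, truth = generate_cohort(cfg, seed=42)
res = LVDDStudy(species, metabolites, kos, meta,
                RunConfig(seed=42, outer_folds=5, inner_folds=3,
                          n_boot=1000)).fit()
print(res.summary())
```

prints

```
Gut microbiome -> metabolome -> LVDD study
  seed: 42
  samples: 800 (discovery 595, validation 205, concurrent 310, baseline 569, incident 241)
  species tested: 120 (of 120)
  ANCOM-II detected: 10
  retained after meta + concordance: 6 -> sp0000, sp0002, sp0003, sp0004, sp0005, sp0006
  metabolites tested: 140 (of 150)
  species-associated metabolites (q<0.1): 72
  prevalent-associated: 39; incident-associated: 11
  proxy sp0000: R=-0.57, p=0.066
  ...
  AUC traditional 0.621 (0.542, 0.699) vs augmented 0.768 (0.703, 0.831); DeLong p = 0.00017
  KO triangle edges: 34
```

Six of the seven planted differential species are recovered at this
reduced scale (all seven at the full scale below); the metabolite-
augmented prediction model clearly improves on traditional risk factors
(AUC 0.77 vs 0.62, DeLong p = 1.7 × 10⁻⁴); the protective planted
species shows a negative proxy correlation with incident disease.

The same chain is scriptable from the shell:

```bash
lvddlink simulate --n 2000 --outdir cohort/
lvddlink run-study --species cohort/species_counts.tsv \
    --metabolites cohort/metabolite_intensities.tsv \
    --kos cohort/ko_relabund.tsv --metadata cohort/sample_metadata.tsv \
    --seed 1 --outdir study_out/
```

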