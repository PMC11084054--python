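"""Synthetic multi-omics cohorts with planted ground truth.

The generator emulates the statistical structure the analysis chain
assumes, at the scale of the motivating cohort (about 2,000 adults, ~550
gut bacterial species, ~700 circulating metabolites, ~2,000 KO gene
families, 46% prevalent and 36% incident disease among baseline-negative
subjects):

* species counts: log-normal latent abundances -> per-sample multinomial
  draws, which yields realistic zero inflation and compositional
  coupling;
* a small set of planted differential species acts on the prevalent
  outcome through a logistic model on covariates + their CLR values;
* a few extra species receive structural zeros (hard absence in the
  case stratum);
* metabolites are linear combinations of planted species CLR values plus
  covariate effects and Gaussian noise, then left-censored at a
  configurable quantile (below-detection values become NaN);
* the incident outcome among baseline-negative subjects follows a
  log-link Bernoulli model on the planted metabolites, so the true
  relative risk per metabolite SD is exp(gamma);
* KO relative abundances come from a second multinomial whose planted
  blocks track their parent species.

Three species are wired for proxy-association recovery: the metabolite
effects of the two protective species run opposite to the metabolites'
incident-risk effects (expected proxy R < 0) and those of one
risk-raising species run parallel (expected R > 0).

``effect_scale=0`` switches every planted effect (and the structural
zeros) off, giving a fully null cohort for calibration testing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .tables import FeatureTable, SampleMetadata, TableKind


@dataclass
class CohortConfig:
    """Generator settings; defaults reproduce the motivating study's
    marginal frequencies in expectation."""

    n: int = 2000
    n_species: int = 550
    n_metabolites: int = 700
    n_kos: int = 2100
    seq_depth: int = 100_000
    ko_depth: int = 200_000
    # planted structure
    da_log_odds: tuple[float, ...] = (-1.2, -1.0, -0.8, 1.2, 1.0, 0.9, 0.8)
    n_structural_zero_species: int = 3
    n_outcome_metabolites: int = 21
    n_extra_assoc_metabolites: int = 200
    gamma_range: tuple[float, float] = (0.08, 0.16)
    n_outcome_metabolites_negative: int = 8
    proxy_edge_scale: float = 1.5
    kos_per_proxy_species: int = 40
    effect_scale: float = 1.0
    # marginal targets
    prevalent_fraction: float = 0.459
    incident_fraction: float = 0.357
    # censoring / set sizes
    censor_quantile: float = 0.10
    heavy_censor_fraction: float = 0.08
    heavy_censor_quantile: float = 0.30
    discovery_fraction: float = 0.755
    metabolome_fraction: float = 0.40
    baseline_v1_fraction: float = 0.70
    followup_fraction: float = 0.55
    # species latent scale
    species_mu_sd: float = 2.4
    species_noise_sd: tuple[float, float] = (0.6, 1.4)

    def __post_init__(self) -> None:
        if self.n < 50:
            raise ValueError("n must be at least 50")
        if self.n_species < 10:
            raise ValueError("need at least 10 species")
        effects = np.concatenate([np.asarray(self.da_log_odds, dtype=float),
                                  np.asarray(self.gamma_range, dtype=float)])
        if not np.isfinite(effects).all() or np.abs(effects).max() > 20:
            raise ValueError("planted effects must be finite and numerically sane")
        if len(self.da_log_odds) + self.n_structural_zero_species > self.n_species // 4:
            raise ValueError("too many planted species for the table size")
        if self.n_outcome_metabolites + self.n_extra_assoc_metabolites > self.n_metabolites:
            raise ValueError("more planted metabolites than metabolites")


@dataclass
class GroundTruth:
    """What was planted, for recovery testing."""

    da_species: dict[str, float]                    # species id -> log odds
    structural_zero_species: list[str]
    proxy_species: dict[str, int]                   # species id -> expected sign of R
    outcome_metabolites: dict[str, float]           # metabolite id -> incident log RR / SD
    species_metabolite_edges: list[tuple[str, str, float]]
    ko_edges: list[tuple[str, str, float]]
    params: dict

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["species_metabolite_edges"] = [list(e) for e in self.species_metabolite_edges]
        payload["ko_edges"] = [list(e) for e in self.ko_edges]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def default_paper_scale() -> CohortConfig:
    """Settings at the scale of the motivating cohort."""
    return CohortConfig()


def _calibrate_intercept(target: float, eta: np.ndarray, link: str) -> float:
    """Intercept making mean(link^{-1}(a + eta)) equal the target rate."""
    if link == "logit":
        f = lambda a: expit(a + eta).mean() - target
    else:  # log link, probabilities clipped below 0.95
        f = lambda a: np.minimum(np.exp(a + eta), 0.95).mean() - target
    return brentq(f, -30.0, 5.0 if link == "log" else 30.0)


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[FeatureTable, FeatureTable, FeatureTable, SampleMetadata, GroundTruth]:
    """Draw one synthetic cohort.

    Returns (species counts, metabolite intensities, KO relative
    abundances, sample metadata, ground truth).  Identical seeds give
    byte-identical outputs.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n, m_sp = cfg.n, cfg.n_species
    es = cfg.effect_scale
    sample_ids = [f"S{i:05d}" for i in range(n)]
    species_ids = [f"sp{k:04d}" for k in range(m_sp)]
    metab_ids = [f"met{k:04d}" for k in range(cfg.n_metabolites)]
    ko_ids = [f"K{k:05d}" for k in range(cfg.n_kos)]

    # ------------------------------------------------------------ covariates
    age = rng.normal(59.4, 8.0, n)
    sex = rng.binomial(1, 0.671, n)
    bmi = rng.normal(30.0, 5.5, n)
    sbp = rng.normal(125.0, 14.0, n) + 0.25 * (age - 59.4)
    meta = pd.DataFrame({
        "age": age,
        "sex": sex,
        "center": rng.integers(0, 4, n),
        "education": rng.integers(0, 3, n),
        "income": rng.integers(0, 3, n),
        "smoking": rng.integers(0, 3, n),
        "alcohol": rng.integers(0, 3, n),
        "physical_activity": np.exp(rng.normal(np.log(500.0), 0.8, n)),
        "ahei2010": rng.normal(48.0, 7.0, n),
        "abx_probiotic_use": rng.binomial(1, 0.05, n),
        "bmi": bmi,
        "sbp": sbp,
        "med_antidiabetic": rng.binomial(1, 0.25, n),
        "med_antihypertensive": rng.binomial(1, 0.35, n),
        "med_lipidlowering": rng.binomial(1, 0.30, n),
        "ldl_c": rng.normal(120.0, 33.0, n),
        "diabetes": rng.binomial(1, 0.30, n),
    }, index=sample_ids)

    # ------------------------------------------------------------ species
    mu = rng.normal(0.0, cfg.species_mu_sd, m_sp)
    sigma = rng.uniform(*cfg.species_noise_sd, m_sp)
    n_da = len(cfg.da_log_odds)
    da_idx = np.arange(n_da)           # first block: differential species
    mu[da_idx] = 1.0                   # common enough to pass prevalence
    sz_idx = np.arange(n_da, n_da + cfg.n_structural_zero_species)
    mu[sz_idx] = 0.5
    log_latent = mu[None, :] + rng.normal(0.0, 1.0, (n, m_sp)) * sigma[None, :]
    # exact CLR of the latent composition (log-scale centering)
    clr_latent = log_latent - log_latent.mean(axis=1, keepdims=True)
    z_species = (clr_latent - clr_latent.mean(axis=0)) / clr_latent.std(axis=0, ddof=1)

    # ------------------------------------------------------------ prevalent outcome
    betas = es * np.asarray(cfg.da_log_odds, dtype=float)
    eta_cov = (0.02 * (age - 59.4) + 0.03 * (bmi - 30.0)
               + 0.01 * (sbp - 125.0) + 0.4 * meta["diabetes"].to_numpy()
               + 0.15 * sex)
    eta_prev = eta_cov + z_species[:, da_idx] @ betas
    alpha = _calibrate_intercept(cfg.prevalent_fraction, eta_prev, "logit")
    prevalent = rng.binomial(1, expit(alpha + eta_prev))

    # grades among cases: terciles of the case linear predictor -> 1..3
    grade = np.zeros(n, dtype=int)
    case = prevalent == 1
    if case.any():
        cuts = np.quantile(eta_prev[case], [1 / 3, 2 / 3])
        grade[case] = 1 + np.searchsorted(cuts, eta_prev[case])

    # structural zeros: hard absence in the case stratum
    structural_ids: list[str] = []
    latent = np.exp(log_latent)
    if es != 0:
        for k in sz_idx:
            latent[case, k] = 0.0
            structural_ids.append(species_ids[k])
    comp = latent / latent.sum(axis=1, keepdims=True)
    depth = rng.integers(int(0.8 * cfg.seq_depth), int(1.2 * cfg.seq_depth), n)
    counts = np.empty((n, m_sp), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depth[i], comp[i])
    species_ft = FeatureTable(
        pd.DataFrame(counts, index=sample_ids, columns=species_ids),
        TableKind.counts,
    )

    # ------------------------------------------------------------ metabolites
    n_out = cfg.n_outcome_metabolites
    mags = np.linspace(cfg.gamma_range[0], cfg.gamma_range[1], n_out)
    signs = np.ones(n_out)
    signs[: cfg.n_outcome_metabolites_negative] = -1.0
    gamma = es * rng.permutation(signs * mags)
    out_met_idx = np.arange(n_out)

    # proxy wiring: species 0 and 1 oppose the risk direction, species 3 follows it
    proxy_map = {k: s for k, s in {0: -1, 1: -1, 3: +1}.items() if k < n_da}
    W = np.zeros((m_sp, cfg.n_metabolites))
    edges: list[tuple[str, str, float]] = []
    for s, sign in proxy_map.items():
        w = sign * cfg.proxy_edge_scale * gamma + rng.normal(0, 0.03, n_out) * es
        W[s, out_met_idx] = w
        edges += [(species_ids[s], metab_ids[j], float(w[i]))
                  for i, j in enumerate(out_met_idx) if w[i] != 0]
    # extra species-associated metabolites hang off the non-proxy planted
    # species, so the incident-associated set stays close to the planted one
    extra_idx = np.arange(n_out, n_out + cfg.n_extra_assoc_metabolites)
    non_proxy = np.array([k for k in range(n_da) if k not in proxy_map]
                         or list(range(n_da)))
    owners = rng.choice(non_proxy, extra_idx.size)
    extra_w = es * rng.uniform(0.25, 0.5, extra_idx.size) * rng.choice([-1, 1], extra_idx.size)
    for j, s, w in zip(extra_idx, owners, extra_w):
        W[da_idx[s], j] = w
        if w != 0:
            edges.append((species_ids[da_idx[s]], metab_ids[j], float(w)))

    age_std = (age - age.mean()) / age.std(ddof=1)
    cov_effect = np.where(rng.random(cfg.n_metabolites) < 0.3,
                          rng.normal(0, 0.15, cfg.n_metabolites), 0.0)
    M = z_species @ W + age_std[:, None] * cov_effect[None, :] \
        + rng.normal(0.0, 1.0, (n, cfg.n_metabolites))
    M_std = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)

    # ------------------------------------------------------------ incident outcome
    # traditional risk factors carry real incident signal, so the
    # reference prediction model is informative on its own
    controls = prevalent == 0
    bmi_std = (bmi - bmi.mean()) / bmi.std(ddof=1)
    sbp_std = (sbp - sbp.mean()) / sbp.std(ddof=1)
    eta_inc = (M_std[:, out_met_idx] @ gamma) \
        + 0.30 * age_std + 0.18 * bmi_std + 0.18 * sbp_std \
        + 0.35 * meta["diabetes"].to_numpy() \
        - 0.10 * (meta["ldl_c"].to_numpy() - 120.0) / 33.0 \
        + 0.08 * meta["alcohol"].to_numpy()
    kappa = _calibrate_intercept(cfg.incident_fraction, eta_inc[controls], "log")
    p_inc = np.minimum(np.exp(kappa + eta_inc), 0.95)
    incident_draw = rng.binomial(1, p_inc)
    followup = rng.binomial(1, cfg.followup_fraction, n).astype(bool)
    incident = np.where(controls & followup, incident_draw, np.nan)

    # left-censoring: intensities below a per-metabolite quantile are missing
    intensity = np.exp(2.0 + 0.5 * M)
    q = np.full(cfg.n_metabolites, cfg.censor_quantile)
    heavy = rng.random(cfg.n_metabolites) < cfg.heavy_censor_fraction
    q[heavy] = cfg.heavy_censor_quantile
    lod = np.array([np.quantile(intensity[:, j], q[j]) for j in range(cfg.n_metabolites)])
    censored = intensity < lod[None, :]
    intensity = np.where(censored, np.nan, intensity)
    metab_ft = FeatureTable(
        pd.DataFrame(intensity, index=sample_ids, columns=metab_ids),
        TableKind.intensity,
    )

    # ------------------------------------------------------------ KOs
    ko_mu = rng.normal(0.0, 2.0, cfg.n_kos)
    ko_log = ko_mu[None, :] + rng.normal(0.0, 1.0, (n, cfg.n_kos))
    ko_edges: list[tuple[str, str, float]] = []
    block = 0
    for s in proxy_map:
        sl = slice(block, block + cfg.kos_per_proxy_species)
        loadings = es * rng.uniform(0.4, 0.8, cfg.kos_per_proxy_species) \
            * rng.choice([-1, 1], cfg.kos_per_proxy_species)
        ko_log[:, sl] += np.outer(z_species[:, s], loadings)
        for i, k in enumerate(range(block, block + cfg.kos_per_proxy_species)):
            if loadings[i] != 0:
                ko_edges.append((species_ids[s], ko_ids[k], float(loadings[i])))
        block += cfg.kos_per_proxy_species
    ko_comp = np.exp(ko_log)
    ko_comp /= ko_comp.sum(axis=1, keepdims=True)
    ko_counts = np.empty((n, cfg.n_kos), dtype=np.int64)
    for i in range(n):
        ko_counts[i] = rng.multinomial(cfg.ko_depth, ko_comp[i])
    ko_rel = ko_counts / ko_counts.sum(axis=1, keepdims=True)
    ko_ft = FeatureTable(
        pd.DataFrame(ko_rel, index=sample_ids, columns=ko_ids),
        TableKind.ko_relabund,
    )

    # ------------------------------------------------------------ metadata
    meta["prevalent_lvdd"] = prevalent
    meta["lvdd_grade"] = grade
    meta["incident_lvdd"] = incident
    meta["analysis_set"] = np.where(
        rng.random(n) < cfg.discovery_fraction, "discovery", "validation")
    meta["has_metabolome"] = rng.random(n) < cfg.metabolome_fraction
    meta["in_baseline_v1"] = rng.random(n) < cfg.baseline_v1_fraction
    meta["has_followup"] = followup

    truth = GroundTruth(
        da_species={species_ids[k]: float(betas[i]) for i, k in enumerate(da_idx)
                    if betas[i] != 0},
        structural_zero_species=structural_ids,
        proxy_species={species_ids[s]: sign for s, sign in proxy_map.items()
                       if es != 0},
        outcome_metabolites={metab_ids[j]: float(gamma[i])
                             for i, j in enumerate(out_met_idx) if gamma[i] != 0},
        species_metabolite_edges=edges,
        ko_edges=ko_edges,
        params={"n": n, "n_species": m_sp, "n_metabolites": cfg.n_metabolites,
                "n_kos": cfg.n_kos, "effect_scale": es, "seed": seed,
                "censor_quantile": cfg.censor_quantile,
                "prevalent_fraction": cfg.prevalent_fraction,
                "incident_fraction": cfg.incident_fraction},
    )
    return species_ft, metab_ft, ko_ft, SampleMetadata(meta), truth
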