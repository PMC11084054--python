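"""The whole-study model: orchestration of the analysis graph.

Stages, each on its own analysis set:

1. preprocessing — prevalence/detection/KO filters, CLR, half-minimum +
   INT;
2. ANCOM-II species discovery on the discovery set;
3. logistic quantification of the detected species in discovery and
   validation sets, DerSimonian-Laird pooling, retention at pooled
   p < 0.05 with directional concordance;
4. combined-set logistic models (Model 1/2/3) and grade-trend tests for
   the retained species;
5. metabolome-wide association of retained species (concurrent set, BH
   FDR per species);
6. logistic models of species-associated metabolites against prevalent
   disease (baseline set, BH FDR);
7. modified Poisson models of prevalent-associated metabolites against
   the incident outcome (baseline-negative subjects with follow-up);
8. proxy association per retained species over the incident-associated
   metabolites;
9. elastic-net risk prediction: traditional risk factors vs risk factors
   + incident-associated metabolites, AUC bootstrap CIs, DeLong test;
10. the KO triangle: species-KO and metabolite-KO linear associations
    (FDR < 0.1), KO-prevalent logistic flags (nominal p < 0.05), edges
    where the three paths are sign-concordant, with partial correlations
    for reported edges.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancom import AncomII
from .config import RunConfig, get_logger
from .models import (AssociationResult, bh_fdr, fit_linear, fit_logistic,
                     grade_trend, modified_poisson, pairwise_linear_assoc,
                     partial_correlation, random_effects_meta, results_frame,
                     standardize)
from .predict import NestedElasticNet, compare_auc
from .preprocess import clr_transform, filter_by_detection, filter_by_prevalence, \
    filter_kos, int_transform
from .proxy import ProxyAssociation, proxy_scatter_frame, to_zscores
from .tables import (DISCOVERY_COVARIATES, MODEL_COVARIATES,
                     TRADITIONAL_RISK_FACTORS, AlignedBundle, FeatureTable,
                     SampleMetadata)


@dataclass
class StudyResults:
    """All per-stage outputs, the manifest, and a plain-text summary."""

    config: RunConfig
    manifest: dict
    ancom: pd.DataFrame
    species_meta: pd.DataFrame
    retained_species: list[str]
    species_models: pd.DataFrame          # Models 1-3, combined set
    grade_trends: pd.DataFrame
    mwaa: pd.DataFrame                    # all species x metabolite fits
    species_associated_metabolites: list[str]
    prevalent_metabolites: pd.DataFrame
    prevalent_associated: list[str]
    incident_metabolites: pd.DataFrame
    incident_associated: list[str]
    proxy: pd.DataFrame
    proxy_scatter: pd.DataFrame
    prediction_traditional: object
    prediction_augmented: object
    delta_auc_p: float | None
    ko_triangle: pd.DataFrame

    def manifest_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.manifest, sort_keys=True, default=str).encode()
        ).hexdigest()

    def summary(self) -> str:
        man = self.manifest
        lines = [
            "Gut microbiome -> metabolome -> LVDD study",
            f"  seed: {self.config.seed}",
            f"  samples: {man['n_total']} "
            f"(discovery {man['n_discovery']}, validation {man['n_validation']}, "
            f"concurrent {man['n_concurrent']}, baseline {man['n_baseline_v1']}, "
            f"incident {man['n_incident']})",
            f"  species tested: {man['n_species_filtered']}"
            f" (of {man['n_species_input']})",
            f"  ANCOM-II detected: {man['n_species_detected']}",
            f"  retained after meta + concordance: {len(self.retained_species)}"
            f" -> {', '.join(self.retained_species)}",
            f"  metabolites tested: {man['n_metabolites_filtered']}"
            f" (of {man['n_metabolites_input']})",
            f"  species-associated metabolites (q<{self.config.fdr_level}): "
            f"{len(self.species_associated_metabolites)}",
            f"  prevalent-associated: {len(self.prevalent_associated)}; "
            f"incident-associated: {len(self.incident_associated)}",
        ]
        for _, row in self.proxy.iterrows():
            lines.append(f"  proxy {row['species_id']}: R={row['R']:+.2f}, "
                         f"p={row['p']:.2g}")
        if self.prediction_traditional is not None:
            a, b = self.prediction_traditional, self.prediction_augmented
            lines.append(
                f"  AUC traditional {a.auc:.3f} "
                f"({a.auc_ci95[0]:.3f}, {a.auc_ci95[1]:.3f}) vs augmented "
                f"{b.auc:.3f} ({b.auc_ci95[0]:.3f}, {b.auc_ci95[1]:.3f}); "
                f"DeLong p = {self.delta_auc_p:.2g}")
        lines.append(f"  KO triangle edges: {len(self.ko_triangle)}")
        return "\n".join(lines)

    def write(self, outdir) -> None:
        """Stage-named TSVs + JSON manifest + plain-text summary."""
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.ancom.to_csv(out / "ancom_results.tsv", sep="\t")
        self.species_meta.to_csv(out / "species_meta.tsv", sep="\t", index=False)
        self.species_models.to_csv(out / "species_models.tsv", sep="\t", index=False)
        self.grade_trends.to_csv(out / "grade_trends.tsv", sep="\t", index=False)
        self.mwaa.to_csv(out / "mwaa.tsv", sep="\t", index=False)
        self.prevalent_metabolites.to_csv(out / "prevalent_metabolites.tsv",
                                          sep="\t", index=False)
        self.incident_metabolites.to_csv(out / "incident_metabolites.tsv",
                                         sep="\t", index=False)
        self.proxy.to_csv(out / "proxy_results.tsv", sep="\t", index=False)
        self.proxy_scatter.to_csv(out / "proxy_scatter.tsv", sep="\t", index=False)
        self.ko_triangle.to_csv(out / "ko_triangle.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)
        (out / "summary.txt").write_text(self.summary() + "\n")


class LVDDStudy:
    """End-to-end study model over an aligned multi-omics bundle.

    Parameters
    ----------
    species, metabolites, kos : FeatureTable
        Raw species counts (or relative abundances), metabolite
        intensities with NaN below detection, KO relative abundances.
    meta : SampleMetadata
    config : RunConfig
    """

    def __init__(
        self,
        species: FeatureTable,
        metabolites: FeatureTable,
        kos: FeatureTable | None,
        meta: SampleMetadata,
        config: RunConfig | None = None,
    ) -> None:
        self.species = species
        self.metabolites = metabolites
        self.kos = kos
        self.meta = meta
        self.config = config or RunConfig()
        self.log = get_logger("study")

    # -- helpers -------------------------------------------------------
    def _covs(self, frame: pd.DataFrame, model_id: int | None = None,
              names: list[str] | None = None) -> pd.DataFrame:
        cols = names if names is not None else MODEL_COVARIATES[model_id or self.config.model_id]
        return frame[cols]

    # -- API -----------------------------------------------------------
    def fit(self) -> StudyResults:
        cfg = self.config
        meta = self.meta
        f = meta.frame
        manifest: dict = {"seed": cfg.seed, "config": cfg.asdict(),
                          "n_total": len(f)}

        masks = {name: meta.set_mask(name).to_numpy()
                 for name in ("discovery", "validation", "concurrent",
                              "baseline_v1", "incident")}
        for name, mask in masks.items():
            manifest[f"n_{name}"] = int(mask.sum())
            self.log.info("analysis set %s: n=%d", name, mask.sum())

        # ---- stage 1: preprocessing ---------------------------------
        manifest["n_species_input"] = self.species.shape[1]
        species_f, sp_rep = filter_by_prevalence(self.species, cfg.species_prevalence)
        manifest["n_species_filtered"] = sp_rep.features_out
        clr_all = clr_transform(species_f, cfg.pseudocount)
        metab_f, met_rep = filter_by_detection(self.metabolites, cfg.metabolite_detection)
        manifest["n_metabolites_input"] = met_rep.features_in
        manifest["n_metabolites_filtered"] = met_rep.features_out
        metab_int, _ = int_transform(metab_f)
        self.log.info("species %d -> %d, metabolites %d -> %d",
                      sp_rep.features_in, sp_rep.features_out,
                      met_rep.features_in, met_rep.features_out)

        # ---- stage 2: ANCOM-II on the discovery set -----------------
        disc_ids = list(f.index[masks["discovery"]])
        sp_disc, _ = filter_by_prevalence(self.species.subset_samples(disc_ids),
                                          cfg.species_prevalence)
        ancom = AncomII(
            sp_disc, f.loc[disc_ids, "prevalent_lvdd"].to_numpy(),
            self._covs(f.loc[disc_ids], names=DISCOVERY_COVARIATES),
            alpha=cfg.ancom_alpha, cutoff=cfg.ancom_cutoff,
            pseudocount=cfg.pseudocount,
            structural_threshold=cfg.structural_zero_threshold,
        ).fit()
        detected = [s for s in ancom.detected if s in clr_all.feature_ids]
        manifest["n_species_detected"] = len(detected)
        self.log.info("ANCOM-II detected %d species", len(detected))

        # ---- stage 3: discovery/validation logistic + DL meta -------
        meta_rows, per_set_rows = [], []
        for sid in detected:
            ests = []
            for set_name in ("discovery", "validation"):
                mask = masks[set_name]
                ids = list(f.index[mask])
                res = fit_logistic(
                    f.loc[ids, "prevalent_lvdd"].to_numpy(),
                    clr_all.data.loc[ids, sid].to_numpy(),
                    self._covs(f.loc[ids], model_id=1),
                    feature_id=sid, exposure_id=f"prevalent/{set_name}",
                    model_id=1)
                per_set_rows.append(res)
                ests.append((res.beta, res.se))
            if any(not np.isfinite(b) or not np.isfinite(s) for b, s in ests):
                continue
            meta_rows.append(random_effects_meta(ests, feature_id=sid))
        species_meta = pd.DataFrame([m.to_dict() for m in meta_rows])
        retained = [m.feature_id for m in meta_rows if m.retained]
        manifest["n_species_retained"] = len(retained)
        self.log.info("retained %d species after pooling + concordance", len(retained))

        # ---- stage 4: combined-set models 1-3 + grade trend ---------
        model_rows, trend_rows = [], []
        for sid in retained:
            x = clr_all.data[sid].to_numpy()
            for mid in (1, 2, 3):
                model_rows.append(fit_logistic(
                    f["prevalent_lvdd"].to_numpy(), x,
                    self._covs(f, model_id=mid),
                    feature_id=sid, exposure_id="prevalent/combined",
                    model_id=mid))
            trend_rows.append(grade_trend(
                x, f["lvdd_grade"].to_numpy(),
                self._covs(f, model_id=1), feature_id=sid))
        species_models = results_frame(model_rows) if model_rows else pd.DataFrame()
        grade_trends = results_frame(trend_rows) if trend_rows else pd.DataFrame()

        # ---- stage 5: MWAA (concurrent set) -------------------------
        conc_ids = list(f.index[masks["concurrent"]])
        mwaa_frames = []
        if retained:
            mwaa_all = pairwise_linear_assoc(
                clr_all.data.loc[conc_ids, retained],
                metab_int.data.loc[conc_ids],
                self._covs(f.loc[conc_ids], model_id=1))
            # one BH family per species across the metabolome
            for sid, grp in mwaa_all.groupby("exposure_id", sort=False):
                grp = grp.copy()
                grp["q"] = bh_fdr(grp["p"].to_numpy())
                mwaa_frames.append(grp)
        mwaa = pd.concat(mwaa_frames, ignore_index=True) if mwaa_frames else \
            pd.DataFrame(columns=["exposure_id", "feature_id", "beta", "se",
                                  "p", "n", "q"])
        sig = mwaa[mwaa["q"] < cfg.fdr_level]
        species_assoc_mets = list(dict.fromkeys(sig["feature_id"]))
        manifest["n_species_associated_metabolites"] = len(species_assoc_mets)
        self.log.info("%d metabolites associated with >=1 retained species",
                      len(species_assoc_mets))

        # ---- stage 6: prevalent-LVDD metabolite logistic ------------
        base_ids = list(f.index[masks["baseline_v1"]])
        prev_rows = []
        for met in species_assoc_mets:
            x = standardize(metab_int.data.loc[base_ids, met].to_numpy())
            prev_rows.append(fit_logistic(
                f.loc[base_ids, "prevalent_lvdd"].to_numpy(), x,
                self._covs(f.loc[base_ids], model_id=1),
                feature_id=met, exposure_id="prevalent", model_id=1))
        prevalent_metabolites = results_frame(prev_rows) if prev_rows else pd.DataFrame()
        if len(prevalent_metabolites):
            prevalent_metabolites["q"] = bh_fdr(prevalent_metabolites["p"].to_numpy())
            prev_assoc = list(prevalent_metabolites.loc[
                prevalent_metabolites["q"] < cfg.fdr_level, "feature_id"])
        else:
            prev_assoc = []
        manifest["n_prevalent_associated"] = len(prev_assoc)

        # ---- stage 7: incident modified Poisson ---------------------
        inc_ids = list(f.index[masks["incident"]])
        y_inc = f.loc[inc_ids, "incident_lvdd"].to_numpy()
        inc_rows = []
        for met in prev_assoc:
            x = standardize(metab_int.data.loc[inc_ids, met].to_numpy())
            inc_rows.append(modified_poisson(
                y_inc, x, self._covs(f.loc[inc_ids], model_id=1),
                feature_id=met, exposure_id="incident", model_id=1))
        incident_metabolites = results_frame(inc_rows) if inc_rows else pd.DataFrame()
        if len(incident_metabolites):
            incident_metabolites["q"] = bh_fdr(incident_metabolites["p"].to_numpy())
            inc_assoc = list(incident_metabolites.loc[
                incident_metabolites["q"] < cfg.fdr_level, "feature_id"])
        else:
            inc_assoc = []
        manifest["n_incident_associated"] = len(inc_assoc)
        self.log.info("prevalent-associated %d, incident-associated %d",
                      len(prev_assoc), len(inc_assoc))

        # ---- stage 8: proxy association -----------------------------
        proxy_rows, scatter_frames = [], []
        if len(inc_assoc) >= 3:
            z_out = pd.Series(
                {r.feature_id: r.z for r in inc_rows
                 if r.feature_id in inc_assoc})
            for sid in retained:
                sub = mwaa[(mwaa["exposure_id"] == sid)
                           & mwaa["feature_id"].isin(inc_assoc)]
                sub = sub.set_index("feature_id").loc[z_out.index]
                z_sp = sub["beta"] / sub["se"]
                pr = ProxyAssociation(z_sp, z_out, species_id=sid).fit()
                proxy_rows.append(pr.to_dict())
                sc = proxy_scatter_frame(z_sp, z_out)
                sc.insert(0, "species_id", sid)
                scatter_frames.append(sc)
        proxy = pd.DataFrame(proxy_rows) if proxy_rows else \
            pd.DataFrame(columns=["species_id", "R", "p", "k", "method",
                                  "significant"])
        proxy_scatter = pd.concat(scatter_frames, ignore_index=True) \
            if scatter_frames else pd.DataFrame()

        # ---- stage 9: prediction ------------------------------------
        pred_trad = pred_aug = None
        delta_p = None
        if len(inc_assoc) >= 1:
            trad = f.loc[inc_ids, TRADITIONAL_RISK_FACTORS].astype(float)
            mets = metab_int.data.loc[inc_ids, inc_assoc]
            aug = pd.concat([trad, mets], axis=1)
            pred_trad = NestedElasticNet(
                trad, y_inc, outer=cfg.outer_folds, inner=cfg.inner_folds,
                repeats=cfg.cv_repeats, n_boot=cfg.n_boot, seed=cfg.seed).fit()
            pred_aug = NestedElasticNet(
                aug, y_inc, outer=cfg.outer_folds, inner=cfg.inner_folds,
                repeats=cfg.cv_repeats, n_boot=cfg.n_boot, seed=cfg.seed).fit()
            delta_p = compare_auc(pred_aug.oof_predictions,
                                  pred_trad.oof_predictions, y_inc)
            manifest["auc_traditional"] = pred_trad.auc
            manifest["auc_augmented"] = pred_aug.auc
            manifest["delta_auc_p"] = delta_p
            self.log.info("AUC traditional %.3f vs augmented %.3f (p=%.3g)",
                          pred_trad.auc, pred_aug.auc, delta_p)

        # ---- stage 10: KO triangle ----------------------------------
        ko_triangle = self._ko_triangle(
            retained_species=[r["species_id"] for r in proxy_rows
                              if r["significant"]] or retained,
            clr_all=clr_all, metab_int=metab_int, inc_assoc=inc_assoc,
            masks=masks)
        manifest["n_ko_triangle_edges"] = len(ko_triangle)

        return StudyResults(
            config=cfg, manifest=manifest, ancom=ancom.frame,
            species_meta=species_meta, retained_species=retained,
            species_models=species_models, grade_trends=grade_trends,
            mwaa=mwaa, species_associated_metabolites=species_assoc_mets,
            prevalent_metabolites=prevalent_metabolites,
            prevalent_associated=prev_assoc,
            incident_metabolites=incident_metabolites,
            incident_associated=inc_assoc, proxy=proxy,
            proxy_scatter=proxy_scatter,
            prediction_traditional=pred_trad, prediction_augmented=pred_aug,
            delta_auc_p=delta_p, ko_triangle=ko_triangle)

    # ------------------------------------------------------------------
    def _ko_triangle(self, retained_species, clr_all, metab_int, inc_assoc,
                     masks) -> pd.DataFrame:
        """Species-KO-metabolite triangle over the proxy-significant species."""
        cols = ["species_id", "ko_id", "metabolite_id",
                "beta_species_ko", "q_species_ko",
                "beta_ko_metabolite", "q_ko_metabolite",
                "beta_ko_outcome", "p_ko_outcome",
                "concordant", "partial_r", "partial_p"]
        if self.kos is None or not retained_species or not inc_assoc:
            return pd.DataFrame(columns=cols)
        cfg = self.config
        f = self.meta.frame
        ko_f, ko_rep = filter_kos(self.kos, cfg.ko_prevalence, cfg.ko_floor)
        if ko_rep.features_out == 0:
            raise ValueError("no KOs left after filtering")
        conc_ids = list(f.index[masks["concurrent"]])
        covs = self._covs(f.loc[conc_ids], model_id=1)
        ko_log = np.log10(ko_f.data.loc[conc_ids] + cfg.ko_floor / 10)

        # KO ~ species (linear, per-species BH family)
        sp_ko = pairwise_linear_assoc(
            clr_all.data.loc[conc_ids, retained_species], ko_log, covs)
        sp_ko["q"] = np.concatenate([
            bh_fdr(g["p"].to_numpy())
            for _, g in sp_ko.groupby("exposure_id", sort=False)])
        sp_ko_sig = sp_ko[sp_ko["q"] < cfg.fdr_level]
        kos_of_interest = sorted(set(sp_ko_sig["feature_id"]))
        if not kos_of_interest:
            return pd.DataFrame(columns=cols)

        # metabolite ~ KO (linear, per-KO BH family over incident metabolites)
        ko_met = pairwise_linear_assoc(
            ko_log[kos_of_interest], metab_int.data.loc[conc_ids, inc_assoc],
            covs)
        ko_met["q"] = np.concatenate([
            bh_fdr(g["p"].to_numpy())
            for _, g in ko_met.groupby("exposure_id", sort=False)])
        ko_met_sig = ko_met[ko_met["q"] < cfg.fdr_level]

        # prevalent outcome ~ KO (logistic, nominal p < 0.05)
        all_ids = list(f.index)
        ko_log_all = np.log10(ko_f.data.loc[all_ids] + cfg.ko_floor / 10)
        covs_all = self._covs(f, model_id=1)
        y_all = f["prevalent_lvdd"].to_numpy()
        ko_out = {}
        for ko in kos_of_interest:
            r = fit_logistic(y_all, standardize(ko_log_all[ko].to_numpy()),
                             covs_all, feature_id=ko, exposure_id="prevalent")
            ko_out[ko] = r
        sp_ko_idx = sp_ko_sig.set_index(["exposure_id", "feature_id"])
        ko_met_idx = ko_met_sig.set_index(["exposure_id", "feature_id"])
        mwaa_beta = {}

        rows = []
        for (sid, ko), sk in sp_ko_idx.iterrows():
            out = ko_out[ko]
            if not out.converged or not (out.p < 0.05):
                continue
            for (ko2, met), km in ko_met_idx.iterrows():
                if ko2 != ko:
                    continue
                key = (sid, met)
                if key not in mwaa_beta:
                    r_sm = fit_linear(
                        metab_int.data.loc[conc_ids, met].to_numpy(),
                        clr_all.data.loc[conc_ids, sid].to_numpy(), covs,
                        feature_id=met, exposure_id=sid)
                    mwaa_beta[key] = r_sm.beta
                concordant = np.sign(sk["beta"]) * np.sign(km["beta"]) \
                    == np.sign(mwaa_beta[key])
                if not concordant:
                    continue
                pr, pp = partial_correlation(
                    ko_log[ko].to_numpy(),
                    metab_int.data.loc[conc_ids, met].to_numpy(), covs)
                rows.append((sid, ko, met, sk["beta"], sk["q"], km["beta"],
                             km["q"], out.beta, out.p, True, pr, pp))
        frame = pd.DataFrame(rows, columns=cols)
        return frame.sort_values(["species_id", "ko_id", "metabolite_id"],
                                 ignore_index=True) if len(frame) else frame


def run_study(
    species: FeatureTable,
    metabolites: FeatureTable,
    kos: FeatureTable | None,
    meta: SampleMetadata,
    config: RunConfig | None = None,
) -> StudyResults:
    """Functional wrapper around :class:`LVDDStudy`."""
    return LVDDStudy(species, metabolites, kos, meta, config).fit()
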