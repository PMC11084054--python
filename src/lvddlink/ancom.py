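"""Covariate-adjusted ANCOM-II differential abundance.

For each taxon pair (i, j) the log-ratio log(x_i / x_j) is regressed on
the binary outcome plus covariates; a taxon's W statistic counts how many
of its m-1 pairwise outcome coefficients survive a within-taxon
Benjamini-Hochberg correction at ``alpha``.  A taxon is declared
differential when W >= cutoff * (m - 1) (default cutoff 0.7, the
reference-implementation convention).

Zeros are classified first:

* structural — the taxon is absent from (almost) all samples of one
  outcome group; such taxa are auto-detected as differential and kept out
  of the pairwise pool,
* outlier — a zero in a group where the taxon is otherwise abundant
  enough that a zero is an extreme lower outlier; treated as missing in
  that taxon's regressions,
* sampling — everything else; imputed by a pseudocount inside log-ratios.

Because OLS is linear in the response, the outcome coefficient of
log(x_i) - log(x_j) on a shared design equals the difference of the
per-taxon coefficients, and the pair residual sum of squares comes from
the per-taxon residual Gram matrix; all m(m-1)/2 regressions are
therefore computed with one least-squares solve.  Taxa with missing
(outlier-zero) entries fall back to per-pair complete-case fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import bh_fdr, build_design
from .tables import FeatureTable, TableKind


@dataclass
class ZeroClassification:
    """Zero taxonomy: structural per (taxon, group), outlier/sampling per cell."""

    structural: pd.DataFrame  # taxa x groups, bool
    outlier: pd.DataFrame     # samples x taxa, bool
    sampling: pd.DataFrame    # samples x taxa, bool

    def one_sided_structural(self) -> pd.Series:
        """Taxa structurally absent from exactly one outcome group."""
        return self.structural.sum(axis=1) == 1


def classify_zeros(
    table: FeatureTable,
    outcome,
    *,
    structural_threshold: float = 0.99,
    outlier_quantile: float = 0.10,
    outlier_multiplier: float = 3.0,
    pseudocount: float = 0.5,
    min_group: int = 5,
) -> ZeroClassification:
    """Classify every zero cell as structural, outlier, or sampling.

    A (taxon, group) pair is a structural zero when the taxon is zero in
    at least ``structural_threshold`` of that group's samples.  A zero is
    an outlier zero when, within its own group, the taxon's nonzero
    log-abundance distribution puts ``log(pseudocount)`` below
    ``quantile(outlier_quantile) - outlier_multiplier * SD``.
    """
    if table.kind not in (TableKind.counts, TableKind.relabund):
        raise ValueError("zero classification expects counts or relabund")
    y = np.asarray(outcome)
    groups = np.unique(y)
    X = table.values
    n, m = X.shape
    taxa = table.feature_ids
    structural = pd.DataFrame(False, index=taxa, columns=groups)
    outlier = pd.DataFrame(False, index=table.sample_ids, columns=taxa)
    zero = X == 0
    logpc = np.log(pseudocount)
    for g in groups:
        rows = y == g
        if rows.sum() < min_group:
            raise ValueError(f"outcome group {g!r} has fewer than {min_group} samples")
        zg = zero[rows]
        structural[g] = zg.mean(axis=0) >= structural_threshold
        Xg = X[rows]
        with np.errstate(divide="ignore"):
            logs = np.where(Xg > 0, np.log(np.where(Xg > 0, Xg, 1.0)), np.nan)
        nz = (~np.isnan(logs)).sum(axis=0)
        enough = nz >= max(min_group, 10)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            qs = np.nanquantile(np.where(enough[None, :], logs, np.nan),
                                outlier_quantile, axis=0)
            sds = np.nanstd(logs, axis=0)
        fence = qs - outlier_multiplier * sds
        is_outlier_taxon = enough & ~structural[g].to_numpy() & (logpc < fence)
        out_block = zg & is_outlier_taxon[None, :]
        outlier.loc[rows, :] |= pd.DataFrame(
            out_block, index=outlier.index[rows], columns=taxa)
    # structural cells: zeros of a taxon inside its structural group
    struct_cells = np.zeros_like(zero)
    for g in groups:
        rows = y == g
        struct_cells[rows] |= structural[g].to_numpy()[None, :]
    sampling = zero & ~outlier.to_numpy() & ~struct_cells
    sampling = pd.DataFrame(sampling, index=table.sample_ids, columns=taxa)
    return ZeroClassification(structural, outlier, sampling)


@dataclass
class AncomIIResults:
    """Per-taxon W statistics and detection calls."""

    frame: pd.DataFrame  # taxon-indexed: W, W_frac, detected, structural_zero_call
    m_tested: int
    alpha: float
    cutoff: float
    zero_classification: ZeroClassification

    @property
    def detected(self) -> list[str]:
        return list(self.frame.index[self.frame["detected"]])

    def summary(self) -> str:
        lines = [
            "ANCOM-II differential abundance",
            f"  taxa tested (pairwise pool): {self.m_tested}",
            f"  within-taxon alpha: {self.alpha}, W cutoff: "
            f"{self.cutoff} * (m - 1) = {self.cutoff * (self.m_tested - 1):.1f}",
            f"  detected taxa: {len(self.detected)}",
        ]
        det = self.frame[self.frame["detected"]]
        for taxon, row in det.iterrows():
            w = "structural" if row["structural_zero_call"] else f"W={int(row['W'])}"
            lines.append(f"    {taxon}: {w}")
        return "\n".join(lines)


class AncomII:
    """ANCOM-II model: compositional table + binary outcome + covariates.

    Parameters
    ----------
    table : FeatureTable
        Prevalence-filtered counts or relative abundances.
    outcome : array-like of 0/1
    covariates : DataFrame, optional
        Adjustment covariates (categoricals are dummy-encoded).
    alpha : float
        Within-taxon level for the BH-corrected pairwise p-values.
    cutoff : float
        Detection threshold as a fraction of m - 1.
    """

    def __init__(
        self,
        table: FeatureTable,
        outcome,
        covariates: pd.DataFrame | None = None,
        *,
        alpha: float = 0.05,
        cutoff: float = 0.7,
        pseudocount: float = 0.5,
        structural_threshold: float = 0.99,
        outlier_quantile: float = 0.10,
        outlier_multiplier: float = 3.0,
        p_adjust: str = "bh",
        min_group: int = 5,
    ) -> None:
        self.table = table
        self.outcome = np.asarray(outcome, dtype=float)
        self.covariates = covariates
        self.alpha = alpha
        self.cutoff = cutoff
        self.pseudocount = pseudocount
        self.structural_threshold = structural_threshold
        self.outlier_quantile = outlier_quantile
        self.outlier_multiplier = outlier_multiplier
        if p_adjust not in ("bh", "bonferroni"):
            raise ValueError("p_adjust must be 'bh' or 'bonferroni'")
        self.p_adjust = p_adjust
        self.min_group = min_group

    # -- internals ----------------------------------------------------
    def _design(self, index) -> np.ndarray:
        D = build_design(self.covariates, index=index)
        D = D.assign(_outcome=self.outcome)
        Dm = D.to_numpy(dtype=float)
        if np.linalg.matrix_rank(Dm) < Dm.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
        return Dm

    def _pairwise_pvalues(self, L: np.ndarray, D: np.ndarray) -> np.ndarray:
        """m x m matrix of two-sided p-values for the outcome coefficient of
        log-ratio regressions; NaN on the diagonal."""
        n, p = D.shape
        m = L.shape[1]
        df = n - p
        DtD_inv = np.linalg.inv(D.T @ D)
        c_out = DtD_inv[-1, -1]
        complete = ~np.isnan(L).any(axis=0)
        P = np.full((m, m), np.nan)
        idx_c = np.where(complete)[0]
        if idx_c.size:
            Lc = L[:, idx_c]
            B, *_ = np.linalg.lstsq(D, Lc, rcond=None)
            b = B[-1, :]
            R = Lc - D @ B
            G = R.T @ R
            rss = np.diag(G)
            BET = b[:, None] - b[None, :]
            RSS = np.maximum(rss[:, None] + rss[None, :] - 2 * G, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(RSS / df * c_out)
                T = BET / se
            Pc = 2 * stats.t.sf(np.abs(T), df)
            P[np.ix_(idx_c, idx_c)] = Pc
        # complete-case fallback for taxa with missing entries
        idx_m = np.where(~complete)[0]
        for i in idx_m:
            for j in range(m):
                if j == i or (j in idx_m and j < i):
                    continue
                keep = ~np.isnan(L[:, i]) & ~np.isnan(L[:, j])
                if keep.sum() <= p + 1:
                    continue
                lr = L[keep, i] - L[keep, j]
                Dk = D[keep]
                Bk, *_ = np.linalg.lstsq(Dk, lr, rcond=None)
                resid = lr - Dk @ Bk
                dfk = keep.sum() - p
                s2 = resid @ resid / dfk
                ck = np.linalg.inv(Dk.T @ Dk)[-1, -1]
                sek = np.sqrt(s2 * ck)
                pij = 2 * stats.t.sf(abs(Bk[-1] / sek), dfk)
                P[i, j] = P[j, i] = pij
        np.fill_diagonal(P, np.nan)
        return P

    # -- API ----------------------------------------------------------
    def fit(self) -> AncomIIResults:
        zc = classify_zeros(
            self.table, self.outcome,
            structural_threshold=self.structural_threshold,
            outlier_quantile=self.outlier_quantile,
            outlier_multiplier=self.outlier_multiplier,
            pseudocount=self.pseudocount,
            min_group=self.min_group,
        )
        one_sided = zc.one_sided_structural()
        any_structural = zc.structural.any(axis=1)
        taxa = list(self.table.feature_ids)
        pool = [t for t in taxa if not any_structural[t]]
        if len(pool) < 3:
            raise ValueError("need at least 3 taxa without structural zeros")
        X = self.table.data[pool].to_numpy(dtype=float)
        L = np.log(np.where(X > 0, X, self.pseudocount))
        out_mask = zc.outlier[pool].to_numpy()
        L[out_mask] = np.nan
        D = self._design(self.table.data.index)
        P = self._pairwise_pvalues(L, D)
        m = len(pool)
        W = np.zeros(m, dtype=int)
        for i in range(m):
            pi = np.delete(P[i], i)
            ok = ~np.isnan(pi)
            if not ok.any():
                continue
            if self.p_adjust == "bh":
                adj = bh_fdr(pi[ok])
            else:
                adj = np.minimum(pi[ok] * ok.sum(), 1.0)
            W[i] = int((adj < self.alpha).sum())
        threshold = self.cutoff * (m - 1)
        rows = []
        for t in taxa:
            if any_structural[t]:
                rows.append((t, np.nan, np.nan, bool(one_sided[t]), True))
            else:
                i = pool.index(t)
                rows.append((t, float(W[i]), W[i] / (m - 1),
                             W[i] >= threshold, False))
        frame = pd.DataFrame(
            rows, columns=["taxon", "W", "W_frac", "detected", "structural_zero_call"]
        ).set_index("taxon")
        return AncomIIResults(frame, m, self.alpha, self.cutoff, zc)
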