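"""Regression and meta-analysis layer.

Per-feature association fits used throughout the pipeline:

* binary logistic regression (odds ratios for prevalent disease),
* ordinary least squares (metabolome-wide association, grade trends),
* modified Poisson regression — a Poisson GLM with log link applied to a
  binary outcome with robust (HC0 sandwich) standard errors, whose
  exponentiated coefficient estimates the relative risk for common
  outcomes,
* DerSimonian-Laird random-effects pooling with a concordance retention
  rule (pooled p < 0.05 and same direction in both analysis sets),
* Benjamini-Hochberg FDR adjustment,
* covariate-adjusted partial correlation.

Exposures are analysed per 1 SD (metabolites) or per CLR unit (species);
standardisation uses the analysis set in use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .tables import CATEGORICAL_COVARIATES


# ---------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------

def build_design(covariates: pd.DataFrame | None, index=None) -> pd.DataFrame:
    """Design matrix with an intercept; categorical covariates become
    drop-first dummy columns."""
    if covariates is None or covariates.shape[1] == 0:
        if index is None:
            raise ValueError("need an index when no covariates are given")
        return pd.DataFrame({"const": np.ones(len(index))}, index=index)
    cat_cols = [c for c in covariates.columns
                if c in CATEGORICAL_COVARIATES
                or covariates[c].dtype == object
                or isinstance(covariates[c].dtype, pd.CategoricalDtype)]
    enc = pd.get_dummies(covariates, columns=cat_cols, drop_first=True, dtype=float)
    enc = enc.astype(float)
    enc.insert(0, "const", 1.0)
    return enc


def standardize(x: np.ndarray) -> np.ndarray:
    """Scale to unit SD (ddof=1) without centering away interpretability."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant exposure cannot be standardized")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------

@dataclass
class AssociationResult:
    """One feature-exposure association."""

    feature_id: str
    exposure_id: str
    beta: float
    se: float
    p: float
    n: int
    effect_measure: str  # "OR", "RR" or "linear"
    model_id: int | None = None
    q: float | None = None
    converged: bool = True

    @property
    def effect(self) -> float:
        return float(np.exp(self.beta)) if self.effect_measure in ("OR", "RR") else self.beta

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = self.beta - 1.96 * self.se, self.beta + 1.96 * self.se
        if self.effect_measure in ("OR", "RR"):
            return float(np.exp(lo)), float(np.exp(hi))
        return float(lo), float(hi)

    @property
    def z(self) -> float:
        return self.beta / self.se

    def to_dict(self) -> dict:
        d = {
            "feature_id": self.feature_id, "exposure_id": self.exposure_id,
            "beta": self.beta, "se": self.se, "p": self.p, "q": self.q,
            "n": self.n, "effect_measure": self.effect_measure,
            "effect": self.effect, "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1], "model_id": self.model_id,
            "converged": self.converged,
        }
        return d


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


@dataclass
class MetaResult:
    """DerSimonian-Laird pooled estimate with the concordance rule."""

    feature_id: str
    beta: float
    se: float
    tau2: float
    p: float
    directions: tuple[float, ...]
    concordant: bool
    retained: bool

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id, "beta": self.beta, "se": self.se,
            "tau2": self.tau2, "p": self.p, "concordant": self.concordant,
            "retained": self.retained,
        }


# ---------------------------------------------------------------------
# single-feature fits
# ---------------------------------------------------------------------

def _check_binary(outcome: np.ndarray) -> np.ndarray:
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y[~np.isnan(y)])
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("outcome must be coded 0/1")
    if classes.size < 2:
        raise ValueError("outcome must contain both classes")
    return y


def fit_logistic(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
    *,
    feature_id: str = "exposure",
    exposure_id: str = "outcome",
    model_id: int | None = None,
) -> AssociationResult:
    """Binary logistic regression; the exposure coefficient is a log OR."""
    y = _check_binary(outcome)
    x = np.asarray(exposure, dtype=float)
    idx = covariates.index if covariates is not None else pd.RangeIndex(len(y))
    X = build_design(covariates, index=idx)
    X = X.assign(_exposure=x)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return AssociationResult(feature_id, exposure_id, np.nan, np.nan,
                                     np.nan, len(y), "OR", model_id,
                                     converged=False)
    beta = float(fit.params[-1])
    se = float(fit.bse[-1])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        converged = False
    p = float(2 * stats.norm.sf(abs(beta / se))) if converged else np.nan
    return AssociationResult(feature_id, exposure_id, beta, se, p, len(y),
                             "OR", model_id, converged=converged)


def fit_linear(
    response,
    exposure,
    covariates: pd.DataFrame | None = None,
    *,
    feature_id: str = "response",
    exposure_id: str = "exposure",
    model_id: int | None = None,
) -> AssociationResult:
    """OLS of a continuous response on exposure + covariates."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(exposure, dtype=float)
    idx = covariates.index if covariates is not None else pd.RangeIndex(len(y))
    X = build_design(covariates, index=idx).assign(_exposure=x)
    Xm = X.to_numpy()
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, Xm).fit()
    return AssociationResult(feature_id, exposure_id, float(fit.params[-1]),
                             float(fit.bse[-1]), float(fit.pvalues[-1]),
                             len(y), "linear", model_id)


fit_linear_mwaa = fit_linear  # metabolite (INT) on species CLR + covariates


def modified_poisson(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
    *,
    feature_id: str = "exposure",
    exposure_id: str = "incident",
    model_id: int | None = None,
    cov_type: str = "HC0",
) -> AssociationResult:
    """Poisson GLM with log link on a binary outcome, sandwich SEs.

    The exponentiated exposure coefficient estimates the relative risk;
    HC0 is the original sandwich flavour (HC1 available via ``cov_type``).
    """
    y = _check_binary(outcome)
    if y.sum() == 0:
        raise ValueError("no events in outcome")
    x = np.asarray(exposure, dtype=float)
    idx = covariates.index if covariates is not None else pd.RangeIndex(len(y))
    X = build_design(covariates, index=idx).assign(_exposure=x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson()).fit(
            cov_type=cov_type, maxiter=200)
    converged = bool(getattr(fit, "converged", True))
    beta, se = float(fit.params[-1]), float(fit.bse[-1])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return AssociationResult(feature_id, exposure_id, beta, se, p, len(y),
                             "RR", model_id, converged=converged)


# ---------------------------------------------------------------------
# bulk linear associations (exact OLS via Frisch-Waugh-Lovell)
# ---------------------------------------------------------------------

def _residualize(M: np.ndarray, D: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ coef


def pairwise_linear_assoc(
    exposures: pd.DataFrame,
    responses: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Every (exposure, response) OLS fit ``response ~ exposure + covariates``.

    Exact OLS computed jointly by residualising both blocks on the
    covariate design.  Returns a long-format frame with columns
    exposure_id, feature_id, beta, se, p, n.
    """
    D = build_design(covariates, index=exposures.index).to_numpy()
    n, p = D.shape
    U = _residualize(exposures.to_numpy(dtype=float), D)
    V = _residualize(responses.to_numpy(dtype=float), D)
    uu = (U * U).sum(axis=0)
    if (uu == 0).any():
        raise ValueError("exposure perfectly explained by covariates")
    vv = (V * V).sum(axis=0)
    S = U.T @ V  # a x b
    beta = S / uu[:, None]
    rss = np.maximum(vv[None, :] - S**2 / uu[:, None], 0.0)
    df = n - p - 1
    sigma2 = rss / df
    se = np.sqrt(sigma2 / uu[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df)
    rows = []
    for i, eid in enumerate(exposures.columns):
        for j, fid in enumerate(responses.columns):
            rows.append((eid, fid, beta[i, j], se[i, j], pvals[i, j], n))
    return pd.DataFrame(rows, columns=["exposure_id", "feature_id",
                                       "beta", "se", "p", "n"])


# ---------------------------------------------------------------------
# meta-analysis, FDR, trend, partial correlation
# ---------------------------------------------------------------------

def random_effects_meta(
    estimates: list[tuple[float, float]],
    *,
    feature_id: str = "feature",
    retain_p: float = 0.05,
) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed
    weights w = 1/SE^2; pooled beta uses weights 1/(SE^2 + tau^2).
    ``retained`` requires pooled p < ``retain_p`` and sign agreement of
    every set-level estimate.
    """
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if len(betas) < 2:
        raise ValueError("need at least two estimates to pool")
    if (ses <= 0).any() or not np.isfinite(ses).all():
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / ses**2
    fixed = np.sum(w * betas) / np.sum(w)
    Q = float(np.sum(w * (betas - fixed) ** 2))
    k = len(betas)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    ws = 1.0 / (ses**2 + tau2)
    pooled = float(np.sum(ws * betas) / np.sum(ws))
    pooled_se = float(np.sqrt(1.0 / np.sum(ws)))
    p = float(2 * stats.norm.sf(abs(pooled / pooled_se)))
    signs = np.sign(betas)
    concordant = bool(np.all(signs == signs[0]) and signs[0] != 0)
    return MetaResult(feature_id, pooled, pooled_se, float(tau2), p,
                      tuple(betas), concordant,
                      retained=bool(p < retain_p and concordant))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def grade_trend(
    species_clr,
    grade,
    covariates: pd.DataFrame | None = None,
    *,
    feature_id: str = "species",
) -> AssociationResult:
    """Linear trend of CLR abundance across ordinal disease grades 0-3."""
    g = np.asarray(grade, dtype=float)
    if np.unique(g).size < 2:
        raise ValueError("grade is constant")
    return fit_linear(species_clr, g, covariates,
                      feature_id=feature_id, exposure_id="lvdd_grade")


def partial_correlation(
    x, y, covariates: pd.DataFrame | None = None
) -> tuple[float, float]:
    """Pearson correlation of covariate-residualised x and y.

    p-value from the t distribution with n - k - 2 degrees of freedom,
    k = number of (encoded) covariate columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    idx = covariates.index if covariates is not None else pd.RangeIndex(n)
    D = build_design(covariates, index=idx).to_numpy()
    k = D.shape[1] - 1
    if n <= k + 3:
        raise ValueError("too few samples for partial correlation")
    rx = _residualize(x[:, None], D).ravel()
    ry = _residualize(y[:, None], D).ravel()
    if rx.std() <= 1e-10 * max(1.0, np.abs(x).max()) \
            or ry.std() <= 1e-10 * max(1.0, np.abs(y).max()):
        raise ValueError("zero residual variance")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - k - 2
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p
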