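"""Incident-risk prediction: nested-CV elastic net, SHAP, AUC, DeLong.

The elastic-net logistic model is tuned by nested cross-validation: the
inner loop picks the penalty strength and l1 mixing ratio on each outer
training set, outer folds supply honest out-of-sample predicted
probabilities, and the reported feature set comes from a refit on all
data at the consensus hyper-parameters.  SHAP attributions for the
(linear) model are exact: phi_ij = coef_j * (x_ij - mean_j).  The AUC is
the Mann-Whitney concordance with tie correction, its CI a percentile
bootstrap, and correlated AUCs are compared with the DeLong test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler


# ---------------------------------------------------------------------
# AUC machinery
# ---------------------------------------------------------------------

def auc_mann_whitney(predictions, outcome) -> float:
    """AUC via the rank (Mann-Whitney) identity with tie correction."""
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(predictions, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc_ci(
    predictions, outcome, n_boot: int = 10_000, seed: int | np.random.Generator = 0
) -> tuple[float, tuple[float, float]]:
    """AUC with a percentile bootstrap 95% CI over resampled pairs."""
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(predictions, dtype=float)
    auc = auc_mann_whitney(s, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = y.size
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.sum() in (0, n):  # degenerate resample: redraw
            aucs[b] = np.nan
            continue
        aucs[b] = auc_mann_whitney(s[idx], yb)
    lo, hi = np.nanpercentile(aucs, [2.5, 97.5])
    return auc, (float(lo), float(hi))


def _delong_components(s: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    pos = s[y == 1]
    neg = s[y == 0]
    # placement values (midrank handling of ties)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / pos.size for q in neg])
    return float(v10.mean()), v10, v01


def delong_test(pred_a, pred_b, outcome) -> tuple[float, float]:
    """DeLong test for two correlated ROC curves on the same samples.

    Returns (delta_auc, two-sided p).  Identical prediction vectors give
    p = 1.
    """
    y = np.asarray(outcome, dtype=float)
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if a.size != b.size or a.size != y.size:
        raise ValueError("prediction vectors and labels must share length")
    auc_a, v10a, v01a = _delong_components(a, y)
    auc_b, v10b, v01b = _delong_components(b, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    delta = auc_a - auc_b
    if var <= 0:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return float(delta), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------
# SHAP for linear models
# ---------------------------------------------------------------------

def shap_linear(
    coefficients, X, feature_means=None
) -> np.ndarray:
    """Exact Shapley attributions for an additive (linear) model.

    phi_ij = coef_j * (x_ij - mean_j); rows sum to the linear predictor
    minus its mean (the efficiency property).
    """
    coef = np.asarray(coefficients, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.shape[1] != coef.size:
        raise ValueError("feature/model dimension mismatch")
    means = (np.asarray(feature_means, dtype=float)
             if feature_means is not None else X.mean(axis=0))
    return coef[None, :] * (X - means[None, :])


# ---------------------------------------------------------------------
# nested-CV elastic net
# ---------------------------------------------------------------------

@dataclass
class PredictionResults:
    """Fitted nested-CV elastic-net model with honest performance."""

    feature_names: list[str]
    selected_features: list[str]
    coefficients: pd.Series          # on the standardized feature scale
    shap: pd.DataFrame               # samples x selected features
    auc: float                       # cross-validated (out-of-fold) AUC
    auc_ci95: tuple[float, float]
    in_sample_auc: float
    oof_predictions: np.ndarray
    outcome: np.ndarray
    cv_spec: dict
    hyperparams: dict
    delta_auc_p: float | None = None

    def shap_importance(self) -> pd.Series:
        """Mean |phi| per selected feature, descending."""
        return self.shap.abs().mean(axis=0).sort_values(ascending=False)

    def summary(self) -> str:
        lines = [
            "Nested-CV elastic-net incident-risk model",
            f"  CV: {self.cv_spec['outer']} outer x {self.cv_spec['inner']} inner folds"
            f" (repeats={self.cv_spec['repeats']}, seed={self.cv_spec['seed']})",
            f"  consensus hyperparameters: C={self.hyperparams['C']:.4g}, "
            f"l1_ratio={self.hyperparams['l1_ratio']:.2f}",
            f"  cross-validated AUC: {self.auc:.3f} "
            f"(95% CI {self.auc_ci95[0]:.3f}, {self.auc_ci95[1]:.3f})",
            f"  selected features ({len(self.selected_features)}):",
        ]
        imp = self.shap_importance()
        for name in imp.index:
            lines.append(f"    {name}: coef={self.coefficients[name]:+.3f}, "
                         f"mean|SHAP|={imp[name]:.4f}")
        return "\n".join(lines)


class NestedElasticNet:
    """Elastic-net logistic risk model with nested cross-validation.

    Parameters
    ----------
    X : DataFrame
        Candidate predictors (standardized internally).
    y : array-like of 0/1
        Incident outcome.
    outer, inner : int
        Fold counts (default 10 x 10).
    repeats : int
        Repeats of the outer split (alternative reading of "10 x 10").
    l1_grid, C_grid : sequences
        Inner-loop search grids for the mixing ratio and inverse penalty.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        *,
        outer: int = 10,
        inner: int = 10,
        repeats: int = 1,
        l1_grid: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
        C_grid: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
        n_boot: int = 2000,
        seed: int = 0,
    ) -> None:
        self.X = X.astype(float)
        self.y = np.asarray(y, dtype=float)
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("outcome must be 0/1")
        if self.X.to_numpy().std(axis=0).max() == 0:
            raise ValueError("all-constant feature matrix")
        self.outer = outer
        self.inner = inner
        self.repeats = repeats
        self.l1_grid = tuple(l1_grid)
        self.C_grid = tuple(C_grid)
        self.n_boot = n_boot
        self.seed = seed

    def _make_lr(self, C: float, l1: float) -> LogisticRegression:
        # a float l1_ratio selects the elastic-net penalty
        return LogisticRegression(
            solver="saga", C=C, l1_ratio=l1,
            max_iter=5000, tol=1e-4, random_state=0)

    def _inner_select(self, Xtr: np.ndarray, ytr: np.ndarray, seed: int) -> tuple[float, float]:
        cv = StratifiedKFold(self.inner, shuffle=True, random_state=seed)
        best, best_score = (self.C_grid[0], self.l1_grid[0]), -np.inf
        folds = list(cv.split(Xtr, ytr))
        for C in self.C_grid:
            for l1 in self.l1_grid:
                aucs = []
                for tr, te in folds:
                    if ytr[te].sum() in (0, len(te)):
                        continue
                    model = self._make_lr(C, l1).fit(Xtr[tr], ytr[tr])
                    aucs.append(auc_mann_whitney(
                        model.decision_function(Xtr[te]), ytr[te]))
                score = float(np.mean(aucs)) if aucs else -np.inf
                if score > best_score:
                    best_score, best = score, (C, l1)
        return best

    def fit(self) -> PredictionResults:
        Xv = self.X.to_numpy()
        scaler = StandardScaler().fit(Xv)
        n = Xv.shape[0]
        oof = np.zeros(n)
        oof_count = np.zeros(n)
        chosen: list[tuple[float, float]] = []
        for rep in range(self.repeats):
            outer_cv = StratifiedKFold(self.outer, shuffle=True,
                                       random_state=self.seed + rep)
            for k, (tr, te) in enumerate(outer_cv.split(Xv, self.y)):
                sc = StandardScaler().fit(Xv[tr])
                Xtr, Xte = sc.transform(Xv[tr]), sc.transform(Xv[te])
                C, l1 = self._inner_select(Xtr, self.y[tr],
                                           seed=self.seed * 1000 + rep * 100 + k)
                chosen.append((C, l1))
                model = self._make_lr(C, l1).fit(Xtr, self.y[tr])
                oof[te] += model.predict_proba(Xte)[:, 1]
                oof_count[te] += 1
        oof /= np.maximum(oof_count, 1)
        # consensus hyperparameters: most frequent pair, ties -> stronger penalty
        pairs, counts = np.unique(np.array(chosen), axis=0, return_counts=True)
        order = np.lexsort((pairs[:, 1], pairs[:, 0], -counts))
        C_star, l1_star = map(float, pairs[order[0]])
        Xs = scaler.transform(Xv)
        final = self._make_lr(C_star, l1_star).fit(Xs, self.y)
        coefs = pd.Series(final.coef_.ravel(), index=self.X.columns)
        selected = list(coefs.index[coefs != 0])
        phi = shap_linear(coefs[selected].to_numpy(), Xs[:, [self.X.columns.get_loc(c) for c in selected]]) \
            if selected else np.zeros((n, 0))
        shap = pd.DataFrame(phi, index=self.X.index, columns=selected)
        rng = np.random.default_rng(self.seed)
        auc, ci = roc_auc_ci(oof, self.y, n_boot=self.n_boot, seed=rng)
        in_sample = auc_mann_whitney(final.predict_proba(Xs)[:, 1], self.y)
        return PredictionResults(
            feature_names=list(self.X.columns),
            selected_features=selected,
            coefficients=coefs,
            shap=shap,
            auc=auc,
            auc_ci95=ci,
            in_sample_auc=float(in_sample),
            oof_predictions=oof,
            outcome=self.y,
            cv_spec={"outer": self.outer, "inner": self.inner,
                     "repeats": self.repeats, "seed": self.seed},
            hyperparams={"C": C_star, "l1_ratio": l1_star},
        )


def compare_auc(pred_a, pred_b, outcome) -> float:
    """Two-sided DeLong p-value for the AUC difference of two correlated
    prediction vectors on the same samples."""
    return delong_test(pred_a, pred_b, outcome)[1]
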