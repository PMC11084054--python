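"""Feature filters and transforms.

Four steps sit between raw tables and the association layer:

* prevalence filtering of taxa (keep species nonzero in strictly more
  than a fraction of samples, default 20%);
* detection filtering of metabolites (keep metabolites observed in
  strictly more than 75% of samples) with below-detection values carried
  as NaN;
* the centered log-ratio (CLR) transform for compositional taxa,
  ``clr(x)_k = log(x_k + c) - mean_k log(x_k + c)``;
* half-minimum imputation of below-detection metabolite levels followed
  by a rank-based inverse normal transform (INT) with the Blom offset
  ``Phi^{-1}((r - 3/8) / (n + 1/4))`` and average ranks for ties.

KO gene families get a two-condition filter: a sample counts toward
prevalence only where the KO's relative abundance reaches a floor
(default 0.001%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable, TableKind


@dataclass
class TransformReport:
    """What a filter or transform did, feature by feature."""

    rule: str
    features_in: int
    features_out: int
    passed: pd.Series  # feature id -> bool
    pseudocount: float | None = None
    imputation_values: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.features_out > self.features_in:
            raise ValueError("features_out exceeds features_in")
        if int(self.passed.sum()) != self.features_out:
            raise ValueError("pass flags inconsistent with feature counts")


def _check_threshold(threshold: float) -> None:
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")


def filter_by_prevalence(
    table: FeatureTable, threshold: float = 0.20
) -> tuple[FeatureTable, TransformReport]:
    """Keep features nonzero in strictly more than ``threshold * n`` samples."""
    _check_threshold(threshold)
    if table.kind not in (TableKind.counts, TableKind.relabund, TableKind.ko_relabund):
        raise ValueError(f"prevalence filter expects abundances, got {table.kind.value}")
    vals = table.values
    n = vals.shape[0]
    nonzero = np.nansum(vals > 0, axis=0)
    passed = pd.Series(nonzero > threshold * n, index=table.data.columns)
    out = table.data.loc[:, passed.to_numpy()]
    rep = TransformReport(
        rule=f"prevalence > {threshold:g}",
        features_in=vals.shape[1],
        features_out=out.shape[1],
        passed=passed,
    )
    if table.kind is TableKind.relabund and out.shape[1]:
        # re-close the composition over the retained features
        out = out.div(out.sum(axis=1), axis=0)
    return FeatureTable(out, table.kind, table.feature_meta), rep


def filter_by_detection(
    table: FeatureTable, threshold: float = 0.75
) -> tuple[FeatureTable, TransformReport]:
    """Keep metabolites detected (non-missing) in strictly more than
    ``threshold * n`` samples."""
    _check_threshold(threshold)
    vals = table.values
    n = vals.shape[0]
    detected = (~np.isnan(vals)).sum(axis=0)
    passed = pd.Series(detected > threshold * n, index=table.data.columns)
    out = table.data.loc[:, passed.to_numpy()]
    rep = TransformReport(
        rule=f"detection > {threshold:g}",
        features_in=vals.shape[1],
        features_out=out.shape[1],
        passed=passed,
    )
    return FeatureTable(out, table.kind, table.feature_meta), rep


def filter_kos(
    table: FeatureTable, prev_threshold: float = 0.20, relabund_floor: float = 1e-5
) -> tuple[FeatureTable, TransformReport]:
    """Two-condition KO filter.

    A sample counts toward a KO's prevalence only where the KO's relative
    abundance is at least ``relabund_floor``; the KO passes when such
    samples number strictly more than ``prev_threshold * n``.
    """
    _check_threshold(prev_threshold)
    if relabund_floor <= 0:
        raise ValueError("relabund_floor must be positive")
    if table.kind is not TableKind.ko_relabund:
        raise ValueError("filter_kos expects a ko_relabund table")
    vals = table.values
    n = vals.shape[0]
    qualifying = np.nansum(vals >= relabund_floor, axis=0)
    passed = pd.Series(qualifying > prev_threshold * n, index=table.data.columns)
    out = table.data.loc[:, passed.to_numpy()]
    rep = TransformReport(
        rule=f"prevalence > {prev_threshold:g} at relabund >= {relabund_floor:g}",
        features_in=vals.shape[1],
        features_out=out.shape[1],
        passed=passed,
    )
    return FeatureTable(out, table.kind, table.feature_meta), rep


def clr_transform(table: FeatureTable, pseudocount: float = 0.5) -> FeatureTable:
    """Centered log-ratio transform over the table's retained features.

    Per sample, ``log(x + c)`` minus the sample mean of those logs, so each
    CLR row sums to zero.  ``pseudocount`` must be positive whenever zeros
    are present; with no zeros it may be 0, in which case the transform is
    scale-invariant within each sample.
    """
    if table.kind not in (TableKind.counts, TableKind.relabund):
        raise ValueError(f"CLR expects counts or relabund, got {table.kind.value}")
    vals = table.values
    if np.isnan(vals).any():
        raise ValueError("CLR input must not contain missing values")
    if (vals.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample: CLR undefined")
    if pseudocount < 0 or (pseudocount == 0 and (vals == 0).any()):
        raise ValueError("positive pseudocount required when zeros are present")
    logs = np.log(vals + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, index=table.data.index, columns=table.data.columns)
    return FeatureTable(out, TableKind.clr, table.feature_meta)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Half-minimum imputation plus Blom-offset inverse normal transform.

    ``values`` is one metabolite across samples; NaN marks below-detection.
    Below-detection entries are replaced by half the minimum detected
    value, then average ranks are mapped through the standard normal
    quantile function with the Blom offset ``(r - 3/8) / (n + 1/4)``.
    """
    x = np.asarray(values, dtype=float).copy()
    detected = ~np.isnan(x)
    if detected.sum() < 3:
        raise ValueError("need at least 3 observed values")
    if not detected.all():
        x[~detected] = x[detected].min() / 2.0
    ranks = stats.rankdata(x, method="average")
    n = x.size
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))


def int_transform(table: FeatureTable) -> tuple[FeatureTable, TransformReport]:
    """Apply :func:`inverse_normal_transform` to every metabolite column."""
    vals = table.values
    out = np.empty_like(vals)
    imput = {}
    for j, fid in enumerate(table.data.columns):
        col = vals[:, j]
        detected = ~np.isnan(col)
        if not detected.any():
            raise ValueError(f"metabolite {fid!r}: all values below detection")
        imput[fid] = float(np.nanmin(col) / 2.0) if (~detected).any() else np.nan
        out[:, j] = inverse_normal_transform(col)
    frame = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    rep = TransformReport(
        rule="half-minimum imputation + Blom INT (average ranks)",
        features_in=vals.shape[1],
        features_out=vals.shape[1],
        passed=pd.Series(True, index=table.data.columns),
        imputation_values=pd.Series(imput),
    )
    return FeatureTable(frame, TableKind.int_transformed, table.feature_meta), rep
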