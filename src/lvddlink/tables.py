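"""Feature tables, sample metadata, and multi-omics sample alignment.

A :class:`FeatureTable` is a dense samples-by-features matrix with typed
contents (``kind``): raw taxon counts, relative abundances, metabolite
intensities, CLR-transformed abundances, inverse-normal-transformed
intensities, or KO relative abundances.  Samples are always rows
internally; readers transpose when told the file is feature-major.

Missing metabolite intensities (below the detection limit) are stored as
NaN — never as zero — so that below-detection handling stays an explicit
preprocessing step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class TableKind(str, enum.Enum):
    counts = "counts"
    relabund = "relabund"
    intensity = "intensity"
    clr = "clr"
    int_transformed = "int_transformed"
    ko_relabund = "ko_relabund"


#: kinds whose observed values must be nonnegative
_NONNEGATIVE_KINDS = {
    TableKind.counts,
    TableKind.relabund,
    TableKind.intensity,
    TableKind.ko_relabund,
}


@dataclass
class FeatureTable:
    """Samples x features numeric matrix with identifiers and a kind tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are features.
    kind : TableKind or str
        What the values mean; drives validation.
    feature_meta : mapping, optional
        feature id -> annotation (taxonomy string, metabolite
        super-pathway, KO pathway).
    """

    data: pd.DataFrame
    kind: TableKind
    feature_meta: Mapping[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.kind = TableKind(self.kind)
        self.data = self.data.astype(float)
        self._validate()

    # -- validation -------------------------------------------------
    def _validate(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        vals = self.data.to_numpy()
        if self.kind in _NONNEGATIVE_KINDS:
            observed = vals[~np.isnan(vals)]
            if observed.size and (observed < 0).any():
                raise ValueError(
                    f"negative values are invalid for kind={self.kind.value}"
                )
        if self.kind is TableKind.relabund and len(cols):
            sums = np.nansum(vals, axis=1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("relative-abundance rows must sum to 1 +- 1e-8")

    # -- convenience ------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def with_data(self, data: pd.DataFrame, kind: TableKind | str | None = None) -> "FeatureTable":
        return FeatureTable(data, kind or self.kind, self.feature_meta)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return self.with_data(self.data.loc[list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        return self.with_data(self.data.loc[:, list(feature_ids)])


def read_feature_table(
    path,
    kind: TableKind | str,
    orientation: str = "samples",
) -> FeatureTable:
    """Read a feature table from TSV or BIOM v2.1.

    TSV layout: header row of feature ids, first column of sample ids
    (``orientation='samples'``, the package convention) or the transpose
    (``orientation='features'``).  ``orientation='auto'`` is accepted only
    when the file declares it unambiguously via an index name of
    ``sample_id``/``feature_id``; anything else raises.
    """
    path = str(path)
    if path.endswith(".biom"):
        return _read_biom(path, kind)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate identifiers in {path}")
    bad = df.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna() & df.notna()
    if bad.to_numpy().any():
        raise ValueError(f"non-numeric cells in {path}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if orientation == "auto":
        name = (df.index.name or "").lower()
        if name in {"sample_id", "sample", "#sampleid"}:
            orientation = "samples"
        elif name in {"feature_id", "feature", "#otu id", "taxon"}:
            orientation = "features"
        else:
            raise ValueError(
                "orientation='auto' needs an index name of sample_id or "
                "feature_id; declare orientation explicitly"
            )
    if orientation == "features":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    return FeatureTable(df, kind)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as TSV (samples in rows) or BIOM v2.1."""
    path = str(path)
    if path.endswith(".biom"):
        _write_biom(table, path)
        return
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def _read_biom(path: str, kind) -> FeatureTable:
    try:
        import biom
    except ImportError as exc:  # pragma: no cover
        raise ImportError("BIOM support needs the biom-format package") from exc
    bt = biom.load_table(path)
    df = bt.to_dataframe(dense=True).T  # biom stores features x samples
    return FeatureTable(df, kind)


def _write_biom(table: FeatureTable, path: str) -> None:
    try:
        import biom
        import h5py
    except ImportError as exc:  # pragma: no cover
        raise ImportError("BIOM support needs the biom-format package") from exc
    bt = biom.Table(
        table.data.to_numpy().T,
        observation_ids=table.feature_ids,
        sample_ids=table.sample_ids,
    )
    with h5py.File(path, "w") as fh:
        bt.to_hdf5(fh, generated_by="lvddlink")


# ---------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------

#: covariate sets for the three adjustment models; Model2 extends Model1
#: with adiposity/blood-pressure, Model3 adds medication use.
MODEL1_COVARIATES = [
    "age", "sex", "center", "education", "income", "smoking",
    "alcohol", "physical_activity", "ahei2010", "abx_probiotic_use",
]
MODEL2_COVARIATES = MODEL1_COVARIATES + ["bmi", "sbp"]
MODEL3_COVARIATES = MODEL2_COVARIATES + [
    "med_antidiabetic", "med_antihypertensive", "med_lipidlowering",
]
MODEL_COVARIATES = {1: MODEL1_COVARIATES, 2: MODEL2_COVARIATES, 3: MODEL3_COVARIATES}

#: covariates used by the differential-abundance discovery stage
DISCOVERY_COVARIATES = ["age", "sex", "center", "abx_probiotic_use"]

#: columns treated as unordered categories when building design matrices
CATEGORICAL_COVARIATES = {"center", "education", "income", "smoking", "alcohol"}

#: traditional cardiovascular risk factors for the prediction reference model
TRADITIONAL_RISK_FACTORS = [
    "age", "bmi", "sbp", "smoking", "alcohol", "ldl_c", "diabetes",
]


@dataclass
class SampleMetadata:
    """Per-sample covariates, outcome labels, and analysis-set membership.

    ``frame`` is indexed by sample id.  Membership is carried by an
    ``analysis_set`` column (discovery / validation) plus boolean flags
    (``has_metabolome``, ``in_baseline_v1``, ``has_followup``) because the
    study's analysis sets overlap.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        if {"prevalent_lvdd", "lvdd_grade"} <= set(f.columns):
            grade_pos = f["lvdd_grade"].to_numpy() > 0
            prev = f["prevalent_lvdd"].to_numpy().astype(bool)
            if not np.array_equal(grade_pos, prev):
                raise ValueError("lvdd_grade > 0 must coincide with prevalent_lvdd = 1")
        if {"prevalent_lvdd", "incident_lvdd"} <= set(f.columns):
            bad = f["incident_lvdd"].notna() & (f["prevalent_lvdd"] == 1)
            if bad.any():
                raise ValueError("incident_lvdd defined for prevalent cases")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)])

    def covariates(self, model_id: int = 1) -> pd.DataFrame:
        cols = MODEL_COVARIATES[model_id]
        sub = self.frame[cols]
        if sub.isna().to_numpy().any():
            raise ValueError(f"missing covariates for Model{model_id}")
        return sub

    def set_mask(self, name: str) -> pd.Series:
        """Boolean membership for an analysis set name."""
        f = self.frame
        if name in ("discovery", "validation"):
            return f["analysis_set"] == name
        if name == "concurrent":
            return f["has_metabolome"].astype(bool)
        if name == "baseline_v1":
            return f["in_baseline_v1"].astype(bool)
        if name == "incident":
            return (f["prevalent_lvdd"] == 0) & f.get(
                "has_followup", pd.Series(True, index=f.index)
            ).astype(bool)
        if name == "all":
            return pd.Series(True, index=f.index)
        raise KeyError(name)

    @classmethod
    def read(cls, path) -> "SampleMetadata":
        sep = "," if str(path).endswith(".csv") else "\t"
        return cls(pd.read_csv(path, sep=sep, index_col=0))

    def write(self, path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        out = self.frame.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep=sep)


@dataclass
class AlignedBundle:
    """Multi-omics layers restricted to their common samples."""

    tables: dict[str, FeatureTable]
    meta: SampleMetadata
    layer_counts: dict[str, int]

    @property
    def sample_ids(self) -> list[str]:
        return self.meta.sample_ids


def align_samples(
    tables: Mapping[str, FeatureTable] | Sequence[FeatureTable],
    meta: SampleMetadata,
) -> AlignedBundle:
    """Restrict all layers and the metadata to their shared samples.

    The metadata's original sample order is preserved.  Raises on an
    empty intersection.  Idempotent: aligning an aligned bundle's pieces
    returns identical contents.
    """
    if not isinstance(tables, Mapping):
        tables = {f"layer{i}": t for i, t in enumerate(tables)}
    if not tables:
        raise ValueError("need at least one feature table")
    layer_counts = {name: t.shape[0] for name, t in tables.items()}
    layer_counts["metadata"] = len(meta.frame)
    common = set(meta.sample_ids)
    for t in tables.values():
        common &= set(t.sample_ids)
    if not common:
        raise ValueError("empty sample intersection across layers")
    keep = [s for s in meta.sample_ids if s in common]
    aligned = {name: t.subset_samples(keep) for name, t in tables.items()}
    return AlignedBundle(aligned, meta.subset(keep), layer_counts)
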