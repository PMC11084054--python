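"""Metabolite-proxy association between species and incident disease.

Per-metabolite association estimates are standardised into Z-scores
(beta / SE) on both sides — metabolite ~ species and incident outcome ~
metabolite — and the two Z vectors are Spearman-correlated over the
metabolites significantly associated with the incident outcome.  A
correlation p-value < 0.05 marks a significant proxy association.

The Spearman p-value is exact (full permutation enumeration) for k <= 9
metabolites and uses the t approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import AssociationResult


def to_zscores(results: list[AssociationResult]) -> pd.Series:
    """Z = beta / SE, indexed by feature id, order-preserving."""
    ids, zs = [], []
    for r in results:
        if not np.isfinite(r.beta) or not np.isfinite(r.se):
            raise ValueError(f"non-finite estimate for {r.feature_id!r}")
        if r.se <= 0:
            raise ValueError(f"SE must be positive for {r.feature_id!r}")
        ids.append(r.feature_id)
        zs.append(r.beta / r.se)
    return pd.Series(zs, index=ids, dtype=float)


@dataclass
class ProxyResult:
    """Spearman correlation between the two Z-score vectors."""

    species_id: str
    R: float
    p: float
    k: int
    metabolite_ids: list[str]
    method: str

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)

    def to_dict(self) -> dict:
        return {"species_id": self.species_id, "R": self.R, "p": self.p,
                "k": self.k, "method": self.method,
                "significant": self.significant}


def _spearman_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for Spearman's rho (k <= 9)."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    k = ra.size
    obs = np.corrcoef(ra, rb)[0, 1]
    perms = np.array(list(itertools.permutations(range(k))))
    rb_c = rb - rb.mean()
    ra_c = ra - ra.mean()
    num = (ra_c[perms] * rb_c[None, :]).sum(axis=1)
    denom = np.sqrt((ra_c**2).sum() * (rb_c**2).sum())
    rhos = num / denom
    p = float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))
    return float(obs), p


class ProxyAssociation:
    """Proxy-association model for one species.

    Parameters
    ----------
    z_species : Series
        Z-scores of metabolite ~ species associations, indexed by
        metabolite id.
    z_outcome : Series
        Z-scores of incident outcome ~ metabolite associations over the
        same metabolites.
    method : {"auto", "exact", "asymptotic"}
        "auto" enumerates all k! orderings when k <= 9.
    """

    def __init__(self, z_species: pd.Series, z_outcome: pd.Series,
                 *, species_id: str = "species", method: str = "auto") -> None:
        if list(z_species.index) != list(z_outcome.index):
            raise ValueError("metabolite orderings differ between sides")
        if len(z_species) < 3:
            raise ValueError("need at least 3 metabolites")
        if z_species.nunique() == 1 or z_outcome.nunique() == 1:
            raise ValueError("constant Z vector")
        if method not in ("auto", "exact", "asymptotic"):
            raise ValueError(f"unknown method {method!r}")
        self.z_species = z_species
        self.z_outcome = z_outcome
        self.species_id = species_id
        self.method = method

    def fit(self) -> ProxyResult:
        a = self.z_species.to_numpy()
        b = self.z_outcome.to_numpy()
        k = a.size
        method = self.method
        if method == "auto":
            method = "exact" if k <= 9 else "asymptotic"
        if method == "exact":
            if k > 9:
                raise ValueError("exact enumeration limited to k <= 9")
            r, p = _spearman_exact_p(a, b)
        else:
            r, p = stats.spearmanr(a, b)
            r, p = float(r), float(p)
        return ProxyResult(self.species_id, r, p, int(k),
                           list(self.z_species.index), method)


def proxy_scatter_frame(
    z_species: pd.Series, z_outcome: pd.Series,
    super_pathways: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Plotting-data export: metabolite, z_species, z_outcome, super-pathway."""
    frame = pd.DataFrame({
        "metabolite": z_species.index,
        "z_species": z_species.to_numpy(),
        "z_outcome": z_outcome.to_numpy(),
    })
    frame["super_pathway"] = [
        (super_pathways or {}).get(m, "") for m in frame["metabolite"]
    ]
    return frame
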