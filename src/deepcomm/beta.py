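"""Between-site (beta) diversity: shared-taxon counts, the Sørensen
presence/absence index, the abundance-based Morisita overlap C_λ and its
dissimilarity complement 1 − C_λ, pairwise dissimilarity matrices, and
hierarchical clustering of sites.

Morisita's index is the comparison metric of choice here because, unlike
Sørensen, it is approximately insensitive to unequal sample sizes — relevant
when one habitat was sequenced two orders of magnitude deeper than the other.
It is computed on raw integer counts at whatever rank the caller aggregated
the table to (genus by default in this pipeline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._cluster import Dendrogram, agglomerate
from .tables_io import CommunityTable

__all__ = [
    "PresenceComparison",
    "MorisitaResult",
    "DistanceMatrix",
    "sorensen",
    "sorensen_from_counts",
    "morisita",
    "dissimilarity_matrix",
    "shared_taxa_matrix",
    "hierarchical_cluster",
]


@dataclass(frozen=True)
class PresenceComparison:
    """Presence/absence overlap between two samples."""

    a: int  # taxa present in sample 1
    b: int  # taxa present in sample 2
    c: int  # taxa present in both
    sorensen: float


@dataclass(frozen=True)
class MorisitaResult:
    lambda_1: float
    lambda_2: float
    cross_sum: float  # Σ_i n1i · n2i
    c_lambda: float
    dissimilarity: float


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over a site list."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(str(x) for x in self.ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        v = np.clip(v, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def condensed(self) -> np.ndarray:
        """Strictly-upper-triangle vectorisation (row-major pair order)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def reorder(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(str(i)) for i in ids]
        return DistanceMatrix(tuple(str(i) for i in ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(map(str, df.index)), df.to_numpy(dtype=float))


def _pair(v1, v2) -> tuple[np.ndarray, np.ndarray]:
    a1 = np.asarray(v1, dtype=float)
    a2 = np.asarray(v2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError("samples must be 1-D vectors over a common taxon list")
    if (a1 < 0).any() or (a2 < 0).any():
        raise ValueError("abundances must be nonnegative")
    return a1, a2


def sorensen(sample1, sample2) -> PresenceComparison:
    """Sørensen index 2c/(a+b) from two abundance vectors on a shared taxon list."""
    a1, a2 = _pair(sample1, sample2)
    a = int((a1 > 0).sum())
    b = int((a2 > 0).sum())
    c = int(((a1 > 0) & (a2 > 0)).sum())
    if a + b == 0:
        raise ValueError("Sørensen undefined: no taxa present in either sample")
    return PresenceComparison(a=a, b=b, c=c, sorensen=2.0 * c / (a + b))


def sorensen_from_counts(a: int, b: int, c: int) -> float:
    """Sørensen index directly from per-sample richness a, b and shared count c."""
    if c > min(a, b) or min(a, b, c) < 0:
        raise ValueError("need 0 <= c <= min(a, b)")
    if a + b == 0:
        raise ValueError("Sørensen undefined for two empty samples")
    return 2.0 * c / (a + b)


def _simpson_lambda(n: np.ndarray) -> float:
    total = n.sum()
    return float((n * (n - 1)).sum() / (total * (total - 1)))


def morisita(sample1, sample2) -> MorisitaResult:
    """Morisita overlap C_λ = 2 Σ n1i·n2i / ((λ1+λ2) N1 N2).

    λ_j = Σ n_ji(n_ji−1) / (N_j(N_j−1)) is the Simpson-type concentration of
    sample j.  The classical form can exceed 1 for small samples; the
    dissimilarity 1 − C_λ is clamped at 0 (with a warning) so it remains a
    valid input to hierarchical clustering.
    """
    a1, a2 = _pair(sample1, sample2)
    if not (np.allclose(a1, np.round(a1)) and np.allclose(a2, np.round(a2))):
        raise ValueError("Morisita is defined on integer counts")
    n1, n2 = np.round(a1), np.round(a2)
    N1, N2 = n1.sum(), n2.sum()
    if N1 < 2 or N2 < 2:
        raise ValueError("each sample needs at least two individuals")
    lam1, lam2 = _simpson_lambda(n1), _simpson_lambda(n2)
    cross = float((n1 * n2).sum())
    if lam1 + lam2 == 0:
        raise ValueError("Morisita undefined: both samples are all singletons")
    c_lambda = 2.0 * cross / ((lam1 + lam2) * N1 * N2)
    dissim = 1.0 - c_lambda
    if dissim < 0:
        warnings.warn(
            f"Morisita overlap {c_lambda:.4f} exceeds 1 (small-sample overshoot); "
            "dissimilarity clamped to 0",
            stacklevel=2,
        )
        dissim = 0.0
    return MorisitaResult(lambda_1=lam1, lambda_2=lam2, cross_sum=cross,
                          c_lambda=c_lambda, dissimilarity=dissim)


def dissimilarity_matrix(table: CommunityTable, metric: str = "morisita") -> DistanceMatrix:
    """Pairwise community dissimilarity over all site pairs.

    ``metric`` is ``morisita`` (1 − C_λ, clamped) or ``sorensen-complement``
    (1 − Sørensen).
    """
    sites = table.sites
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    counts = table.counts.to_numpy()
    n = len(sites)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "morisita":
                d = morisita(counts[i], counts[j]).dissimilarity
            elif metric == "sorensen-complement":
                d = 1.0 - sorensen(counts[i], counts[j]).sorensen
            else:
                raise ValueError(f"unknown metric {metric!r}")
            out[i, j] = out[j, i] = d
    return DistanceMatrix(tuple(sites), out)


def shared_taxa_matrix(table: CommunityTable) -> pd.DataFrame:
    """Integer matrix of taxa shared between site pairs.

    The diagonal holds each site's own observed-taxon count.
    """
    present = (table.counts.to_numpy() > 0).astype(np.int64)
    shared = present @ present.T
    return pd.DataFrame(shared, index=table.counts.index, columns=table.counts.index)


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative dendrogram of sites from a dissimilarity matrix.

    Average linkage (UPGMA) by default; export with
    :meth:`Dendrogram.to_newick`.
    """
    if len(dist.ids) < 2:
        raise ValueError("need at least two sites to cluster")
    return agglomerate(dist.values, labels=dist.ids, linkage=linkage)
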