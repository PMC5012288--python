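"""Bray-Curtis/UPGMA clustering of FAME profiles with bootstrap support.

Profiles are compared by Bray-Curtis dissimilarity, clustered by UPGMA
(average linkage; merge heights are the merge dissimilarity itself) and the
dendrogram's fidelity to the original distances is summarised by the
cophenetic correlation coefficient. Node support comes from resampling the
fatty-acid species columns with replacement and counting how often each
leaf bipartition recurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .fame import FameProfile

__all__ = [
    "DissimilarityMatrix",
    "Dendrogram",
    "bray_curtis",
    "dissimilarity_matrix",
    "upgma",
    "cophenetic_correlation",
    "cut_into_groups",
    "bootstrap_support",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric Bray-Curtis matrix over lexicographically sorted strain labels."""

    labels: tuple[str, ...]
    values: np.ndarray  # square form

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "values", v)

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree in scipy linkage form, plus optional node supports.

    ``linkage`` row k merges clusters Z[k,0] and Z[k,1] at height Z[k,2]
    (the merge dissimilarity, not halved). ``supports`` aligns with linkage
    rows and holds bootstrap percentages in [0, 100], or None.
    """

    labels: tuple[str, ...]
    linkage: np.ndarray
    supports: np.ndarray | None = None

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic_matrix(self) -> np.ndarray:
        """Condensed matrix of first-merge heights between leaf pairs."""
        return hierarchy.cophenet(self.linkage)

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf set under each internal merge node, in linkage-row order."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for k, (a, b, _, _) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            out.append(merged)
        return out


def bray_curtis(p: FameProfile, q: FameProfile) -> float:
    """Bray-Curtis dissimilarity sum|p_i - q_i| / sum(p_i + q_i) in [0, 1].

    Species absent from one profile contribute zero on that side.
    """
    keys = sorted(set(p.abundances) | set(q.abundances))
    pv = np.array([p.abundances.get(k, 0.0) for k in keys])
    qv = np.array([q.abundances.get(k, 0.0) for k in keys])
    denom = float((pv + qv).sum())
    if denom == 0:
        raise ValueError("both profiles are all-zero")
    return float(np.abs(pv - qv).sum() / denom)


def _abundance_matrix(profiles: list[FameProfile]) -> tuple[list[str], list[str], np.ndarray]:
    labels = sorted(p.strain_id for p in profiles)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strain ids")
    by_id = {p.strain_id: p for p in profiles}
    species = sorted({k for p in profiles for k in p.abundances})
    mat = np.array(
        [[by_id[lbl].abundances.get(sp, 0.0) for sp in species] for lbl in labels]
    )
    return labels, species, mat


def dissimilarity_matrix(profiles: list[FameProfile]) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis over a profile collection (labels sorted)."""
    labels, _, mat = _abundance_matrix(profiles)
    return DissimilarityMatrix(
        labels=tuple(labels), values=squareform(pdist(mat, metric="braycurtis"))
    )


def upgma(d: DissimilarityMatrix) -> Dendrogram:
    """UPGMA (unweighted average linkage) dendrogram of a dissimilarity matrix.

    At each step the closest pair of clusters merges at its current
    dissimilarity; distances to the merged cluster are size-weighted means
    over members. Labels are pre-sorted so residual ties resolve by label
    order deterministically.
    """
    if len(d.labels) < 2:
        raise ValueError("need at least 2 leaves")
    Z = hierarchy.linkage(d.condensed, method="average")
    return Dendrogram(labels=d.labels, linkage=Z)


def cophenetic_correlation(dend: Dendrogram, d: DissimilarityMatrix) -> float:
    """Pearson r between original dissimilarities and cophenetic distances."""
    if tuple(dend.labels) != tuple(d.labels):
        raise ValueError("dendrogram and matrix labels differ")
    if len(d.labels) < 3:
        raise ValueError("cophenetic correlation needs at least 3 leaves")
    r, _ = pearsonr(d.condensed, dend.cophenetic_matrix())
    return float(r)


def cut_into_groups(dend: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into k flat groups (for phylotype-recovery checks)."""
    assign = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    return {lbl: int(g) for lbl, g in zip(dend.labels, assign)}


def bootstrap_support(
    profiles: list[FameProfile], B: int = 1000, seed: int | None = None
) -> Dendrogram:
    """UPGMA dendrogram with species-resampled bootstrap node supports.

    The exchangeable axis of a strains x fatty-acids table is the species
    column: each replicate resamples columns with replacement, recomputes
    Bray-Curtis + UPGMA, and a node's support is the percentage of
    replicates whose dendrogram contains the same leaf set. B = 0 returns
    the plain dendrogram with no supports.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles")
    labels, species, mat = _abundance_matrix(profiles)
    if len(species) < 2:
        raise ValueError("need at least 2 fatty-acid species to resample")
    if B < 0:
        raise ValueError("B must be >= 0")

    base = Dendrogram(
        labels=tuple(labels),
        linkage=hierarchy.linkage(pdist(mat, metric="braycurtis"), method="average"),
    )
    if B == 0:
        return base

    target = base.bipartitions()
    hits = np.zeros(len(target))
    rng = np.random.default_rng(seed)
    n_sp = len(species)
    for _ in range(B):
        cols = rng.integers(0, n_sp, size=n_sp)
        resampled = mat[:, cols]
        keep = resampled.sum(axis=1) > 0
        if not keep.all():  # a strain lost all its mass: replicate uninformative
            continue
        Z = hierarchy.linkage(pdist(resampled, metric="braycurtis"), method="average")
        rep = Dendrogram(labels=tuple(labels), linkage=Z)
        rep_parts = set(rep.bipartitions())
        for i, part in enumerate(target):
            if part in rep_parts:
                hits[i] += 1
    return Dendrogram(
        labels=base.labels, linkage=base.linkage, supports=100.0 * hits / B
    )
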