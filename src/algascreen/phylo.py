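"""18S rRNA phylotyping: alignment cleaning, distances, neighbour joining.

The pipeline consumes an already-aligned FASTA (alignment itself is out of
scope), removes ambiguous regions with a Gblocks-style block filter
(minimum block length 10, no gap columns, non-conserved runs longer than 8
rejected, 85% flank rule), computes pairwise distances (p-distance or its
JC69 correction), reconstructs an unrooted neighbour-joining tree with
column-bootstrap supports, and demarcates phylotypes as single-linkage
groups of leaves whose patristic distance is at most a threshold
(0.001 substitutions/site by default).

Trees are scikit-bio :class:`~skbio.TreeNode` objects; distance matrices
are :class:`~skbio.DistanceMatrix`.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "Alignment",
    "BlockFilterParams",
    "PhylotypeAssignment",
    "length_filter",
    "clean_alignment",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_tree",
    "tree_splits",
    "demarcate_phylotypes",
]

GAP_CHARS = frozenset("-.")
AMBIGUOUS_CHARS = frozenset("N")


@dataclass(frozen=True)
class Alignment:
    """A rectangular multiple alignment over {A, C, G, T, -, N}."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"not aligned: ragged sequence lengths {sorted(lengths)}")
        object.__setattr__(self, "seqs", tuple(s.upper() for s in self.seqs))

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.seqs)

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(
            ids=self.ids, seqs=tuple("".join(s[j] for j in cols) for s in self.seqs)
        )

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.ids, self.seqs))


@dataclass(frozen=True)
class BlockFilterParams:
    """Gblocks-style block-cleaning parameters.

    Defaults mirror a strict cleaning: blocks of >= 10 columns, no gap
    columns, runs of more than 8 contiguous non-conserved columns rejected,
    block flanks require >= 85% identity, a column is conserved when its
    modal residue exceeds 50% of sequences (strictly greater).
    """

    min_block_length: int = 10
    allow_gap_columns: bool = False
    max_contiguous_nonconserved: int = 8
    flank_fraction: float = 0.85
    conserved_fraction: float = 0.50

    def __post_init__(self) -> None:
        if not (0.5 <= self.flank_fraction <= 1.0):
            raise ValueError("flank_fraction must lie in [0.5, 1]")
        if not (0.5 <= self.conserved_fraction <= 1.0):
            raise ValueError("conserved_fraction must lie in (0.5, 1]")
        if self.flank_fraction < self.conserved_fraction:
            raise ValueError("flank_fraction must be >= conserved_fraction")
        if self.min_block_length < 1 or self.max_contiguous_nonconserved < 0:
            raise ValueError("bad block-length parameters")


def ungapped_length(seq: str) -> int:
    return sum(1 for c in seq if c not in GAP_CHARS)


def length_filter(
    sequences: Mapping[str, str], min_bp: int = 400
) -> dict[str, str]:
    """Keep sequences whose ungapped length is strictly greater than min_bp."""
    kept = {sid: s for sid, s in sequences.items() if ungapped_length(s) > min_bp}
    dropped = sorted(set(sequences) - set(kept))
    if dropped:
        warnings.warn(
            f"{len(dropped)} sequence(s) <= {min_bp} bp excluded: {', '.join(dropped)}",
            stacklevel=2,
        )
    return kept


def _column_status(aln: Alignment, params: BlockFilterParams):
    """Per-column (has_gap, conserved, flank_conserved) flags."""
    n = aln.n_taxa
    has_gap = np.zeros(aln.n_columns, dtype=bool)
    conserved = np.zeros(aln.n_columns, dtype=bool)
    flank = np.zeros(aln.n_columns, dtype=bool)
    for j in range(aln.n_columns):
        col = aln.column(j)
        has_gap[j] = any(c in GAP_CHARS for c in col)
        residues = [c for c in col if c not in GAP_CHARS and c not in AMBIGUOUS_CHARS]
        if residues:
            modal = Counter(residues).most_common(1)[0][1] / n
        else:
            modal = 0.0
        conserved[j] = modal > params.conserved_fraction
        flank[j] = modal >= params.flank_fraction
    return has_gap, conserved, flank


def clean_alignment(
    aln: Alignment, params: BlockFilterParams | None = None
) -> tuple[Alignment, list[int]]:
    """Remove gap columns and poorly aligned blocks; return kept-column map.

    Five steps: classify columns; drop gap columns; reject runs of more
    than ``max_contiguous_nonconserved`` consecutive non-conserved columns;
    trim each surviving block until both flanks are high-identity columns;
    discard blocks shorter than ``min_block_length``. Kept columns are
    reported as indices into the input alignment, in original order. An
    empty result is signalled with a warning, not an error.
    """
    params = params or BlockFilterParams()
    has_gap, conserved, flank = _column_status(aln, params)

    cols = [
        j for j in range(aln.n_columns)
        if params.allow_gap_columns or not has_gap[j]
    ]

    # split at non-conserved runs longer than the cap
    blocks: list[list[int]] = []
    current: list[int] = []
    run: list[int] = []  # pending non-conserved run
    for j in cols:
        if conserved[j]:
            if len(run) > params.max_contiguous_nonconserved:
                # overlong run rejected entirely; it splits the block
                if current:
                    blocks.append(current)
                current = []
            else:
                current.extend(run)
            run = []
            current.append(j)
        else:
            run.append(j)
    if run and len(run) <= params.max_contiguous_nonconserved:
        current.extend(run)
    if current:
        blocks.append(current)

    kept: list[int] = []
    for block in blocks:
        lo, hi = 0, len(block)
        while lo < hi and not flank[block[lo]]:
            lo += 1
        while hi > lo and not flank[block[hi - 1]]:
            hi -= 1
        trimmed = block[lo:hi]
        if len(trimmed) >= params.min_block_length:
            kept.extend(trimmed)

    if not kept:
        warnings.warn("block filtering removed every column", stacklevel=2)
    return aln.take_columns(kept), kept


def pairwise_distance(aln: Alignment, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise p-distance or JC69 distance with pairwise deletion of gaps/N.

    JC69 is -(3/4) ln(1 - 4p/3); saturated pairs (p >= 0.75) have no finite
    JC69 distance and are reported as an error naming the pairs.
    """
    if model not in ("p_distance", "jc69"):
        raise ValueError(f"unknown model {model!r}")
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(s) for s in aln.seqs])
    valid = ~(
        np.isin(arr, list(GAP_CHARS)) | np.isin(arr, list(AMBIGUOUS_CHARS))
    )
    n = aln.n_taxa
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            sites = int(both.sum())
            if sites == 0:
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / sites
            if model == "jc69":
                if p >= 0.75:
                    saturated.append((aln.ids[i], aln.ids[j], p))
                    continue
                p = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    if saturated:
        pairs = ", ".join(f"{a}-{b} (p={p:.3f})" for a, b, p in saturated)
        raise ValueError(f"JC69 distance undefined (p >= 0.75) for: {pairs}")
    return DistanceMatrix(d, ids=aln.ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining on a symmetric distance matrix.

    Repeatedly joins the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j;
    branch lengths use the rate-corrected split formula, with negative
    lengths clamped to zero and the deficit moved to the sister branch.
    Ties break deterministically by (lexicographically smallest member)
    label order. The result is the conventional unrooted tree with a
    trifurcating root; on additive matrices topology and branch lengths
    are recovered exactly.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]
    # tie-break key: smallest member label of each active cluster
    keys: list[str] = [str(i) for i in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best_pair = None
        best_q = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                if (
                    best_q is None
                    or q < best_q - 1e-12
                    or (abs(q - best_q) <= 1e-12 and key < best_key)
                ):
                    best_q, best_pair, best_key = q, (i, j), key
        i, j = best_pair
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj, li = D[i, j], 0.0
            warnings.warn("negative branch length clamped to 0", stacklevel=2)
        elif lj < 0:
            li, lj = D[i, j], 0.0
            warnings.warn("negative branch length clamped to 0", stacklevel=2)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        parent = TreeNode(children=[child_i, child_j])
        # distances to the new cluster
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    children = []
    for k, lk in ((a, la), (b, lb), (c, lc)):
        if lk < 0:
            warnings.warn("negative branch length clamped to 0", stacklevel=2)
            lk = 0.0
        nodes[k].length = float(lk)
        children.append(nodes[k])
    return TreeNode(children=children)


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalised.

    Each internal edge splits the taxa in two; the side not containing the
    lexicographically smallest taxon represents the split, which makes the
    set rooting- and orientation-invariant.
    """
    taxa = frozenset(t.name for t in tree.tips())
    anchor = min(taxa)
    splits = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 2 <= len(clade) <= len(taxa) - 2:
            side = taxa - clade if anchor in clade else clade
            splits.add(side)
    return splits


def bootstrap_tree(
    aln: Alignment,
    B: int = 1000,
    model: str = "p_distance",
    seed: int | None = None,
) -> TreeNode:
    """NJ tree with column-bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement B times; each internal
    edge's support is the percentage of replicate trees containing the same
    bipartition, stored as ``node.support`` (which the Newick writer emits
    as the internal-node label).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    base = neighbor_joining(pairwise_distance(aln, model=model))
    taxa = frozenset(aln.ids)
    anchor = min(taxa)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    n_cols = aln.n_columns
    usable = 0
    for _ in range(B):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_aln = aln.take_columns(list(cols))
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep_aln, model=model))
        except ValueError:
            continue  # e.g. saturated JC69 replicate: counts as no support
        usable += 1
        for split in tree_splits(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    for node in base.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 2 <= len(clade) <= len(taxa) - 2:
            side = taxa - clade if anchor in clade else clade
            node.support = 100.0 * counts.get(side, 0) / B
    base.n_bootstrap = B
    base.n_usable_replicates = usable
    return base


@dataclass(frozen=True)
class PhylotypeAssignment:
    """Partition of leaves into phylotypes at a patristic-distance threshold."""

    assignment: Mapping[str, int]
    threshold: float

    @property
    def n_phylotypes(self) -> int:
        return len(set(self.assignment.values()))

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for taxon, pid in self.assignment.items():
            out.setdefault(pid, []).append(taxon)
        return {k: sorted(v) for k, v in out.items()}


def demarcate_phylotypes(tree: TreeNode, threshold: float = 0.001) -> PhylotypeAssignment:
    """Group leaves whose patristic distance is <= threshold (single linkage).

    Two leaves share a phylotype if connected by a chain of leaves with
    consecutive path-length distances at or below the threshold; the result
    is a partition and is monotone in the threshold.
    """
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    parent = {t: t for t in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if dm[a, b] <= threshold:
                parent[find(a)] = find(b)

    roots: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for t in sorted(ids):
        root = find(t)
        if root not in roots:
            roots[root] = len(roots) + 1
        assignment[t] = roots[root]
    return PhylotypeAssignment(assignment=assignment, threshold=threshold)
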