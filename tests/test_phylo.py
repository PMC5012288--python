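"""Alignment cleaning, distances, neighbour joining and phylotype demarcation."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from algascreen.phylo import (
    Alignment,
    BlockFilterParams,
    clean_alignment,
    demarcate_phylotypes,
    length_filter,
    neighbor_joining,
    pairwise_distance,
    bootstrap_tree,
    tree_splits,
)
from algascreen.synthetic import _evolve_jc


def _supports(tree):
    return [
        n.support for n in tree.non_tips(include_self=False) if hasattr(n, "support")
    ]


class TestLengthFilter:
    def test_strictly_greater_than_400(self):
        seqs = {"a": "A" * 399, "b": "A" * 400, "c": "A" * 401}
        with pytest.warns(UserWarning):
            kept = length_filter(seqs)
        assert set(kept) == {"c"}

    def test_gaps_do_not_count(self):
        seqs = {"a": "A" * 390 + "-" * 60, "b": "A" * 401 + "-" * 49}
        with pytest.warns(UserWarning):
            kept = length_filter(seqs)
        assert set(kept) == {"b"}

    def test_all_short_returns_empty_with_warning(self):
        with pytest.warns(UserWarning):
            assert length_filter({"a": "ACGT"}) == {}


def _toy_alignment(run_length: int) -> Alignment:
    """15 identical cols, a run of `run_length` all-different cols, then
    identical cols padding to 40 total (3 sequences)."""
    tail = 40 - 15 - run_length
    rows = {0: [], 1: [], 2: []}
    for _ in range(15):
        for r in rows.values():
            r.append("A")
    for _ in range(run_length):
        for r, c in zip(rows.values(), "ACG"):
            r.append(c)
    for _ in range(tail):
        for r in rows.values():
            r.append("T")
    return Alignment(
        ids=("s1", "s2", "s3"), seqs=tuple("".join(rows[i]) for i in range(3))
    )


class TestCleanAlignment:
    def test_all_gap_column_removed(self):
        base = "ACGTACGTACGT"
        aln = Alignment(("a", "b"), (base[:6] + "-" + base[6:],) * 2)
        cleaned, kept = clean_alignment(aln)
        assert cleaned.seqs == (base, base)
        assert kept == [0, 1, 2, 3, 4, 5] + list(range(7, 13))

    def test_identical_gap_free_alignment_unchanged(self):
        aln = Alignment(("a", "b", "c"), ("ACGT" * 5,) * 3)
        cleaned, kept = clean_alignment(aln)
        assert cleaned.seqs == aln.seqs
        assert kept == list(range(20))

    def test_nonconserved_run_of_nine_rejected_eight_kept(self):
        # hand-traced oracle of the five cleaning steps on a 40-column toy
        cleaned9, kept9 = clean_alignment(_toy_alignment(9))
        assert len(kept9) == 40 - 9  # the overlong run is dropped
        assert kept9 == list(range(15)) + list(range(24, 40))
        cleaned8, kept8 = clean_alignment(_toy_alignment(8))
        assert kept8 == list(range(40))  # an 8-run is retained

    def test_short_blocks_dropped(self):
        # raising the minimum block length drops both flanking blocks
        # (15 and 16 columns around the rejected 9-column run)
        aln = _toy_alignment(9)
        params = BlockFilterParams(min_block_length=20)
        with pytest.warns(UserWarning, match="removed every column"):
            _, kept = clean_alignment(aln, params)
        assert kept == []

    def test_kept_columns_in_order_and_idempotent(self):
        # mostly conserved alignment with scattered mutations and gaps
        rng = np.random.default_rng(0)
        base = rng.choice(list("ACGT"), size=120)
        cols = np.tile(base, (4, 1))
        mutate = rng.random(cols.shape) < 0.08
        cols[mutate] = rng.choice(list("ACGT-"), size=int(mutate.sum()))
        aln = Alignment(
            tuple(f"t{i}" for i in range(4)), tuple("".join(r) for r in cols)
        )
        cleaned, kept = clean_alignment(aln)
        assert kept == sorted(kept)
        recleaned, kept2 = clean_alignment(cleaned)
        assert recleaned.seqs == cleaned.seqs
        assert kept2 == list(range(cleaned.n_columns))

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="not aligned"):
            Alignment(("a", "b"), ("ACGT", "ACG"))


class TestPairwiseDistance:
    def test_identical_sequences(self):
        aln = Alignment(("a", "b"), ("ACGT" * 25,) * 2)
        for model in ("p_distance", "jc69"):
            assert pairwise_distance(aln, model)["a", "b"] == 0.0

    def test_ten_mismatches_in_100(self):
        s1 = "A" * 100
        s2 = "C" * 10 + "A" * 90
        aln = Alignment(("a", "b"), (s1, s2))
        assert pairwise_distance(aln, "p_distance")["a", "b"] == pytest.approx(0.10)
        jc = -0.75 * math.log(1 - 4 * 0.10 / 3)
        assert pairwise_distance(aln, "jc69")["a", "b"] == pytest.approx(jc, abs=1e-5)
        assert jc == pytest.approx(0.10732, abs=1e-5)

    def test_gaps_deleted_pairwise(self):
        aln = Alignment(("a", "b"), ("AC-TA", "ACGTC"))
        # compared sites: 4; one mismatch
        assert pairwise_distance(aln)["a", "b"] == pytest.approx(0.25)

    def test_jc_exceeds_p(self):
        rng = np.random.default_rng(1)
        s1 = "".join(rng.choice(list("ACGT"), 200))
        s2 = "".join(rng.choice(list("ACGT"), 150)) + s1[150:]
        aln = Alignment(("a", "b"), (s1, s2))
        p = pairwise_distance(aln, "p_distance")["a", "b"]
        jc = pairwise_distance(aln, "jc69")["a", "b"]
        assert jc >= p

    def test_saturated_pair_errors_under_jc(self):
        aln = Alignment(("a", "b"), ("A" * 100, "C" * 100))
        with pytest.raises(ValueError, match="a-b"):
            pairwise_distance(aln, "jc69")


def _random_additive_tree(n, seed):
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"T{i}", length=float(rng.uniform(0.1, 1.0))) for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(0.1, 1.0))
        )
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    return TreeNode(children=nodes)


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        dm = DistanceMatrix(d, ids=["A", "B", "C", "D"])
        tree = neighbor_joining(dm)
        out = tree.tip_tip_distances().filter(["A", "B", "C", "D"])
        assert np.allclose(out.data, d)
        assert tree_splits(tree) == {frozenset({"C", "D"})}

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float), ids=["A", "B", "C"]
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_additive_exactness_random_trees(self, n):
        for seed in range(5):
            true = _random_additive_tree(n, 100 * n + seed)
            dm = true.tip_tip_distances()
            est = neighbor_joining(dm)
            est_dm = est.tip_tip_distances().filter(dm.ids)
            assert np.allclose(est_dm.data, dm.data, atol=1e-9)
            assert tree_splits(est) == tree_splits(true)

    def test_agrees_with_independent_nj_implementation(self):
        true = _random_additive_tree(6, 77)
        dm = true.tip_tip_distances()
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert tree_splits(ours) == tree_splits(theirs)

    def test_ultrametric_matrix_matches_upgma_topology(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 3))
        Z = hierarchy.linkage(pts, method="average")
        coph = squareform(hierarchy.cophenet(Z))
        labels = [f"T{i}" for i in range(6)]
        tree = neighbor_joining(DistanceMatrix(coph, ids=labels))
        # UPGMA clades, expressed as splits
        members = {i: frozenset([labels[i]]) for i in range(6)}
        taxa = frozenset(labels)
        anchor = min(taxa)
        upgma_splits = set()
        for k, (a, b, _, _) in enumerate(Z):
            merged = members[int(a)] | members[int(b)]
            members[6 + k] = merged
            if 2 <= len(merged) <= 4:
                upgma_splits.add(taxa - merged if anchor in merged else merged)
        assert tree_splits(tree) == upgma_splits

    def test_asymmetric_matrix_rejected(self):
        class Loose:  # bypasses DistanceMatrix's own symmetry validation
            ids = ("a", "b", "c")
            data = np.array([[0, 5, 2], [1, 0, 3], [2, 3, 0]], float)

        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(Loose())


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment(sites=5000, seed=0):
        rng = np.random.default_rng(seed)
        root = rng.integers(0, 4, size=sites)
        left = _evolve_jc(root, 0.2, rng)
        right = _evolve_jc(root, 0.2, rng)
        seqs = {
            "A": _evolve_jc(left, 0.05, rng),
            "B": _evolve_jc(left, 0.05, rng),
            "C": _evolve_jc(right, 0.05, rng),
            "D": _evolve_jc(right, 0.05, rng),
        }
        chars = np.array(list("ACGT"))
        return Alignment(
            ids=tuple(sorted(seqs)),
            seqs=tuple("".join(chars[seqs[k]]) for k in sorted(seqs)),
        )

    def test_long_internal_branch_has_high_support(self):
        aln = self._two_clade_alignment()
        tree = bootstrap_tree(aln, B=100, seed=0)
        sup = _supports(tree)
        assert len(sup) == 1
        assert sup[0] >= 99.0

    def test_b1_supports_binary(self):
        aln = self._two_clade_alignment(sites=300, seed=1)
        tree = bootstrap_tree(aln, B=1, seed=2)
        assert set(_supports(tree)) <= {0.0, 100.0}

    def test_seed_reproducibility(self):
        aln = self._two_clade_alignment(sites=300, seed=1)
        s1 = _supports(bootstrap_tree(aln, B=20, seed=5))
        s2 = _supports(bootstrap_tree(aln, B=20, seed=5))
        assert s1 == s2

    def test_b_zero_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_tree(self._two_clade_alignment(sites=100), B=0)


class TestDemarcatePhylotypes:
    def test_zero_branch_lengths_single_phylotype(self):
        tree = TreeNode.read(["((A:0,B:0):0,(C:0,D:0):0);"])
        assert demarcate_phylotypes(tree).n_phylotypes == 1

    def test_zero_threshold_splits_everything(self):
        tree = TreeNode.read(["((A:0.1,B:0.2):0.1,(C:0.3,D:0.4):0.1);"])
        assert demarcate_phylotypes(tree, threshold=0.0).n_phylotypes == 4

    def test_two_tight_pairs(self):
        nwk = "((A:0.00025,B:0.00025):0.02,(C:0.00025,D:0.00025):0.02,(E:0.05,F:0.07):0.02);"
        tree = TreeNode.read([nwk])
        pa = demarcate_phylotypes(tree, threshold=0.001)
        assert pa.n_phylotypes == 6 - 2
        groups = {frozenset(v) for v in pa.groups().values()}
        assert frozenset({"A", "B"}) in groups and frozenset({"C", "D"}) in groups

    def test_monotone_in_threshold(self):
        tree = TreeNode.read(["((A:0.001,B:0.002):0.01,(C:0.003,D:0.004):0.01);"])
        last = None
        for thr in (0.0, 0.003, 0.007, 0.05, 1.0):
            n = demarcate_phylotypes(tree, threshold=thr).n_phylotypes
            if last is not None:
                assert n <= last
            last = n

    def test_partition_property(self):
        tree = TreeNode.read(["((A:0.1,B:0.2):0.1,(C:0.3,D:0.4):0.1);"])
        pa = demarcate_phylotypes(tree, threshold=0.5)
        assert sorted(pa.assignment) == ["A", "B", "C", "D"]
        assert sum(len(v) for v in pa.groups().values()) == 4
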