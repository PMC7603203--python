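"""Alignment, identity, neighbor joining, bootstrap and clade assignment."""

import numpy as np
import pytest

from tpsinv.phylo import (
    AlignmentParams,
    align_global,
    assign_by_reference,
    bootstrap_support,
    nj_tree,
    pairwise_identity,
    progressive_msa,
    to_newick,
    tree_bipartitions,
)


class TestAlignGlobal:
    def test_identical_sequences_align_without_gaps(self):
        aln = align_global("ACDE", "ACDE")
        assert aln.aligned_a == aln.aligned_b == "ACDE"

    def test_deletion_introduces_one_gap_column(self):
        aln = align_global("ACDE", "ACE")
        assert len(aln.aligned_a) == 4
        assert aln.aligned_a.count("-") == 0
        assert aln.aligned_b.count("-") == 1

    def test_score_symmetry(self):
        a, b = "MKTAYIAKQR", "MKTAHIAKQRQIS"
        assert align_global(a, b).score == pytest.approx(align_global(b, a).score)

    def test_scores_match_biopython_aligner(self):
        """Cross-check the Gotoh DP against Biopython's pairwise aligner."""
        from Bio.Align import PairwiseAligner, substitution_matrices

        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        aligner.mode = "global"
        rng = np.random.default_rng(7)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(aas[i] for i in rng.integers(0, 20, size=rng.integers(10, 60)))
            b = "".join(aas[i] for i in rng.integers(0, 20, size=rng.integers(10, 60)))
            assert align_global(a, b).score == pytest.approx(aligner.score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "ACDE")


class TestPairwiseIdentity:
    def test_identical_is_100(self):
        assert pairwise_identity("MKTAYIAKQR", "MKTAYIAKQR") == 100.0

    def test_single_mismatch_over_four_columns(self):
        assert pairwise_identity("ACDE", "ACDF") == pytest.approx(75.0)

    def test_symmetry(self):
        a, b = "MKTAYIAKQRLMW", "MKTAHIAKQR"
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_full_denominator_is_100_iff_equal(self):
        params = AlignmentParams(identity_denominator="full")
        assert pairwise_identity("ACDEFG", "ACDEFG", params) == 100.0
        # a nested substring reaches 100 only under the trimmed convention
        assert pairwise_identity("AAACDE", "CDE", params) < 100.0
        assert 0.0 <= pairwise_identity("AAACDE", "CDE") <= 100.0

    def test_bounds(self):
        assert 0.0 <= pairwise_identity("WWWW", "AAAA") <= 100.0


def _random_additive_tree(rng, n_taxa):
    """Random binary tree; returns (distance matrix, set of bipartitions).

    Pairwise distances are accumulated at each merge (leaf depth within each
    subtree plus the two new edges), so the matrix is additive by
    construction — an oracle independent of the NJ implementation.
    """
    names = [f"t{i}" for i in range(n_taxa)]
    pair_d = {}
    nodes = [({nm}, {nm: 0.0}) for nm in names]
    splits = []
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (sa, da), (sb, db) = nodes[i], nodes[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        for x in sa:
            for y in sb:
                pair_d[frozenset((x, y))] = da[x] + la + db[y] + lb
        merged = {t: d + la for t, d in da.items()}
        merged.update({t: d + lb for t, d in db.items()})
        union = sa | sb
        if 2 <= len(union) <= n_taxa - 2:
            splits.append(frozenset(union))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [(union, merged)]
    (sa, da), (sb, db) = nodes
    bridge = rng.uniform(0.1, 1.0)
    for x in sa:
        for y in sb:
            pair_d[frozenset((x, y))] = da[x] + db[y] + bridge
    dist = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            dist[x, y] = dist[y, x] = pair_d[frozenset((names[x], names[y]))]
    all_taxa = frozenset(names)
    anchor = min(names)
    canonical = {s if anchor not in s else all_taxa - s for s in splits}
    return names, dist, canonical


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # distances generated from tree ((A:1,B:2):1,(C:3,D:4))
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(d, ids=list("ABCD"))
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = [n.length for n in tree.non_tips(include_self=False)]
        assert internal == pytest.approx([1.0])

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(d, ids=list("ABC"))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})

    def test_equidistant_matrix_ties_resolve_to_lowest_indices(self):
        d = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(d, ids=list("ABCD"))
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d, ids=list("ABC"))

    def test_random_additive_trees_recovered(self):
        """NJ is exact on additive distances (path-length oracle, <= 8 taxa)."""
        rng = np.random.default_rng(11)
        for trial in range(25):
            n = int(rng.integers(4, 9))
            names, dist, expected = _random_additive_tree(rng, n)
            tree = nj_tree(dist, ids=names)
            assert tree_bipartitions(tree) == expected, f"trial {trial}"

    def test_agrees_with_skbio_on_additive_matrix(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        names, dist, _ = _random_additive_tree(rng, 7)
        ours = tree_bipartitions(nj_tree(dist, ids=names))
        theirs = tree_bipartitions(skbio_nj(DistanceMatrix(dist, ids=names)))
        assert ours == theirs


def _mutated(seq, k, rng):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = list(seq)
    for i in rng.choice(len(out), size=k, replace=False):
        out[i] = aas[(aas.index(out[i]) + 7) % 20]
    return "".join(out)


@pytest.fixture(scope="module")
def two_families():
    rng = np.random.default_rng(3)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    fam1 = "".join(aas[i] for i in rng.integers(0, 20, size=120))
    fam2 = "".join(aas[i] for i in rng.integers(0, 20, size=120))
    refs = {
        "a1": _mutated(fam1, 3, rng),
        "a2": _mutated(fam1, 5, rng),
        "b1": _mutated(fam2, 3, rng),
        "b2": _mutated(fam2, 5, rng),
    }
    labels = {"a1": "famA", "a2": "famA", "b1": "famB", "b2": "famB"}
    return fam1, fam2, refs, labels


class TestBootstrap:
    def test_divergent_clusters_get_full_support(self, two_families):
        _, _, refs, _ = two_families
        tree = bootstrap_support(list(refs.items()), n_replicates=50, seed=1)
        supports = [n.support for n in tree.non_tips(include_self=False) if n.support is not None]
        assert supports == [100.0]

    def test_single_replicate_supports_are_binary(self, two_families):
        _, _, refs, _ = two_families
        tree = bootstrap_support(list(refs.items()), n_replicates=1, seed=0)
        for n in tree.non_tips(include_self=False):
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_seed_determinism_and_order_invariance(self, two_families):
        _, _, refs, _ = two_families
        items = list(refs.items())
        t1 = to_newick(bootstrap_support(items, n_replicates=30, seed=9))
        t2 = to_newick(bootstrap_support(items[::-1], n_replicates=30, seed=9))
        assert t1 == t2

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support([("a", "ACDE"), ("b", "ACD")], n_replicates=2, seed=0)


class TestAssignByReference:
    def test_planted_neighbor_recovers_family_label(self, two_families):
        fam1, _, refs, labels = two_families
        rng = np.random.default_rng(8)
        query = _mutated(fam1, 2, rng)
        assert assign_by_reference("q", query, refs, labels, seed=4) == "famA"

    def test_label_renaming_renames_output(self, two_families):
        fam1, _, refs, labels = two_families
        rng = np.random.default_rng(8)
        query = _mutated(fam1, 2, rng)
        renamed = {k: v.replace("fam", "clade") for k, v in labels.items()}
        assert assign_by_reference("q", query, refs, renamed, seed=4) == "cladeA"

    def test_zero_threshold_always_labels(self, two_families):
        fam1, _, refs, labels = two_families
        rng = np.random.default_rng(12)
        query = _mutated(fam1, 30, rng)
        result = assign_by_reference("q", query, refs, labels, support_threshold=0.0, seed=4)
        assert result in ("famA", "famB")

    def test_single_label_rejected(self, two_families):
        fam1, _, refs, _ = two_families
        labels = {k: "same" for k in refs}
        with pytest.raises(ValueError):
            assign_by_reference("q", fam1, refs, labels)

    def test_unequal_lengths_go_through_progressive_alignment(self, two_families):
        fam1, _, refs, labels = two_families
        refs = dict(refs)
        refs["a2"] = refs["a2"][:110]
        rng = np.random.default_rng(8)
        query = _mutated(fam1, 2, rng)
        assert assign_by_reference("q", query, refs, labels, seed=4) == "famA"


class TestProgressiveMsa:
    def test_alignment_columns_preserve_sequences(self, two_families):
        _, _, refs, _ = two_families
        seqs = dict(refs)
        seqs["short"] = seqs["a1"][:100]
        msa = progressive_msa(seqs)
        lengths = {len(s) for s in msa.values()}
        assert len(lengths) == 1
        for name, aligned in msa.items():
            assert aligned.replace("-", "") == seqs[name]
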