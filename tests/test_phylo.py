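"""Strain matrices, SNV rates, distance matrices, neighbor joining."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix as SkDistanceMatrix
from skbio.tree import nj as skbio_nj

from straintrace import DistanceMatrix, distance_matrix, nj_tree, snv_rate
from straintrace.consensus import ConsensusSequence
from straintrace.phylo import StrainMatrix, neighbor_joining, project_and_concatenate
from straintrace._seq import encode

from conftest import normalize_splits, random_additive_tree, tree_splits


def cons(sample, mid, seq, species="sp"):
    unmasked = sum(c != "N" for c in seq) / len(seq)
    return ConsensusSequence(sample, species, mid, seq, unmasked)


class TestProjection:
    def test_identical_consensuses_give_identical_rows(self):
        m = project_and_concatenate(
            {"a": [cons("a", "m1", "ACGT")], "b": [cons("b", "m1", "ACGT")]}, "sp"
        )
        assert (m.codes[0] == m.codes[1]).all()

    def test_missing_marker_fills_n_in_that_row_only(self):
        m = project_and_concatenate(
            {
                "a": [cons("a", "m1", "ACGT"), cons("a", "m2", "GGCC")],
                "b": [cons("b", "m1", "ACGT")],
            },
            "sp",
        )
        assert m.marker_ids == ["m1", "m2"]
        assert m.row_sequence("a") == "ACGTGGCC"
        assert m.row_sequence("b") == "ACGTNNNN"

    def test_column_count_is_sum_of_marker_lengths(self):
        m = project_and_concatenate(
            {
                "a": [cons("a", "m1", "ACGTAC"), cons("a", "m2", "GG")],
                "b": [cons("b", "m1", "ACGTAC"), cons("b", "m2", "GG")],
            },
            "sp",
        )
        assert m.n_columns == 8

    def test_reference_strains_added_as_rows(self):
        m = project_and_concatenate(
            {"a": [cons("a", "m1", "ACGT")], "b": [cons("b", "m1", "ACGT")]},
            "sp",
            reference_strains={"ref1": {"m1": "ACGA"}},
        )
        assert m.samples == ["a", "b", "ref1"]
        assert m.row_sequence("ref1") == "ACGA"

    def test_species_absent_everywhere_raises(self):
        with pytest.raises(ValueError):
            project_and_concatenate({"a": []}, "sp")


class TestSnvRate:
    def test_four_in_ten_thousand_is_rate_0_04(self, rng):
        base = rng.choice(list("ACGT"), 10_000)
        other = base.copy()
        for pos in [17, 1000, 5000, 9999]:
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        r = snv_rate("".join(base), "".join(other))
        assert r.n_columns == 10_000
        assert r.rate == pytest.approx(0.04, abs=1e-12)
        assert 100 - r.rate == pytest.approx(99.96)  # identity scale

    def test_identity_and_simple_fraction(self):
        assert snv_rate("ACGT" * 300, "ACGT" * 300, min_columns=1).rate == 0.0
        r = snv_rate("ACGTACGTAC", "ACGTACGTAT", min_columns=1)
        assert r.rate == pytest.approx(10.0)

    def test_insufficient_overlap_flagged(self):
        r = snv_rate("ACGT", "ACGT", min_columns=1000)
        assert not r.sufficient
        r0 = snv_rate("NNNN", "ACGT", min_columns=1)
        assert not r0.sufficient and r0.n_columns == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_masking_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, 300).astype(np.uint8)  # 4 == N
        b = rng.integers(0, 5, 300).astype(np.uint8)
        ra = snv_rate(a, b, min_columns=1)
        rb = snv_rate(b, a, min_columns=1)
        assert ra == rb
        # adding masked columns never changes the rate on the remaining ones
        a2 = np.concatenate([a, np.full(50, 4, np.uint8)])
        b2 = np.concatenate([b, rng.integers(0, 5, 50).astype(np.uint8)])
        b2[-50:] = 4
        r2 = snv_rate(a2, b2, min_columns=1)
        assert r2.n_columns == ra.n_columns
        if ra.n_columns:
            assert r2.rate == ra.rate

    def test_zero_rate_iff_identical_on_joint_columns(self, rng):
        a = rng.integers(0, 4, 100).astype(np.uint8)
        b = a.copy()
        b[:10] = 4
        assert snv_rate(a, b, min_columns=1).rate == 0.0


class TestDistanceMatrix:
    def make_matrix(self, rng, n=5, length=200):
        codes = rng.integers(0, 5, (n, length)).astype(np.uint8)
        return StrainMatrix("sp", [f"s{i}" for i in range(n)], ["m1"], codes)

    def test_identical_rows_all_zero(self):
        codes = np.tile(encode("ACGT" * 10), (3, 1))
        m = StrainMatrix("sp", ["a", "b", "c"], ["m1"], codes)
        dm = distance_matrix(m, min_columns=1)
        assert (dm.values == 0).all()

    def test_matches_brute_force_double_loop(self, rng):
        m = self.make_matrix(rng)
        dm = distance_matrix(m, min_columns=1)
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert dm.values[i, j] == 0
                    continue
                a, b = m.codes[i], m.codes[j]
                joint = [(x, y) for x, y in zip(a, b) if x != 4 and y != 4]
                want = 100 * sum(x != y for x, y in joint) / len(joint)
                assert dm.values[i, j] == pytest.approx(want, abs=1e-12)

    def test_permutation_consistency(self, rng):
        m = self.make_matrix(rng)
        dm = distance_matrix(m, min_columns=1)
        perm = [2, 0, 4, 1, 3]
        m2 = StrainMatrix("sp", [m.samples[i] for i in perm], ["m1"], m.codes[perm])
        dm2 = distance_matrix(m2, min_columns=1)
        for ii, i in enumerate(perm):
            for jj, j in enumerate(perm):
                assert dm2.values[ii, jj] == pytest.approx(dm.values[i, j])

    def test_all_insufficient_raises(self):
        codes = np.full((2, 10), 4, np.uint8)
        m = StrainMatrix("sp", ["a", "b"], ["m1"], codes)
        with pytest.raises(ValueError):
            distance_matrix(m, min_columns=1000)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        tree = neighbor_joining(d, ["A", "B", "C"])
        bl = {t.name: t.length for t in tree.tips()}
        assert bl["A"] == pytest.approx(0.1)
        assert bl["B"] == pytest.approx(0.1)
        assert bl["C"] == pytest.approx(0.3)

    def test_two_labels_cherry_with_half_distances(self):
        d = np.array([[0, 0.6], [0.6, 0]])
        tree = neighbor_joining(d, ["A", "B"])
        assert {t.length for t in tree.tips()} == {0.3}

    def test_equal_distances_star_like_under_tie_rule(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(d, ["A", "B", "C", "D"])
        tips = {t.name: t for t in tree.tips()}
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    assert tips[a].distance(tips[b]) == pytest.approx(1.0)
        assert {t.length for t in tree.tips()} == {0.5}

    def test_additive_metric_recovered_exactly(self, rng):
        labels, d, splits = random_additive_tree(6, rng)
        tree = neighbor_joining(d, labels)
        tips = {t.name: t for t in tree.tips()}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert tips[a].distance(tips[b]) == pytest.approx(d[i, j], abs=1e-9)
        assert tree_splits(tree, labels) == normalize_splits(splits, labels)

    def test_matches_skbio_nj_topology_on_additive_input(self, rng):
        labels, d, _ = random_additive_tree(7, rng)
        ours = neighbor_joining(d, labels)
        theirs = skbio_nj(SkDistanceMatrix(d, labels))
        assert tree_splits(ours, labels) == tree_splits(theirs, labels)

    def test_newick_round_trip_fixed_point(self, rng):
        from io import StringIO
        from skbio import TreeNode

        labels, d, _ = random_additive_tree(5, rng)
        tree = neighbor_joining(d, labels)
        nwk1 = str(tree)
        nwk2 = str(TreeNode.read(StringIO(nwk1)))
        assert nwk1 == nwk2

    def test_nj_tree_scales_percent_to_fraction(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]),
            np.full((3, 3), 10_000, int),
        )
        tree = nj_tree(dm)
        bl = {t.name: t.length for t in tree.tips()}
        assert bl["A"] == pytest.approx(0.001)  # 0.1% -> 0.001 substitutions/site

    def test_negative_branches_clamped(self):
        # strongly non-additive matrix that induces a negative NJ branch
        d = np.array(
            [[0, 1.0, 1.0, 5.0],
             [1.0, 0, 1.0, 5.0],
             [1.0, 1.0, 0, 1.0],
             [5.0, 5.0, 1.0, 0]]
        )
        tree = neighbor_joining(d, list("ABCD"))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0
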