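"""Robinson-Foulds, crossing counts, untangling, assignment tables."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (crossings_quadratic, dendropy_rf, random_binary_newick,
                     tanglegram_optimum)

from picotax import (Clustering, TanglegramLayout, ValidationError,
                     build_assignment_table, crossing_count,
                     discrepancy_stats, read_newick, robinson_foulds,
                     untangle)
from picotax.fixtures import perturb_tree_nni
from picotax.method_compare import tanglegram_svg


# ---------------------------------------------------------------------------
# Robinson-Foulds


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = read_newick("((A,B),(C,D),(E,F));")
        assert robinson_foulds(t, t, normalized=False) == 0
        assert robinson_foulds(t, t) == 0.0

    def test_hand_enumerated_example(self):
        """{AB|CDE, DE|ABC} vs {AC|BDE, DE|ABC}: symmetric difference 2
        of 4 total non-trivial bipartitions."""
        t1 = read_newick("((A,B),C,(D,E));")
        t2 = read_newick("((A,C),B,(D,E));")
        assert robinson_foulds(t1, t2, normalized=False) == 2
        assert robinson_foulds(t1, t2) == 0.5

    def test_disjoint_bipartitions_normalized_one(self):
        t1 = read_newick("(((A,B),(C,D)),(E,F));")
        t2 = read_newick("(((A,F),(C,E)),(B,D));")
        assert robinson_foulds(t1, t2) == 1.0

    def test_symmetry_and_pruning(self):
        t1 = read_newick("((A,B),(C,D),(E,X));")
        t2 = read_newick("((A,B),(C,D),(E,Y));")
        assert robinson_foulds(t1, t2) == robinson_foulds(t2, t1)
        # inputs untouched by pruning
        assert "X" in t1.leaf_set() and "Y" in t2.leaf_set()

    def test_too_few_shared_leaves(self):
        t1 = read_newick("((A,B),(C,Z));")
        t2 = read_newick("((A,B),(Y,W));")
        with pytest.raises(ValidationError, match="4"):
            robinson_foulds(t1, t2)

    def test_matches_dendropy_oracle_random_pairs(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            nw1 = random_binary_newick(labels, rng)
            nw2 = random_binary_newick(labels, rng)
            mine = robinson_foulds(read_newick(nw1), read_newick(nw2),
                                   normalized=False)
            assert mine == dendropy_rf(nw1, nw2)

    def test_single_nni_law(self, rng):
        """One NNI move changes exactly one non-trivial bipartition."""
        for _ in range(20):
            n = int(rng.integers(6, 15))
            labels = [f"t{i}" for i in range(n)]
            t = read_newick(random_binary_newick(labels, rng))
            p = perturb_tree_nni(t, 1, seed=int(rng.integers(2**31)))
            assert p.leaf_set() == t.leaf_set()
            assert robinson_foulds(t, p, normalized=False) == 2

    def test_zero_nni_moves_isomorphic(self, rng):
        t = read_newick(random_binary_newick([f"t{i}" for i in range(8)], rng))
        assert robinson_foulds(t, perturb_tree_nni(t, 0), normalized=False) == 0


# ---------------------------------------------------------------------------
# crossing_count


class TestCrossingCount:
    def test_identity_layout(self):
        lay = TanglegramLayout(list("ABC"), list("ABC"), {x: x for x in "ABC"})
        assert crossing_count(lay) == 0

    def test_full_reversal(self):
        lay = TanglegramLayout(list("ABC"), list("CBA"), {x: x for x in "ABC"})
        assert crossing_count(lay) == 3

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.permutations(list(range(12))))
    def test_equals_quadratic_oracle(self, perm):
        left = [f"L{i}" for i in range(12)]
        right = [f"L{i}" for i in perm]
        matching = {x: x for x in left}
        lay = TanglegramLayout(left, right, matching)
        assert crossing_count(lay) == crossings_quadratic(left, right, matching)

    def test_unmatched_leaves_excluded(self):
        lay = TanglegramLayout(list("ABCX"), list("CBAY"),
                               {"A": "A", "B": "B", "C": "C"})
        assert crossing_count(lay) == 3


# ---------------------------------------------------------------------------
# untangle


class TestUntangle:
    def test_planar_returned_unchanged(self):
        tl = read_newick("((A,B),(C,D));")
        tr = read_newick("((A,B),(C,D));")
        lay = untangle(tl, tr, {x: x for x in "ABCD"})
        assert lay.crossings == 0
        assert lay.left_order == lay.right_order == list("ABCD")

    def test_swapped_cherry_resolved(self):
        tl = read_newick("((A,B),(C,D));")
        tr = read_newick("((B,A),(C,D));")
        lay = untangle(tl, tr, {x: x for x in "ABCD"})
        assert lay.crossings == 0
        assert lay.crossings == tanglegram_optimum(tl, tr, {x: x for x in "ABCD"})

    def test_never_worse_and_bounded_by_optimum(self, rng):
        labels = [f"L{i}" for i in range(8)]
        n_opt = 0
        trials = 25
        for _ in range(trials):
            tl = read_newick(random_binary_newick(labels, rng))
            tr = read_newick(random_binary_newick(labels, rng))
            m = {x: x for x in labels}
            init = TanglegramLayout(tl.leaf_labels(), tr.leaf_labels(), m)
            c0 = crossing_count(init)
            lay = untangle(tl, tr, m, iterations=3)
            opt = tanglegram_optimum(tl, tr, m)
            assert opt <= lay.crossings <= c0
            n_opt += lay.crossings == opt
        assert n_opt >= trials * 0.8

    def test_unknown_leaf_in_matching(self):
        tl = read_newick("((A,B),(C,D));")
        tr = read_newick("((A,B),(C,D));")
        with pytest.raises(ValidationError, match="ZZ"):
            untangle(tl, tr, {"A": "ZZ"})

    def test_layout_json_and_svg_deterministic(self):
        tl = read_newick("((A,B),(C,D));")
        tr = read_newick("((B,A),(D,C));")
        lay1 = untangle(tl, tr, {x: x for x in "ABCD"})
        lay2 = untangle(tl, tr, {x: x for x in "ABCD"})
        assert lay1.to_json() == lay2.to_json()
        assert tanglegram_svg(lay1) == tanglegram_svg(lay2)
        assert "<svg" in tanglegram_svg(lay1)


# ---------------------------------------------------------------------------
# assignment tables and discrepancy stats


def _cl(method, assignment, rank="family"):
    return Clustering(method_id=method, rank=rank, assignment=assignment)


class TestAssignmentTable:
    def test_single_clustering_echoed(self):
        cl = _cl("ref", {"a": "F1", "b": "F1", "c": "F2"})
        t = build_assignment_table([cl], "ref")
        assert [t.label(x, "ref") for x in ["a", "b", "c"]] == ["F1", "F1", "F2"]

    def test_identical_methods_no_disagreement(self):
        a = _cl("ref", {"a": "F1", "b": "F1", "c": "F2"})
        b = _cl("m2", {"a": "X", "b": "X", "c": "Y"})
        t = build_assignment_table([a, b], "ref")
        stats = discrepancy_stats(t)
        assert stats.per_method["m2"].n_disagree == 0
        assert t.harmonization["m2"] == {"X": "F1", "Y": "F2"}

    def test_max_overlap_harmonization(self):
        """A method-B cluster overlapping F1 (3 leaves) and F2 (1 leaf)
        maps to F1."""
        ref = _cl("ref", {"a": "F1", "b": "F1", "c": "F1", "d": "F2"})
        b = _cl("B", {"a": "Z", "b": "Z", "c": "Z", "d": "Z"})
        t = build_assignment_table([ref, b], "ref")
        assert t.harmonization["B"]["Z"] == "F1"

    def test_tie_goes_to_lexicographically_smallest(self):
        ref = _cl("ref", {"a": "F1", "b": "F2"})
        b = _cl("B", {"a": "Z", "b": "Z"})
        t = build_assignment_table([ref, b], "ref")
        assert t.harmonization["B"]["Z"] == "F1"

    def test_absent_leaf_excluded_from_counts(self):
        ref = _cl("ref", {"a": "F1", "b": "F1", "c": "F2"})
        b = _cl("B", {"a": "F1", "b": "F2"})  # c missing (e.g. QC-dropped)
        t = build_assignment_table([ref, b], "ref")
        stats = discrepancy_stats(t)
        assert stats.per_method["B"].n_compared == 2
        assert t.label("c", "B") is None

    def test_counts_and_pct(self):
        """10 shared leaves, 2 harmonized mismatches -> 20% disagreement."""
        ref_assign = {f"x{i}": ("F1" if i < 5 else "F2") for i in range(10)}
        b_assign = {f"x{i}": "A1" for i in range(5)}
        b_assign.update({f"x{i}": "A2" for i in range(5, 8)})
        b_assign.update({"x8": "A1", "x9": "A1"})  # A1 still maps to F1 (5 > 2)
        t = build_assignment_table(
            [_cl("ref", ref_assign), _cl("B", b_assign)], "ref")
        m = discrepancy_stats(t).per_method["B"]
        assert (m.n_compared, m.n_disagree) == (10, 2)
        assert m.pct_disagree == pytest.approx(20.0)

    def test_disagreement_conservation(self):
        ref = _cl("ref", {"a": "F1", "b": "F1", "c": "F2", "d": "F2"})
        b = _cl("B", {"a": "F1", "b": "F2", "c": "F2", "d": "F1"})
        t = build_assignment_table([ref, b], "ref")
        m = discrepancy_stats(t).per_method["B"]
        n_agree = m.n_compared - m.n_disagree
        assert n_agree + m.n_disagree == m.n_compared

    def test_duplicate_method_ids_rejected(self):
        a = _cl("m", {"a": "F1"})
        b = _cl("m", {"a": "F2"})
        with pytest.raises(ValidationError, match="duplicate"):
            build_assignment_table([a, b], "m")

    def test_mixed_ranks_rejected(self):
        a = _cl("m1", {"a": "F1"}, rank="family")
        b = _cl("m2", {"a": "G1"}, rank="genus")
        with pytest.raises(ValidationError, match="rank"):
            build_assignment_table([a, b], "m1")
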