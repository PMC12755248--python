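"""Core tree representation: Newick I/O, splits, RF distance, surgery."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from rfwalk import (
    LeafSetMismatchError,
    NewickError,
    Split,
    Tree,
    TreeError,
    collapse_side,
    default_labels,
    expand_leaf,
    fresh_label,
    induced_subtree,
    is_isomorphic,
    max_rf_distance,
    parse_newick,
    random_tree,
    rf_distance,
    splits_compatible,
    tree_from_splits,
    write_newick,
)


QUARTET = "((a,b),(c,d));"


class TestNewickIO:
    def test_trifurcating_and_rooted_encodings_agree(self):
        assert parse_newick("((a,b),c,d);") == parse_newick(QUARTET)

    def test_branch_lengths_and_internal_labels_discarded(self):
        t = parse_newick("((a:0.1,b:2)x:3,(c,d)y);")
        assert t == parse_newick(QUARTET)

    @pytest.mark.parametrize(
        "bad",
        [
            "((a,a),(c,d));",  # duplicate label
            "",  # empty
            "   ",
            "((a,b),(c,d),(e,f),(g,h));",  # degree-4 node
            "(a,b);",  # too few leaves
            "((a,b)",  # unbalanced
        ],
    )
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_canonical_string_is_fixed(self):
        assert write_newick(parse_newick(QUARTET)) == "(a,b,(c,d));"

    def test_isomorphic_trees_serialize_identically(self):
        variants = ["((a,b),(c,d));", "((d,c),(b,a));", "(c,(b,a),d);"]
        assert len({write_newick(parse_newick(v)) for v in variants}) == 1

    @given(st.integers(0, 10**6), st.integers(3, 12))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_newick_round_trip(self, seed, n):
        t = random_tree(default_labels(n), seed=seed)
        assert parse_newick(write_newick(t)) == t


class TestSplits:
    def test_quartet_split_counts(self):
        t = parse_newick(QUARTET)
        assert len(t.splits()) == 5
        nt = t.nontrivial_splits()
        assert nt == {Split.of("ab", "cd")}

    def test_caterpillar_six_leaves(self):
        t = parse_newick("(a,(b,(c,(d,(e,f)))));")
        assert len(t.splits()) == 9
        assert len(t.nontrivial_splits()) == 3

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_split_counts_formula(self, n):
        t = random_tree(default_labels(n), seed=n)
        assert len(t.splits()) == 2 * n - 3
        assert len(t.nontrivial_splits()) == n - 3

    def test_all_split_pairs_compatible(self):
        t = random_tree(default_labels(9), seed=7)
        for s1, s2 in itertools.combinations(t.splits(), 2):
            assert splits_compatible(s1, s2)

    def test_canonical_orientation(self):
        s = Split.of("cde", "ab")
        assert s.side_a == frozenset("ab")
        assert s.size == 2 and not s.is_trivial
        tie = Split.of("cd", "ab")
        assert tie.side_a == frozenset("ab")  # tie broken by smallest label


class TestTreeFromSplits:
    def test_quartet_reconstruction(self):
        t = parse_newick(QUARTET)
        assert tree_from_splits(t.splits()) == t

    def test_round_trip_exhaustive_five_leaves(self, catalog5):
        for t in catalog5:
            assert tree_from_splits(t.splits()) == t

    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_round_trip_random_ten_leaves(self, seed):
        t = random_tree(default_labels(10), seed=seed)
        assert tree_from_splits(t.splits()) == t

    def test_incompatible_pair_rejected(self):
        with pytest.raises(TreeError):
            tree_from_splits({Split.of("ab", "cd"), Split.of("ac", "bd")})

    def test_complete_but_incompatible_set_rejected(self):
        t = parse_newick("(a,(b,(c,(d,e))));")
        broken = set(t.splits())
        broken.remove(Split.of("de", "abc"))
        broken.add(Split.of("ae", "bcd"))  # incompatible with ab|cde
        with pytest.raises(TreeError):
            tree_from_splits(broken)


class TestRFDistance:
    def test_identity_and_quartet(self):
        t = parse_newick(QUARTET)
        r = parse_newick("((a,c),(b,d));")
        assert rf_distance(t, t) == 0
        assert rf_distance(t, r) == 2

    def test_leaf_set_mismatch_is_an_error(self):
        with pytest.raises(LeafSetMismatchError):
            rf_distance(parse_newick(QUARTET), parse_newick("((a,b),(c,e));"))

    def test_agrees_with_isomorphism_exhaustively(self, catalog5):
        for t, r in itertools.product(catalog5, repeat=2):
            assert (rf_distance(t, r) == 0) == is_isomorphic(t, r)

    def test_metric_properties_sampled_six_leaves(self, catalog6):
        rng = random.Random(0)
        trees = catalog6.trees
        for _ in range(2000):
            a, b, c = (trees[rng.randrange(len(trees))] for _ in range(3))
            dab, dba = rf_distance(a, b), rf_distance(b, a)
            assert dab == dba
            assert dab % 2 == 0
            assert 0 <= dab <= max_rf_distance(6)
            assert rf_distance(a, c) <= dab + rf_distance(b, c)

    def test_maximum_attained_iff_no_shared_nontrivial_split(self, catalog6):
        seen_max = False
        for t, r in itertools.combinations(catalog6.trees, 2):
            at_max = rf_distance(t, r) == 6
            no_shared = not (t.nontrivial_splits() & r.nontrivial_splits())
            assert at_max == no_shared
            seen_max = seen_max or at_max
        assert seen_max


class TestSurgery:
    def test_collapse_quartet_to_star(self):
        t = parse_newick(QUARTET)
        s = Split.of("ab", "cd")
        c = collapse_side(t, s, "a", "x")
        assert c.leaf_set == frozenset({"x", "c", "d"})
        assert c.n_leaves == 3

    def test_collapse_then_expand_is_identity(self):
        t = parse_newick("(((a,b),(c,d)),(e,(f,g)));")
        for s in t.nontrivial_splits():
            for side in ("a", "b"):
                fresh = fresh_label(t.leaf_set)
                c = collapse_side(t, s, side, fresh)
                collapsed = s.side_a if side == "a" else s.side_b
                assert c.n_leaves == t.n_leaves - len(collapsed) + 1
                sub = induced_subtree(t, collapsed)
                assert expand_leaf(c, fresh, sub) == t

    def test_expand_preserves_rf_distance(self, catalog5):
        donor = parse_newick("(((p,q),r),(s,(t,u)));")
        sub = induced_subtree(donor, frozenset("pqr"))
        expanded = [expand_leaf(t, "a", sub) for t in catalog5]
        for (t1, e1), (t2, e2) in itertools.combinations(
            zip(catalog5.trees, expanded), 2
        ):
            assert rf_distance(e1, e2) == rf_distance(t1, t2)

    def test_expand_by_single_leaf_is_relabeling(self):
        t = parse_newick(QUARTET)
        sub = induced_subtree(parse_newick("((z,p),(q,r));"), frozenset("z"))
        e = expand_leaf(t, "a", sub)
        assert e.leaf_set == frozenset("zbcd")
        assert rf_distance(e, parse_newick("((z,b),(c,d));")) == 0

    def test_expand_label_collision_rejected(self):
        t = parse_newick(QUARTET)
        sub = induced_subtree(parse_newick("((b,p),(q,r));"), frozenset({"b", "p"}))
        with pytest.raises(TreeError):
            expand_leaf(t, "a", sub)

    def test_induced_subtree_cherry_and_single_leaf(self):
        t = parse_newick("(((a,b),(c,d)),(e,(f,g)));")
        cherry = induced_subtree(t, frozenset("ab"))
        assert cherry.n_leaves == 2 and len(cherry.adj[cherry.handle]) == 2
        single = induced_subtree(t, frozenset("e"))
        assert single.n_leaves == 1 and single.handle in single.leaf_label

    def test_induced_subtree_restricts_nested_splits(self):
        t = parse_newick("(((a,b),(c,d)),(e,(f,g)));")
        A = frozenset("abcd")
        sub = induced_subtree(t, A)
        host = parse_newick("((x,y),(z,w));")
        placed = expand_leaf(host, "x", sub)
        inside = {
            s.side_a if s.side_a <= A else s.side_b
            for s in placed.nontrivial_splits()
            if (s.side_a <= A or s.side_b <= A) and
               1 < len(s.side_a if s.side_a <= A else s.side_b) < len(A)
        }
        expected = {
            side
            for s in t.nontrivial_splits()
            for side in (s.side_a, s.side_b)
            if side < A and len(side) > 1
        }
        assert inside == expected

    def test_induced_subtree_rejects_non_clade(self):
        t = parse_newick("(((a,b),(c,d)),(e,(f,g)));")
        with pytest.raises(TreeError):
            induced_subtree(t, frozenset("ad"))
        with pytest.raises(TreeError):
            induced_subtree(t, t.leaf_set)
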