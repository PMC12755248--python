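"""The two path constructions and the path validator."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from rfwalk import (
    NNIMove,
    SPRMove,
    TreeError,
    cherry_walk,
    default_labels,
    is_nni_adjacent,
    max_rf_distance,
    nni_monotone_path,
    parse_newick,
    random_tree,
    rf_distance,
    shared_split_recursion,
    spr_strict_path,
    spr_strict_step,
    validate_path,
    validate_tree_sequence,
)
from rfwalk.paths import NNI_MONOTONE, SPR_STRICT, _leaf_path


class TestMonotoneNNIPath:
    def test_isomorphic_trees_give_singleton_path(self):
        t = parse_newick("(((a,b),c),(d,(e,f)));")
        p = nni_monotone_path(t, parse_newick("((e,f),d,(c,(b,a)));"))
        assert len(p) == 0 and p.rf_profile == [0]

    def test_distinct_quartets_one_move(self, catalog4):
        for t, r in itertools.permutations(catalog4.trees, 2):
            p = nni_monotone_path(t, r)
            assert len(p) == 1
            assert validate_path(p).ok

    def test_exhaustive_five_leaves(self, catalog5):
        for t, r in itertools.permutations(catalog5.trees, 2):
            p = nni_monotone_path(t, r)
            rep = validate_path(p)
            assert rep.ok, rep.message()

    @given(st.integers(0, 10**6), st.integers(4, 8))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_random_pairs_validate(self, seed, n):
        rng = random.Random(seed)
        labels = default_labels(n)
        t = random_tree(labels, rng=rng)
        r = random_tree(labels, rng=rng)
        p = nni_monotone_path(t, r)
        rep = validate_path(p)
        assert rep.ok, rep.message()
        assert p.trees[0] == t and p.trees[-1] == r

    def test_shared_splits_preserved_along_both_path_kinds(self, catalog6):
        rng = random.Random(3)
        trees = catalog6.trees
        for _ in range(60):
            t, r = rng.sample(trees, 2)
            shared = t.nontrivial_splits() & r.nontrivial_splits()
            for p in (nni_monotone_path(t, r), spr_strict_path(t, r)):
                for tree in p.trees:
                    assert shared <= tree.splits()


class TestSharedSplitRecursion:
    def test_requires_a_shared_nontrivial_split(self):
        t = parse_newick("((a,b),(c,d));")
        r = parse_newick("((a,c),(b,d));")
        with pytest.raises(TreeError):
            shared_split_recursion(t, r, next(iter(t.nontrivial_splits())))

    def test_identical_trees_trivial_path(self):
        t = parse_newick("(((a,b),c),(d,(e,f)));")
        s = next(iter(t.nontrivial_splits()))
        p = shared_split_recursion(t, t, s)
        assert len(p) == 0

    def test_path_confined_to_the_differing_side(self):
        # same structure on {e,f,g}, different arrangement of {a,b,c,d}
        t = parse_newick("(((a,b),(c,d)),(e,(f,g)));")
        r = parse_newick("(((a,c),(b,d)),(e,(f,g)));")
        shared = t.nontrivial_splits() & r.nontrivial_splits()
        s = next(s for s in shared if s.has_side(frozenset("abcd")))
        p = shared_split_recursion(t, r, s)
        rep = validate_path(p)
        assert rep.ok, rep.message()
        b_side_splits = {
            sp for sp in t.splits()
            if sp.side_a <= frozenset("efg") or sp.side_b <= frozenset("efg")
        }
        for tree in p.trees:
            assert b_side_splits <= tree.splits()

    def test_no_fresh_labels_leak_into_the_path(self, catalog6):
        rng = random.Random(5)
        for _ in range(20):
            t, r = rng.sample(catalog6.trees, 2)
            p = nni_monotone_path(t, r)
            for tree in p.trees:
                assert tree.leaf_set == t.leaf_set


class TestCherryWalk:
    def _max_rf_pairs(self, catalog, k, seed=1):
        rng = random.Random(seed)
        pairs = [
            (t, r)
            for t, r in itertools.permutations(catalog.trees, 2)
            if rf_distance(t, r) == max_rf_distance(6)
        ]
        return rng.sample(pairs, k)

    def test_rejects_trees_sharing_a_split(self):
        t = parse_newick("(((a,b),c),(d,(e,f)));")
        with pytest.raises(TreeError):
            cherry_walk(t, t)

    def test_profile_flat_then_drops(self, catalog6):
        for t, r in self._max_rf_pairs(catalog6, 40):
            tip, prefix = cherry_walk(t, r)
            prof = prefix.rf_profile  # measured to r, not to the tip
            assert all(d == max_rf_distance(6) for d in prof[:-1])
            assert prof[-1] < max_rf_distance(6)
            assert tip == prefix.trees[-1]

    def test_terminates_within_the_cherry_formation_bound(self, catalog6):
        for t, r in self._max_rf_pairs(catalog6, 40, seed=2):
            tip, prefix = cherry_walk(t, r)
            from rfwalk.paths import _cherries

            c1, c2 = _cherries(r)[0]
            start_len = len(_leaf_path(t, c1, c2)) - 1  # edges
            assert len(prefix) <= start_len - 2
            for a, b in zip(prefix.trees, prefix.trees[1:]):
                assert is_nni_adjacent(a, b)


class TestStrictSPRPath:
    def test_isomorphic_trees_give_singleton_path(self):
        t = parse_newick("(((a,b),c),(d,(e,f)));")
        p = spr_strict_path(t, t)
        assert len(p) == 0 and p.rf_profile == [0]

    def test_one_leaf_relocation_converges_in_one_step(self):
        current = parse_newick("((a,b),c,(d,e));")
        target = parse_newick("((a,c),b,(d,e));")
        move, nxt = spr_strict_step(current, target)
        assert nxt == target
        assert rf_distance(current, target) - rf_distance(nxt, target) == 2

    def test_max_rf_caterpillar_pair_first_step_strict(self):
        t = parse_newick("(a,(b,(c,(d,(e,f)))));")
        r = parse_newick("(b,(c,(d,(e,(f,a)))));")
        assert rf_distance(t, r) == max_rf_distance(6)
        p = spr_strict_path(t, r)
        assert 1 <= len(p) <= rf_distance(t, r) // 2
        assert p.rf_profile[1] < p.rf_profile[0]

    def test_a_single_step_can_drop_rf_by_more_than_two(self):
        rng = random.Random(9)
        labels = default_labels(8)
        found = False
        for _ in range(200):
            t = random_tree(labels, rng=rng)
            r = random_tree(labels, rng=rng)
            if t == r:
                continue
            _, nxt = spr_strict_step(t, r)
            if rf_distance(t, r) - rf_distance(nxt, r) >= 4:
                found = True
                break
        assert found, "no step resolving several splits at once found"

    def test_exhaustive_five_leaves(self, catalog5):
        for t, r in itertools.permutations(catalog5.trees, 2):
            p = spr_strict_path(t, r)
            rep = validate_path(p, check_neighborhoods=True)
            assert rep.ok, rep.message()
            assert len(p) <= rf_distance(t, r) // 2

    @given(st.integers(0, 10**6), st.sampled_from([6, 10, 20, 50]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_random_pairs_validate(self, seed, n):
        rng = random.Random(seed)
        labels = default_labels(n)
        t = random_tree(labels, rng=rng)
        r = random_tree(labels, rng=rng)
        p = spr_strict_path(t, r)
        rep = validate_path(p)
        assert rep.ok, rep.message()
        assert len(p) <= rf_distance(t, r) // 2


class TestValidator:
    def test_mutated_path_fails_at_the_right_index(self, catalog6):
        rng = random.Random(4)
        while True:
            t, r = rng.sample(catalog6.trees, 2)
            p = nni_monotone_path(t, r)
            if len(p) >= 2:
                break
        k = len(p.trees) // 2
        intruder = next(
            x for x in catalog6.trees if x not in (p.trees[k - 1], p.trees[k])
        )
        p.trees[k] = intruder
        rep = validate_path(p)
        assert not rep.ok
        assert rep.first_bad_index == k - 1

    def test_spr_path_under_nni_criterion_fails_adjacency_only(self):
        t = parse_newick("(a,(b,(c,(d,(e,f)))));")
        r = parse_newick("(b,(c,(d,(e,(f,a)))));")
        p = spr_strict_path(t, r)
        assert any(
            rf_distance(a, b) > 2 for a, b in zip(p.trees, p.trees[1:])
        ), "need a genuinely non-NNI SPR step for this check"
        rep = validate_path(p, mode=NNI_MONOTONE)
        assert not rep.ok
        assert all("NNI-adjacent" in msg for _, msg in rep.failures)

    def test_bare_sequence_validation_round_trip(self, catalog6):
        rng = random.Random(6)
        t, r = rng.sample(catalog6.trees, 2)
        nni_seq = nni_monotone_path(t, r).trees
        assert validate_tree_sequence(nni_seq, NNI_MONOTONE).ok
        spr_seq = spr_strict_path(t, r).trees
        assert validate_tree_sequence(spr_seq, SPR_STRICT).ok
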