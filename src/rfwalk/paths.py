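"""Constructive treespace paths with decreasing Robinson-Foulds distance.

Two constructions are provided for any pair of unrooted binary trees on the
same leaf set:

* :func:`nni_monotone_path` — a path in the NNI graph along which the RF
  distance to the target never increases.  Built by induction: if the trees
  share a non-trivial split, collapse each side of it in turn, recurse on the
  smaller trees, lift the two sub-paths back by re-expanding the collapsed
  subtrees, and concatenate; if they share none (maximum RF distance), walk a
  cherry of the target together with NNI moves until the distance first drops,
  then recurse.  Plateaus (equal consecutive RF values) can be unavoidable:
  there are tree pairs with no strictly decreasing NNI path (see
  :func:`rfwalk.spaces.find_nni_counterexamples`).

* :func:`spr_strict_path` — a path in the SPR graph along which the RF
  distance to the target strictly decreases (by at least 2) at every step.
  Each step picks a minimum-size non-trivial split A|B of the target missing
  from the current tree; minimality forces the two target clades A1, A2 with
  A1 ∪ A2 = A to be pendant in the current tree, and pruning the A1 subtree
  onto the edge above the A2 subtree creates A|B while only touching splits
  that were already in the symmetric difference.

Every SPR move is also a TBR move, so the strict SPR path doubles as a strict
TBR path (see :func:`rfwalk.moves.spr_move_as_tbr`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .moves import (
    SPRMove,
    apply_move,
    apply_spr,
    format_move,
    infer_nni_move,
    is_nni_adjacent,
    spr_neighbors,
)
from .trees import (
    LeafSetMismatchError,
    PendantSubtree,
    Split,
    Tree,
    TreeError,
    collapse_side,
    expand_leaf,
    fresh_label,
    induced_subtree,
    rf_distance,
)

__all__ = [
    "TreePath",
    "PathReport",
    "nni_monotone_path",
    "shared_split_recursion",
    "cherry_walk",
    "spr_strict_path",
    "spr_strict_step",
    "validate_path",
    "validate_tree_sequence",
]

NNI_MONOTONE = "nni_monotone"
SPR_STRICT = "spr_strict"


@dataclass
class TreePath:
    """A walk in a rearrangement graph with its moves and RF profile.

    ``trees[i+1]`` is ``moves[i]`` applied to ``trees[i]``.  ``rf_profile``
    lists the RF distance of every tree on the path to the path's target
    (by default its final tree).
    """

    trees: list
    moves: list
    mode: str
    target: Optional[Tree] = None

    @property
    def rf_profile(self) -> list:
        tgt = self.target if self.target is not None else self.trees[-1]
        return [rf_distance(t, tgt) for t in self.trees]

    def __len__(self) -> int:
        """Number of moves (path length in the rearrangement graph)."""
        return len(self.moves)

    def as_newick_lines(self) -> list:
        return [t.newick() for t in self.trees]

    def provenance_table(self) -> list:
        """Rows (step, move text, rf-to-target); step 0 has no move."""
        prof = self.rf_profile
        rows = [(0, "-", prof[0])]
        rows += [
            (i + 1, format_move(m), prof[i + 1]) for i, m in enumerate(self.moves)
        ]
        return rows


@dataclass
class PathReport:
    """Structured result of path validation."""

    ok: bool
    failures: list = field(default_factory=list)  # (index, message)

    @property
    def first_bad_index(self) -> Optional[int]:
        return min((i for i, _ in self.failures), default=None)

    def message(self) -> str:
        if self.ok:
            return "path valid"
        i, msg = sorted(self.failures)[0]
        return f"invalid at step {i}: {msg}"


# ---------------------------------------------------------------------------
# Monotone NNI path
# ---------------------------------------------------------------------------


def _check_same_leaves(t: Tree, r: Tree) -> None:
    if t.leaf_set != r.leaf_set:
        raise LeafSetMismatchError(
            f"leaf sets differ: {sorted(t.leaf_set ^ r.leaf_set)}"
        )


def _pick_shared_split(t: Tree, r: Tree) -> Optional[Split]:
    shared = t.nontrivial_splits() & r.nontrivial_splits()
    if not shared:
        return None
    return min(shared, key=Split.sort_key)


def _nni_sequence(t: Tree, r: Tree) -> list:
    """Tree sequence of a monotone NNI path from t to r (inclusive)."""
    if t == r:
        return [t]
    s = _pick_shared_split(t, r)
    if s is not None:
        return _shared_split_sequence(t, r, s)
    walk = _cherry_walk_sequence(t, r)
    return walk[:-1] + _nni_sequence(walk[-1], r)


def _shared_split_sequence(t: Tree, r: Tree, s: Split) -> list:
    """Recurse on both sides of a shared split and concatenate the lifts."""
    A, B = s.side_a, s.side_b
    X = t.leaf_set
    a = fresh_label(X, "a")
    b = fresh_label(X | {a}, "b")

    # collapse side A in both trees, solve the smaller instance, lift back
    # by re-expanding with the *source* tree's A subtree
    tA = collapse_side(t, s, A, a)
    rA = collapse_side(r, s, A, a)
    seq_a = _nni_sequence(tA, rA)
    sub_t_A = induced_subtree(t, A)
    lifted_a = [expand_leaf(x, a, sub_t_A) for x in seq_a]

    # same on side B, lifting with the *target* tree's B subtree
    tB = collapse_side(t, s, B, b)
    rB = collapse_side(r, s, B, b)
    seq_b = _nni_sequence(tB, rB)
    sub_r_B = induced_subtree(r, B)
    lifted_b = [expand_leaf(x, b, sub_r_B) for x in seq_b]

    if lifted_a[0] != t or lifted_b[-1] != r:
        raise RuntimeError("lifted path endpoints do not match the inputs")
    if lifted_a[-1] != lifted_b[0]:
        raise RuntimeError(
            "junction trees of the two lifted paths are not isomorphic"
        )
    # canonicalize endpoints/junction to single objects
    lifted_a[0] = t
    lifted_b[-1] = r
    lifted_b[0] = lifted_a[-1]
    return lifted_a + lifted_b[1:]


def _leaf_path(t: Tree, c1: str, c2: str) -> list:
    """Node path from leaf c1 to leaf c2."""
    adj = t.adjacency()
    start, goal = t.node_of(c1), t.node_of(c2)
    parent = {start: None}
    stack = [start]
    while stack:
        v = stack.pop()
        if v == goal:
            break
        for u in adj[v]:
            if u not in parent:
                parent[u] = v
                stack.append(u)
    path = [goal]
    while path[-1] != start:
        path.append(parent[path[-1]])
    return path[::-1]


def _cherries(t: Tree) -> list:
    """All cherries of t as sorted label pairs."""
    adj = t.adjacency()
    labels = t.leaf_labels()
    out = set()
    for v in adj:
        if v in labels:
            continue
        leaves = sorted(labels[u] for u in adj[v] if u in labels)
        if len(leaves) == 2:
            out.add(tuple(leaves))
    return sorted(out)


def _cherry_walk_sequence(t: Tree, r: Tree) -> list:
    """Walk a target cherry together until the RF distance first drops.

    Preconditions: t and r share no non-trivial split, so their RF distance
    is at the maximum 2(n-3).  Picks the lexicographically smallest cherry
    (c1, c2) of r and repeatedly applies the NNI move on the second edge of
    the current c1-to-c2 path that exchanges the c2-side component with c1's
    sibling subtree, shortening the path by one edge.  Stops at the first
    tree strictly closer to r; that happens at the latest when the cherry is
    formed.
    """
    if t.nontrivial_splits() & r.nontrivial_splits():
        raise TreeError("cherry walk requires trees sharing no non-trivial split")
    start_rf = rf_distance(t, r)
    c1, c2 = _cherries(r)[0]
    seq = [t]
    current = t
    while rf_distance(current, r) >= start_rf:
        node_path = _leaf_path(current, c1, c2)
        # node_path[0] is the c1 leaf; with no shared split the cherry cannot
        # be present yet on the first iteration, so the path has >= 4 nodes
        if len(node_path) == 3:
            raise RuntimeError("cherry formed without the RF distance dropping")
        c1_node, p1, p2, nxt = node_path[0], node_path[1], node_path[2], node_path[3]
        adj = current.adjacency()
        sibling = next(x for x in adj[p1] if x not in (c1_node, p2))
        toward_c2 = nxt
        # NNI across edge (p1, p2): swap c1's sibling with the c2-side subtree
        adj[p1].discard(sibling)
        adj[sibling].discard(p1)
        adj[p2].discard(toward_c2)
        adj[toward_c2].discard(p2)
        adj[p1].add(toward_c2)
        adj[toward_c2].add(p1)
        adj[p2].add(sibling)
        adj[sibling].add(p2)
        current = Tree(adj, current.leaf_labels())
        seq.append(current)
    return seq


def _moves_for_nni_sequence(seq: list) -> list:
    return [infer_nni_move(seq[i], seq[i + 1]) for i in range(len(seq) - 1)]


def nni_monotone_path(t: Tree, r: Tree) -> TreePath:
    """A path from ``t`` to ``r`` in the NNI graph, RF-monotone to ``r``.

    Every consecutive pair is NNI-adjacent and the RF distance to ``r``
    never increases along the path (it may plateau, which for some pairs is
    unavoidable).  Isomorphic inputs give a single-tree path; distinct
    4-leaf trees give a single move.
    """
    _check_same_leaves(t, r)
    seq = _nni_sequence(t, r)
    return TreePath(
        trees=seq, moves=_moves_for_nni_sequence(seq), mode=NNI_MONOTONE, target=r
    )


def shared_split_recursion(t: Tree, r: Tree, s: Split) -> TreePath:
    """Monotone NNI path built by recursing on the shared split ``s``.

    ``s`` must be a non-trivial split of both trees.  Every split shared by
    ``t`` and ``r`` — in particular ``s`` — is present in every tree on the
    returned path: the construction only ever rearranges within one side of
    the shared split at a time.
    """
    _check_same_leaves(t, r)
    if s.is_trivial:
        raise TreeError("shared split must be non-trivial")
    if s not in t.splits() or s not in r.splits():
        raise TreeError(f"{s} is not a split of both trees")
    seq = [t] if t == r else _shared_split_sequence(t, r, s)
    return TreePath(
        trees=seq, moves=_moves_for_nni_sequence(seq), mode=NNI_MONOTONE, target=r
    )


def cherry_walk(t: Tree, r: Tree) -> tuple:
    """Case for trees sharing no split: returns (first closer tree, prefix).

    The prefix is a :class:`TreePath` from ``t`` to the first tree whose RF
    distance to ``r`` is strictly below the starting maximum; its profile
    (measured to ``r``) is flat at the maximum and drops only at the end.
    """
    _check_same_leaves(t, r)
    seq = _cherry_walk_sequence(t, r)
    prefix = TreePath(
        trees=seq, moves=_moves_for_nni_sequence(seq), mode=NNI_MONOTONE, target=r
    )
    return seq[-1], prefix


# ---------------------------------------------------------------------------
# Strict SPR path
# ---------------------------------------------------------------------------


def spr_strict_step(current: Tree, target: Tree) -> tuple:
    """One SPR move toward ``target`` that strictly lowers the RF distance.

    Chooses the minimum-size non-trivial split A|B of ``target`` absent from
    ``current`` (ties broken lexicographically).  In ``target`` the A-side
    subtree splits into pendant clades A1 and A2; by minimality both are
    pendant in ``current`` as well.  The smaller of the two is pruned and
    regrafted onto the edge above the other, creating the split A|B.  Returns
    ``(move, next_tree)``.
    """
    missing = sorted(
        target.nontrivial_splits() - current.nontrivial_splits(), key=Split.sort_key
    )
    if not missing:
        raise TreeError("trees are already isomorphic")
    s = missing[0]
    A = s.side_a  # the minimum-size side
    u, v = target.edge_of_split(s)  # u on A's component in target
    stub_nbr = v
    children = [x for x in target.adjacency()[u] if x != stub_nbr]
    clades = sorted(
        (target.component_leaf_set(u, x) for x in children),
        key=lambda c: (len(c), tuple(sorted(c))),
    )
    pruned, kept = clades[0], clades[1]
    for clade in (pruned, kept):
        if len(clade) > 1 and not current.has_clade(clade):
            raise RuntimeError(
                f"clade {sorted(clade)} not pendant in the current tree; "
                "minimality invariant broken"
            )
    rest = current.leaf_set - pruned - kept
    move = SPRMove(pruned_clade=pruned, regraft_split=Split.of(kept, rest))
    nxt = apply_spr(current, move)
    if s not in nxt.splits():
        raise RuntimeError("SPR step failed to create the selected split")
    if rf_distance(nxt, target) >= rf_distance(current, target):
        raise RuntimeError("SPR step did not lower the RF distance")
    return move, nxt


def spr_strict_path(t: Tree, r: Tree) -> TreePath:
    """A path from ``t`` to ``r`` in the SPR graph, strictly RF-decreasing.

    Each step lowers the RF distance to ``r`` by at least 2, so the length
    is at most dRF(t, r) / 2.  Isomorphic inputs give a single-tree path.
    """
    _check_same_leaves(t, r)
    trees = [t]
    moves = []
    current = t
    while current != r:
        move, current = spr_strict_step(current, r)
        trees.append(current)
        moves.append(move)
    return TreePath(trees=trees, moves=moves, mode=SPR_STRICT, target=r)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _profile_failures(profile: list, mode: str) -> list:
    out = []
    if profile[-1] != 0:
        out.append((len(profile) - 1, f"final RF distance is {profile[-1]}, not 0"))
    for i in range(len(profile) - 1):
        if mode == NNI_MONOTONE and profile[i + 1] > profile[i]:
            out.append((i, f"RF profile increases: {profile[i]} -> {profile[i + 1]}"))
        if mode == SPR_STRICT and profile[i + 1] > profile[i] - 2:
            out.append(
                (i, f"RF profile not strictly decreasing by >= 2: "
                    f"{profile[i]} -> {profile[i + 1]}")
            )
    return out


def validate_path(p: TreePath, mode: Optional[str] = None,
                  check_neighborhoods: bool = False) -> PathReport:
    """Check every invariant of a :class:`TreePath`.

    Verifies that each recorded move reproduces the next tree, that
    consecutive trees are distinct and adjacent in the required graph (NNI
    adjacency for mode ``nni_monotone``; a valid SPR application — optionally
    full neighborhood membership — for ``spr_strict``), and that the RF
    profile to the final tree is monotone (weakly or strictly per mode) and
    ends at zero.  Failures are report entries, never exceptions.
    """
    mode = mode or p.mode
    failures = []
    if len(p.moves) != len(p.trees) - 1:
        failures.append((0, "move count does not match tree count"))
        return PathReport(ok=False, failures=failures)
    for i, m in enumerate(p.moves):
        t, nxt = p.trees[i], p.trees[i + 1]
        try:
            applied = apply_move(t, m)
        except TreeError as exc:
            failures.append((i, f"move does not apply: {exc}"))
            continue
        if applied != nxt:
            failures.append((i, "recorded move does not produce the next tree"))
        if t == nxt:
            failures.append((i, "consecutive trees are isomorphic"))
            continue
        if mode == NNI_MONOTONE and not is_nni_adjacent(t, nxt):
            failures.append((i, "consecutive trees are not NNI-adjacent"))
        if mode == SPR_STRICT and check_neighborhoods:
            if nxt not in spr_neighbors(t):
                failures.append((i, "next tree is not an SPR neighbor"))
    tgt = p.trees[-1]
    profile = [rf_distance(t, tgt) for t in p.trees]
    failures.extend(_profile_failures(profile, mode))
    return PathReport(ok=not failures, failures=failures)


def validate_tree_sequence(trees: list, mode: str) -> PathReport:
    """Validate a bare tree sequence (e.g. re-read from Newick lines).

    Without recorded moves, adjacency is checked directly against the
    rearrangement oracles: NNI adjacency for ``nni_monotone``, SPR
    neighborhood membership for ``spr_strict``.
    """
    failures = []
    if not trees:
        return PathReport(ok=False, failures=[(0, "empty path")])
    for i in range(len(trees) - 1):
        t, nxt = trees[i], trees[i + 1]
        if t == nxt:
            failures.append((i, "consecutive trees are isomorphic"))
            continue
        if mode == NNI_MONOTONE and not is_nni_adjacent(t, nxt):
            failures.append((i, "consecutive trees are not NNI-adjacent"))
        if mode == SPR_STRICT and nxt not in spr_neighbors(t):
            failures.append((i, "consecutive trees are not SPR-adjacent"))
    profile = [rf_distance(t, trees[-1]) for t in trees]
    failures.extend(_profile_failures(profile, mode))
    return PathReport(ok=not failures, failures=failures)
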