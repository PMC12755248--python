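"""NNI, SPR, and TBR rearrangement moves on unrooted binary trees.

Moves are declarative and identified by splits (not by internal node ids), so
they survive re-parsing and canonicalization of the trees they apply to.  The
three neighborhoods nest: every NNI move is an SPR move and every SPR move is
a TBR move.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .trees import (
    LeafSetMismatchError,
    Split,
    Tree,
    TreeError,
    UnsupportedSizeError,
    rf_distance,
)

__all__ = [
    "MoveError",
    "NNIMove",
    "SPRMove",
    "TBRMove",
    "apply_nni",
    "apply_spr",
    "apply_tbr",
    "apply_move",
    "nni_neighbors",
    "spr_neighbors",
    "tbr_neighbors",
    "is_nni_adjacent",
    "infer_nni_move",
    "spr_move_as_tbr",
    "format_move",
]


class MoveError(TreeError):
    """A move that cannot be applied to the given tree."""


@dataclass(frozen=True)
class NNIMove:
    """Nearest Neighbor Interchange across the internal edge inducing ``edge``.

    An internal edge has two subtrees hanging off each endpoint; holding one
    subtree on each side fixed, there are exactly two non-identity exchanges,
    selected by ``swap_choice`` (0 or 1).  The subtrees at each endpoint are
    ordered by their smallest leaf label, so the encoding is canonical.
    """

    edge: Split
    swap_choice: int


@dataclass(frozen=True)
class SPRMove:
    """Subtree Prune and Regraft.

    ``pruned_clade`` names the leaf set of the component that is pruned (it
    must be one side of a split of the source tree, leaving at least two
    leaves behind); ``regraft_split`` identifies the edge of the remaining
    component — as a split over the remaining leaf set — onto which the
    pruned component is reattached.
    """

    pruned_clade: frozenset
    regraft_split: Split


@dataclass(frozen=True)
class TBRMove:
    """Tree Bisection and Reconnection.

    ``bisect_split`` is the edge to remove.  ``reattach_a``/``reattach_b``
    identify an edge in the side_a / side_b component (as a split over that
    component's leaf set after suppressing the cut stub); ``None`` for a
    single-leaf component, whose reattach point is the leaf itself.
    """

    bisect_split: Split
    reattach_a: Optional[Split]
    reattach_b: Optional[Split]


# ---------------------------------------------------------------------------
# NNI
# ---------------------------------------------------------------------------


def _swap_subtrees(adj: dict, u: int, x: int, v: int, y: int) -> None:
    """Exchange subtree rooted at x (child of u) with subtree at y (child of v)."""
    adj[u].discard(x)
    adj[x].discard(u)
    adj[v].discard(y)
    adj[y].discard(v)
    adj[u].add(y)
    adj[y].add(u)
    adj[v].add(x)
    adj[x].add(v)


def apply_nni(t: Tree, m: NNIMove) -> Tree:
    """Apply an NNI move; the result differs from ``t`` in exactly one split."""
    if m.swap_choice not in (0, 1):
        raise MoveError(f"swap_choice must be 0 or 1, got {m.swap_choice}")
    if m.edge.is_trivial:
        raise MoveError("NNI edge must be internal (a non-trivial split)")
    try:
        u, v = t.edge_of_split(m.edge)
    except TreeError as exc:
        raise MoveError(str(exc)) from None
    u_subs = sorted(
        (x for x in t.adjacency()[u] if x != v),
        key=lambda x: min(t.component_leaf_set(u, x)),
    )
    v_subs = sorted(
        (y for y in t.adjacency()[v] if y != u),
        key=lambda y: min(t.component_leaf_set(v, y)),
    )
    adj = t.adjacency()
    _swap_subtrees(adj, u, u_subs[1], v, v_subs[m.swap_choice])
    return Tree(adj, t.leaf_labels())


def nni_neighbors(t: Tree) -> list:
    """All trees one NNI move from ``t``: exactly 2(n - 3) distinct trees."""
    if t.n_leaves < 4:
        return []
    out: dict = {}
    for e in sorted(t.nontrivial_splits(), key=Split.sort_key):
        for choice in (0, 1):
            nb = apply_nni(t, NNIMove(e, choice))
            out.setdefault(nb, nb)
    return list(out.values())


def is_nni_adjacent(t: Tree, r: Tree) -> bool:
    """True iff ``t`` and ``r`` are connected by a single NNI move.

    Uses the contraction characterization: the trees are NNI-adjacent iff
    there are edges e in t and f in r whose contraction yields isomorphic
    (non-binary) trees, i.e. Γ(t) - {e} = Γ(r) - {f}.  For binary trees on
    the same leaf set this holds exactly when |Γ(t) Δ Γ(r)| = 2.
    """
    if t.leaf_set != r.leaf_set:
        raise LeafSetMismatchError(
            f"leaf sets differ: {sorted(t.leaf_set ^ r.leaf_set)}"
        )
    return len(t.splits() ^ r.splits()) == 2


def infer_nni_move(t: Tree, r: Tree) -> NNIMove:
    """The NNI move turning ``t`` into ``r`` (the trees must be NNI-adjacent)."""
    diff = t.splits() - r.splits()
    if len(diff) != 1:
        raise MoveError("trees are not NNI-adjacent")
    e = next(iter(diff))
    for choice in (0, 1):
        m = NNIMove(e, choice)
        if apply_nni(t, m) == r:
            return m
    raise MoveError("trees are not NNI-adjacent")


# ---------------------------------------------------------------------------
# shared low-level helpers
# ---------------------------------------------------------------------------


def _component_nodes(adj: dict, start: int) -> set:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return seen


def _suppress_degree2(adj: dict, v: int) -> tuple:
    """Remove degree-2 node v, joining its neighbors; returns the new edge."""
    a, b = adj[v]
    adj[a].discard(v)
    adj[b].discard(v)
    adj[a].add(b)
    adj[b].add(a)
    del adj[v]
    return (a, b)


def _edge_splits_of_component(adj: dict, leaf_label: dict, nodes: set) -> dict:
    """Split (over the component's leaf set) -> edge (u, v) for every edge.

    Works on raw adjacency so it can serve components that are too small to
    be a valid :class:`Tree` (down to a single edge).
    """
    X = frozenset(leaf_label[v] for v in nodes if v in leaf_label)
    root = next(iter(nodes))
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u != parent[v]:
                parent[u] = v
                order.append(u)
                stack.append(u)
    below: dict = {}
    for v in reversed(order):
        if v in leaf_label:
            below[v] = frozenset((leaf_label[v],))
        else:
            below[v] = frozenset().union(
                *(below[u] for u in adj[v] if u != parent[v])
            )
    out = {}
    for v in order[1:]:
        L = below[v]
        out[Split.of(L, X - L)] = (parent[v], v)
    return out


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------


def _find_clade_split(t: Tree, clade: frozenset) -> Split:
    for s in t.splits():
        if s.has_side(clade):
            return s
    raise MoveError(f"{sorted(clade)} is not a clade of the tree")


def apply_spr(t: Tree, m: SPRMove) -> Tree:
    """Apply an SPR move.

    The split separating the pruned component from the rest is present in the
    result.  Regrafting onto the edge formed by suppressing the old attachment
    point recreates ``t``; that is a legal application but is excluded from
    :func:`spr_neighbors`.
    """
    P = frozenset(m.pruned_clade)
    X = t.leaf_set
    if len(X - P) < 2:
        raise MoveError("pruning must leave at least two leaves")
    s = _find_clade_split(t, P)
    u, v = t.edge_of_split(s)
    prune_root = u if s.side_a == P else v
    stub = v if prune_root == u else u
    adj = t.adjacency()
    leaf_label = t.leaf_labels()
    adj[prune_root].discard(stub)
    adj[stub].discard(prune_root)
    _suppress_degree2(adj, stub)
    remaining = _component_nodes(adj, t.node_of(min(X - P)))
    edge_splits = _edge_splits_of_component(adj, leaf_label, remaining)
    if m.regraft_split not in edge_splits:
        raise MoveError(
            f"regraft edge {m.regraft_split} is not an edge of the remaining component"
        )
    x, y = edge_splits[m.regraft_split]
    w = max(adj) + 1
    adj[x].discard(y)
    adj[y].discard(x)
    adj[w] = {x, y, prune_root}
    adj[x].add(w)
    adj[y].add(w)
    adj[prune_root].add(w)
    return Tree(adj, leaf_label)


def spr_neighbors(t: Tree) -> list:
    """All trees one SPR move from ``t`` (a superset of the NNI neighbors).

    Degenerate regrafts onto the edge adjacent to the original attachment —
    which recreate ``t`` — are excluded, as are duplicate results.
    """
    if t.n_leaves < 4:
        return []
    X = t.leaf_set
    out: dict = {}
    for s in sorted(t.splits(), key=Split.sort_key):
        for P in (s.side_a, s.side_b):
            if len(X - P) < 2:
                continue
            for m in _spr_moves_for_prune(t, P):
                nb = apply_spr(t, m)
                if nb != t:
                    out.setdefault(nb, nb)
    return list(out.values())


def _spr_moves_for_prune(t: Tree, P: frozenset) -> Iterable[SPRMove]:
    """All non-degenerate SPR moves pruning the clade ``P``."""
    s = _find_clade_split(t, P)
    u, v = t.edge_of_split(s)
    prune_root = u if s.side_a == P else v
    stub = v if prune_root == u else u
    adj = t.adjacency()
    leaf_label = t.leaf_labels()
    adj[prune_root].discard(stub)
    adj[stub].discard(prune_root)
    merged = _suppress_degree2(adj, stub)
    remaining = _component_nodes(adj, merged[0])
    edge_splits = _edge_splits_of_component(adj, leaf_label, remaining)
    merged_edge = frozenset(merged)
    for rs, (x, y) in edge_splits.items():
        if frozenset((x, y)) == merged_edge:
            continue  # regraft at the original attachment: recreates t
        yield SPRMove(pruned_clade=P, regraft_split=rs)


# ---------------------------------------------------------------------------
# TBR
# ---------------------------------------------------------------------------


def apply_tbr(t: Tree, m: TBRMove) -> Tree:
    """Apply a TBR move: bisect at an edge, reconnect via one edge per side.

    A single-leaf component has no edge; its reattach split is ``None`` and
    the new connecting edge meets the leaf itself.
    """
    try:
        u, v = t.edge_of_split(m.bisect_split)  # u on side_a's component
    except TreeError as exc:
        raise MoveError(str(exc)) from None
    adj = t.adjacency()
    leaf_label = t.leaf_labels()
    adj[u].discard(v)
    adj[v].discard(u)
    attach_points = []
    nxt = max(adj) + 1
    for side_root, reattach, side_leaves in (
        (u, m.reattach_a, m.bisect_split.side_a),
        (v, m.reattach_b, m.bisect_split.side_b),
    ):
        if len(side_leaves) == 1:
            if reattach is not None:
                raise MoveError("single-leaf component has no reattach edge")
            attach_points.append(side_root)
            continue
        _suppress_degree2(adj, side_root)
        nodes = _component_nodes(adj, t.node_of(min(side_leaves)))
        edge_splits = _edge_splits_of_component(adj, leaf_label, nodes)
        if reattach is None or reattach not in edge_splits:
            raise MoveError(
                f"reattach edge {reattach} is not an edge of its component"
            )
        x, y = edge_splits[reattach]
        w = nxt
        nxt += 1
        adj[x].discard(y)
        adj[y].discard(x)
        adj[w] = {x, y}
        adj[x].add(w)
        adj[y].add(w)
        attach_points.append(w)
    a, b = attach_points
    adj[a].add(b)
    adj[b].add(a)
    return Tree(adj, leaf_label)


def tbr_neighbors(t: Tree) -> list:
    """All trees one TBR move from ``t`` (a superset of the SPR neighbors)."""
    if t.n_leaves < 4:
        return []
    out: dict = {}
    leaf_label = t.leaf_labels()
    for s in sorted(t.splits(), key=Split.sort_key):
        u, v = t.edge_of_split(s)
        adj = t.adjacency()
        adj[u].discard(v)
        adj[v].discard(u)
        options = []
        for side_root, side_leaves in ((u, s.side_a), (v, s.side_b)):
            if len(side_leaves) == 1:
                options.append([None])
                continue
            side_adj = {w: set(nb) for w, nb in adj.items()}
            _suppress_degree2(side_adj, side_root)
            nodes = _component_nodes(
                side_adj, t.node_of(min(side_leaves))
            )
            options.append(
                list(_edge_splits_of_component(side_adj, leaf_label, nodes))
            )
        for ra in options[0]:
            for rb in options[1]:
                nb = apply_tbr(t, TBRMove(s, ra, rb))
                if nb != t:
                    out.setdefault(nb, nb)
    return list(out.values())


def spr_move_as_tbr(t: Tree, m: SPRMove) -> TBRMove:
    """Express an SPR move on ``t`` as the equivalent TBR move.

    The bisection edge is the prune edge; in the pruned component the
    reattach edge is the one formed by suppressing the old attachment point
    (so the component reconnects at the same spot), and in the other
    component it is the SPR regraft edge.
    """
    P = frozenset(m.pruned_clade)
    s = _find_clade_split(t, P)
    if len(P) == 1:
        inner = None
    else:
        u, v = t.edge_of_split(s)
        prune_root = u if s.side_a == P else v
        stub = v if prune_root == u else u
        # the two children of the prune root partition P
        child = next(x for x in t.adjacency()[prune_root] if x != stub)
        c1 = t.component_leaf_set(prune_root, child)
        inner = Split.of(c1, P - c1)
    if s.side_a == P:
        return TBRMove(bisect_split=s, reattach_a=inner, reattach_b=m.regraft_split)
    return TBRMove(bisect_split=s, reattach_a=m.regraft_split, reattach_b=inner)


# ---------------------------------------------------------------------------
# dispatch / serialization
# ---------------------------------------------------------------------------


def apply_move(t: Tree, m) -> Tree:
    if isinstance(m, NNIMove):
        return apply_nni(t, m)
    if isinstance(m, SPRMove):
        return apply_spr(t, m)
    if isinstance(m, TBRMove):
        return apply_tbr(t, m)
    raise MoveError(f"unknown move type: {type(m).__name__}")


def format_move(m) -> str:
    """One-line text form of a move (splits as 'a,b|c,d')."""
    if isinstance(m, NNIMove):
        return f"NNI edge={m.edge} choice={m.swap_choice}"
    if isinstance(m, SPRMove):
        return (
            f"SPR prune={','.join(sorted(m.pruned_clade))} "
            f"regraft={m.regraft_split}"
        )
    if isinstance(m, TBRMove):
        ra = m.reattach_a if m.reattach_a is not None else "-"
        rb = m.reattach_b if m.reattach_b is not None else "-"
        return f"TBR bisect={m.bisect_split} a={ra} b={rb}"
    raise MoveError(f"unknown move type: {type(m).__name__}")
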