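"""Exhaustive treespace machinery for small leaf sets.

Enumeration of all (2n-5)!! unrooted binary trees, BFS graph-distance
oracles in the NNI and SPR graphs, and the exhaustive search for tree pairs
admitting no strictly RF-decreasing NNI step — the counterexample showing
that monotone NNI paths sometimes must plateau.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Optional

from .moves import nni_neighbors, spr_neighbors
from .trees import (
    LeafSetMismatchError,
    Tree,
    UnsupportedSizeError,
    rf_distance,
)

__all__ = [
    "TreespaceCatalog",
    "default_labels",
    "n_unrooted_trees",
    "enumerate_trees",
    "graph_distance",
    "find_nni_counterexamples",
    "counterexample_report",
]

_MAX_ENUM_LEAVES = 9
_MAX_BFS_LEAVES = 7


def default_labels(n: int) -> tuple:
    """n leaf labels: letters a.. for n <= 26, else t01, t02, ..."""
    if n <= 26:
        return tuple(chr(ord("a") + i) for i in range(n))
    width = len(str(n))
    return tuple(f"t{i + 1:0{width}d}" for i in range(n))


def n_unrooted_trees(n: int) -> int:
    """(2n - 5)!!, the number of unrooted binary trees on n labeled leaves."""
    if n < 3:
        raise UnsupportedSizeError("defined for n >= 3")
    out = 1
    for k in range(2 * n - 5, 1, -2):
        out *= k
    return out


@dataclass
class TreespaceCatalog:
    """Every unrooted binary tree on a fixed label set, each exactly once."""

    labels: tuple
    trees: list

    def __post_init__(self):
        self._index = {t: i for i, t in enumerate(self.trees)}

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def index_of(self, t: Tree) -> int:
        try:
            return self._index[t]
        except KeyError:
            raise LeafSetMismatchError("tree is not in the catalog") from None


def enumerate_trees(labels: Iterable[str]) -> TreespaceCatalog:
    """All unrooted binary trees on ``labels`` by stepwise leaf insertion.

    Starting from the unique 3-leaf tree, each further leaf is attached to
    every edge of every tree; this generates each of the (2n-5)!! topologies
    exactly once.  Supported for 3 <= n <= 9.
    """
    labels = tuple(labels)
    n = len(labels)
    if not 3 <= n <= _MAX_ENUM_LEAVES:
        raise UnsupportedSizeError(
            f"enumeration supports 3..{_MAX_ENUM_LEAVES} leaves, got {n}"
        )
    # work on raw (adj, leaf_label) pairs; node 0.. fresh per tree
    star_adj = {0: {1, 2, 3}, 1: {0}, 2: {0}, 3: {0}}
    star_labels = {1: labels[0], 2: labels[1], 3: labels[2]}
    work = [(star_adj, star_labels)]
    for lab in labels[3:]:
        nxt_work = []
        for adj, leaf_label in work:
            edges = {frozenset((u, v)) for u in adj for v in adj[u]}
            for e in edges:
                u, v = sorted(e)
                new_adj = {w: set(nb) for w, nb in adj.items()}
                mid = max(new_adj) + 1
                leaf = mid + 1
                new_adj[u].discard(v)
                new_adj[v].discard(u)
                new_adj[mid] = {u, v, leaf}
                new_adj[u].add(mid)
                new_adj[v].add(mid)
                new_adj[leaf] = {mid}
                new_labels = dict(leaf_label)
                new_labels[leaf] = lab
                nxt_work.append((new_adj, new_labels))
        work = nxt_work
    trees = [Tree(adj, leaf_label) for adj, leaf_label in work]
    return TreespaceCatalog(labels=labels, trees=trees)


def graph_distance(t: Tree, r: Tree, move_kind: str = "nni") -> int:
    """BFS shortest-path length between ``t`` and ``r`` in the NNI/SPR graph.

    A deliberately small-scale oracle (n <= 7): the general problem is
    NP-hard, and this exists to sanity-check constructed paths, not to scale.
    """
    if t.leaf_set != r.leaf_set:
        raise LeafSetMismatchError(
            f"leaf sets differ: {sorted(t.leaf_set ^ r.leaf_set)}"
        )
    if t.n_leaves > _MAX_BFS_LEAVES:
        raise UnsupportedSizeError(
            f"BFS oracle supports up to {_MAX_BFS_LEAVES} leaves"
        )
    if move_kind == "nni":
        neighbors = nni_neighbors
    elif move_kind == "spr":
        neighbors = spr_neighbors
    else:
        raise ValueError(f"move_kind must be 'nni' or 'spr', got {move_kind!r}")
    if t == r:
        return 0
    seen = {t}
    frontier = deque([(t, 0)])
    while frontier:
        node, d = frontier.popleft()
        for nb in neighbors(node):
            if nb == r:
                return d + 1
            if nb not in seen:
                seen.add(nb)
                frontier.append((nb, d + 1))
    raise RuntimeError("rearrangement graph is connected; this cannot happen")


def find_nni_counterexamples(
    n: int, labels: Optional[Iterable[str]] = None
) -> list:
    """All ordered pairs (T, R) with no strictly RF-decreasing NNI step.

    Searches the full catalog on ``n`` leaves for pairs with dRF(T, R) > 0
    such that every NNI neighbor of T is at least as far from R as T is.
    Empty for n = 4; non-empty for n = 6, where each returned pair realizes
    the maximum distance 2(n-3) and certifies that strictly decreasing NNI
    paths do not exist in general.
    """
    if n > _MAX_BFS_LEAVES:
        raise UnsupportedSizeError(
            f"counterexample search supports up to {_MAX_BFS_LEAVES} leaves"
        )
    catalog = enumerate_trees(labels if labels is not None else default_labels(n))
    split_sets = [t.splits() for t in catalog.trees]
    neighbor_ids = [
        [catalog.index_of(nb) for nb in nni_neighbors(t)] for t in catalog.trees
    ]
    out = []
    m = len(catalog)
    for i in range(m):
        si = split_sets[i]
        for j in range(m):
            if i == j:
                continue
            d = len(si ^ split_sets[j])
            if d == 0:
                continue
            if all(
                len(split_sets[k] ^ split_sets[j]) >= d for k in neighbor_ids[i]
            ):
                out.append((catalog.trees[i], catalog.trees[j]))
    return out


def counterexample_report(pairs: list) -> list:
    """Rows (pair id, T newick, R newick, dRF, neighbor distances) for output."""
    rows = []
    for k, (t, r) in enumerate(pairs):
        nbr_d = sorted(rf_distance(nb, r) for nb in nni_neighbors(t))
        rows.append((k, t.newick(), r.newick(), rf_distance(t, r), nbr_d))
    return rows
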