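"""Unrooted binary phylogenetic trees, splits, and the Robinson-Foulds distance.

A tree here is a connected acyclic graph whose degree-1 nodes (leaves) are
bijectively labeled by a taxon set ``X`` and whose internal nodes all have
degree three.  Cutting any edge bipartitions ``X`` into a *split* ``A|B``; the
set of all splits uniquely identifies the tree, and the Robinson-Foulds (RF)
distance between two trees on the same taxon set is the size of the symmetric
difference of their split sets.

This module provides Newick I/O, split extraction, reconstruction of a tree
from a compatible split set, RF distance, leaf-label-preserving isomorphism,
and the collapse/expand subtree surgery used by the path-construction
algorithms in :mod:`rfwalk.paths`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "TreeError",
    "NewickError",
    "LeafSetMismatchError",
    "UnsupportedSizeError",
    "Split",
    "splits_compatible",
    "Tree",
    "PendantSubtree",
    "parse_newick",
    "write_newick",
    "splits",
    "tree_from_splits",
    "rf_distance",
    "max_rf_distance",
    "is_isomorphic",
    "collapse_side",
    "expand_leaf",
    "induced_subtree",
    "fresh_label",
]


class TreeError(ValueError):
    """Invalid tree, split, or operation on one."""


class NewickError(TreeError):
    """Malformed or unsupported Newick input."""


class LeafSetMismatchError(TreeError):
    """Two trees were expected to share a leaf-label set but do not."""


class UnsupportedSizeError(TreeError):
    """A leaf count outside the range an operation supports."""


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Split:
    """A bipartition ``A|B`` of a leaf-label set, canonically oriented.

    ``side_a`` is the smaller side; on ties the side containing the
    lexicographically smallest label.  The canonical orientation makes splits
    hashable and comparable across trees, which every tie-break in this
    package relies on.
    """

    side_a: frozenset
    side_b: frozenset

    @classmethod
    def of(cls, first: Iterable[str], second: Iterable[str]) -> "Split":
        a, b = frozenset(first), frozenset(second)
        if not a or not b:
            raise TreeError("both sides of a split must be non-empty")
        if a & b:
            raise TreeError(f"split sides overlap: {sorted(a & b)}")
        if (len(a), min(a)) > (len(b), min(b)):
            a, b = b, a
        return cls(a, b)

    @property
    def size(self) -> int:
        """min(|A|, |B|): the size of the split."""
        return len(self.side_a)

    @property
    def is_trivial(self) -> bool:
        return len(self.side_a) == 1

    @property
    def leaf_set(self) -> frozenset:
        return self.side_a | self.side_b

    def has_side(self, leaves: frozenset) -> bool:
        return self.side_a == leaves or self.side_b == leaves

    def sort_key(self) -> tuple:
        """Deterministic total order: by size, then lexicographic on side_a."""
        return (len(self.side_a), tuple(sorted(self.side_a)))

    def __str__(self) -> str:
        return f"{','.join(sorted(self.side_a))}|{','.join(sorted(self.side_b))}"


def splits_compatible(s: Split, t: Split) -> bool:
    """True iff the two splits (over the same leaf set) can coexist in a tree.

    Two splits are compatible iff at least one of the four pairwise side
    intersections is empty.
    """
    return (
        not (s.side_a & t.side_a)
        or not (s.side_a & t.side_b)
        or not (s.side_b & t.side_a)
        or not (s.side_b & t.side_b)
    )


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


class Tree:
    """Unrooted binary leaf-labeled tree.

    Internal representation is an adjacency dict over integer node ids plus a
    leaf-id -> label map.  Trees compare equal (and hash equal) iff their
    split sets are equal, i.e. iff they are isomorphic as leaf-labeled trees.
    Instances are treated as immutable; all operations return new trees.
    """

    __slots__ = (
        "_adj",
        "_leaf_label",
        "_label_node",
        "_splits",
        "_edge_of_split",
        "_split_of_edge",
        "_nontrivial",
        "_sides",
        "_newick",
    )

    def __init__(self, adj: dict, leaf_label: dict, _validated: bool = False):
        self._adj = {v: set(nbrs) for v, nbrs in adj.items()}
        self._leaf_label = dict(leaf_label)
        self._label_node = {lab: v for v, lab in self._leaf_label.items()}
        self._splits = None
        self._edge_of_split = None
        self._split_of_edge = None
        self._nontrivial = None
        self._sides = None
        self._newick = None
        if not _validated:
            self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        adj, leaf_label = self._adj, self._leaf_label
        if len(self._label_node) != len(leaf_label):
            dupes = sorted(
                {lab for lab in leaf_label.values()
                 if sum(1 for x in leaf_label.values() if x == lab) > 1}
            )
            raise TreeError(f"duplicate leaf labels: {dupes}")
        if any(not lab for lab in leaf_label.values()):
            raise TreeError("empty leaf label")
        n = len(leaf_label)
        if n < 3:
            raise UnsupportedSizeError(f"trees need at least 3 leaves, got {n}")
        for v, nbrs in adj.items():
            deg = len(nbrs)
            if v in leaf_label:
                if deg != 1:
                    raise TreeError(f"labeled leaf {leaf_label[v]!r} has degree {deg}")
            elif deg != 3:
                raise TreeError(
                    f"internal node of degree {deg}; tree is not binary"
                    if deg != 1
                    else "unlabeled degree-1 node"
                )
        if len(adj) != 2 * n - 2:
            raise TreeError(f"expected {2 * n - 2} nodes for {n} leaves, found {len(adj)}")
        # connectivity (acyclicity then follows from the node/edge count)
        seen = set()
        stack = [next(iter(adj))]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(adj[v] - seen)
        if len(seen) != len(adj):
            raise TreeError("tree graph is not connected")
        n_edges = sum(len(nbrs) for nbrs in adj.values()) // 2
        if n_edges != 2 * n - 3:
            raise TreeError(f"expected {2 * n - 3} edges, found {n_edges}")

    # -- basic accessors ----------------------------------------------------

    @property
    def leaf_set(self) -> frozenset:
        return frozenset(self._label_node)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_label)

    def node_of(self, label: str) -> int:
        try:
            return self._label_node[label]
        except KeyError:
            raise TreeError(f"no leaf labeled {label!r}") from None

    def adjacency(self) -> dict:
        """A copy of the adjacency structure (node id -> set of node ids)."""
        return {v: set(nbrs) for v, nbrs in self._adj.items()}

    def leaf_labels(self) -> dict:
        """A copy of the leaf-node-id -> label map."""
        return dict(self._leaf_label)

    # -- splits -------------------------------------------------------------

    def _ensure_splits(self) -> None:
        if self._splits is not None:
            return
        adj = self._adj
        X = self.leaf_set
        root = next(iter(adj))
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
            if v in self._leaf_label:
                below[v] = frozenset((self._leaf_label[v],))
            else:
                acc = frozenset()
                for u in adj[v]:
                    if u != parent[v]:
                        acc |= below[u]
                below[v] = acc
        edge_of_split: dict = {}
        split_of_edge: dict = {}
        for v in order[1:]:
            L = below[v]
            s = Split.of(L, X - L)
            u, w = (v, parent[v]) if s.side_a == L else (parent[v], v)
            edge_of_split[s] = (u, w)  # u lies on side_a's component
            split_of_edge[frozenset((v, parent[v]))] = s
        self._edge_of_split = edge_of_split
        self._split_of_edge = split_of_edge
        self._splits = frozenset(edge_of_split)

    def splits(self) -> frozenset:
        """The split set Γ(T): one canonical :class:`Split` per edge."""
        self._ensure_splits()
        return self._splits

    def nontrivial_splits(self) -> frozenset:
        if self._nontrivial is None:
            self._nontrivial = frozenset(s for s in self.splits() if not s.is_trivial)
        return self._nontrivial

    def edge_of_split(self, s: Split) -> tuple:
        """Endpoints (u, v) of the edge inducing ``s``; u on side_a's component."""
        self._ensure_splits()
        try:
            return self._edge_of_split[s]
        except KeyError:
            raise TreeError(f"split {s} is not a split of this tree") from None

    def split_of_edge(self, u: int, v: int) -> Split:
        self._ensure_splits()
        try:
            return self._split_of_edge[frozenset((u, v))]
        except KeyError:
            raise TreeError(f"({u}, {v}) is not an edge of this tree") from None

    def component_leaf_set(self, u: int, v: int) -> frozenset:
        """Leaf labels of the component containing ``v`` when edge u-v is cut."""
        s = self.split_of_edge(u, v)
        a, _ = self.edge_of_split(s)
        return s.side_a if a == v else s.side_b

    def has_clade(self, leaves: frozenset) -> bool:
        """True iff ``leaves`` is one side of some split (a pendant subtree)."""
        if self._sides is None:
            self._sides = {s.side_a for s in self.splits()} | {
                s.side_b for s in self.splits()
            }
        return frozenset(leaves) in self._sides

    # -- identity -----------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return self.splits() == other.splits()

    def __hash__(self) -> int:
        return hash(self.splits())

    def __repr__(self) -> str:
        return f"Tree({self.newick()!r})"

    # -- Newick -------------------------------------------------------------

    def newick(self) -> str:
        """Canonical Newick string; see :func:`write_newick`."""
        if self._newick is not None:
            return self._newick
        adj, leaf_label = self._adj, self._leaf_label
        first = min(self._label_node)
        leaf0 = self._label_node[first]
        root = next(iter(adj[leaf0]))  # internal node adjacent to smallest leaf
        # smallest descendant label per directed edge away from root
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
        minlab: dict = {}
        for v in reversed(order):
            if v in leaf_label:
                minlab[v] = leaf_label[v]
            else:
                minlab[v] = min(
                    minlab[u] for u in adj[v] if u != parent[v]
                )
        rendered: dict = {}
        for v in reversed(order):
            if v in leaf_label:
                rendered[v] = leaf_label[v]
            elif v != root:
                kids = sorted(
                    (u for u in adj[v] if u != parent[v]), key=lambda u: minlab[u]
                )
                rendered[v] = "(" + ",".join(rendered[u] for u in kids) + ")"
        top = sorted(adj[root], key=lambda u: minlab[u])
        self._newick = "(" + ",".join(rendered[u] for u in top) + ");"
        return self._newick


# ---------------------------------------------------------------------------
# Pendant subtrees (trees-with-handle)
# ---------------------------------------------------------------------------


@dataclass
class PendantSubtree:
    """A subtree cut off a tree, carrying its attachment point.

    ``handle`` is the node at which the subtree was (or will be) attached to
    the rest of a tree: for a single leaf the leaf itself, otherwise a
    degree-2 node whose two neighbors are the subtree's children.
    """

    adj: dict
    leaf_label: dict
    handle: int

    @property
    def leaf_set(self) -> frozenset:
        return frozenset(self.leaf_label.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into an unrooted binary :class:`Tree`.

    Branch lengths and internal node labels are accepted and discarded.  A
    top-level trifurcation is read as-is; a rooted bifurcation is unrooted by
    suppressing the root.  Any other non-binary structure is rejected.
    """
    if text is None or not text.strip():
        raise NewickError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except NewickError:
        raise
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"malformed Newick: {exc}") from None

    ids: dict = {}

    def nid(node) -> int:
        return ids.setdefault(id(node), len(ids))

    adj: dict = {}
    leaf_label: dict = {}
    for node in dtree.preorder_node_iter():
        v = nid(node)
        adj.setdefault(v, set())
        for child in node.child_nodes():
            u = nid(child)
            adj[v].add(u)
            adj.setdefault(u, set()).add(v)
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise NewickError("unlabeled leaf in Newick input")
            leaf_label[v] = node.taxon.label

    labels = list(leaf_label.values())
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickError(f"duplicate leaf labels: {dupes}")

    root = ids[id(dtree.seed_node)]
    if root not in leaf_label and len(adj[root]) == 2:
        u, w = adj[root]
        adj[u].discard(root)
        adj[w].discard(root)
        adj[u].add(w)
        adj[w].add(u)
        del adj[root]
    try:
        return Tree(adj, leaf_label)
    except NewickError:
        raise
    except TreeError as exc:
        raise NewickError(str(exc)) from None


def write_newick(t: Tree) -> str:
    """Canonical Newick serialization of ``t``.

    The tree is written as a trifurcation at the internal node adjacent to the
    lexicographically smallest leaf, siblings ordered by smallest descendant
    label, so isomorphic trees always serialize identically and
    ``parse_newick(write_newick(t)) == t``.
    """
    return t.newick()


def splits(t: Tree) -> frozenset:
    """The split set Γ(T) of ``t`` (|Γ(T)| = 2n - 3)."""
    return t.splits()


def tree_from_splits(split_set: Iterable[Split]) -> Tree:
    """Reconstruct the unique tree whose split set is ``split_set``.

    ``split_set`` must be the complete, pairwise compatible split set of a
    binary tree: 2n - 3 splits over a common leaf set, n of them trivial.
    Incompatible or incomplete input raises :class:`TreeError`.

    The construction starts from a star and resolves one non-trivial split at
    a time in order of increasing size; compatibility guarantees that at each
    step the leaves of the smaller side hang off a single node.
    """
    ss = list(split_set)
    if not ss:
        raise TreeError("empty split set")
    X = ss[0].leaf_set
    if any(s.leaf_set != X for s in ss):
        raise TreeError("splits are not over a common leaf set")
    n = len(X)
    if n < 3:
        raise UnsupportedSizeError(f"need at least 3 leaves, got {n}")
    if len(set(ss)) != len(ss):
        raise TreeError("duplicate splits")
    if len(ss) != 2 * n - 3:
        raise TreeError(f"expected {2 * n - 3} splits for {n} leaves, got {len(ss)}")
    trivial = [s for s in ss if s.is_trivial]
    if len(trivial) != n:
        raise TreeError("split set must contain every trivial split exactly once")
    nontrivial = sorted((s for s in ss if not s.is_trivial), key=Split.sort_key)
    for i, s in enumerate(nontrivial):
        for t2 in nontrivial[i + 1 :]:
            if not splits_compatible(s, t2):
                raise TreeError(f"incompatible splits: {s} vs {t2}")

    # star tree
    center = 0
    adj: dict = {center: set()}
    leaf_label: dict = {}
    nxt = 1
    for lab in sorted(X):
        adj[nxt] = {center}
        adj[center].add(nxt)
        leaf_label[nxt] = lab
        nxt += 1

    def component_sets(v: int) -> dict:
        """neighbor u of v -> leaf labels of u's component when v is removed."""
        out = {}
        for u in adj[v]:
            comp = set()
            seen = {v, u}
            stack = [u]
            while stack:
                w = stack.pop()
                if w in leaf_label:
                    comp.add(leaf_label[w])
                for x in adj[w]:
                    if x not in seen:
                        seen.add(x)
                        stack.append(x)
            out[u] = frozenset(comp)
        return out

    for s in nontrivial:
        A = s.side_a
        placed = False
        for v in list(adj):
            if v in leaf_label:
                continue
            comps = component_sets(v)
            inside = [u for u, c in comps.items() if c <= A]
            if inside and frozenset().union(*(comps[u] for u in inside)) == A:
                if len(inside) < 2:
                    raise TreeError(f"split {s} already resolved; duplicate structure")
                w = nxt
                nxt += 1
                adj[w] = {v}
                for u in inside:
                    adj[v].discard(u)
                    adj[u].discard(v)
                    adj[u].add(w)
                    adj[w].add(u)
                adj[v].add(w)
                placed = True
                break
        if not placed:
            raise TreeError(f"could not resolve split {s}; split set incompatible")
    try:
        result = Tree(adj, leaf_label)
    except TreeError as exc:
        raise TreeError(f"split set does not define a binary tree: {exc}") from None
    if result.splits() != frozenset(ss):
        raise TreeError("split set does not define a binary tree")
    return result


def rf_distance(t: Tree, r: Tree) -> int:
    """Robinson-Foulds distance |Γ(t) Δ Γ(r)|.

    Requires equal leaf sets.  Always even; 0 iff the trees are isomorphic;
    at most 2(n - 3).  Trivial splits are shared whenever leaf sets are equal,
    so the value coincides with the usual count over non-trivial splits.
    """
    if t.leaf_set != r.leaf_set:
        raise LeafSetMismatchError(
            f"leaf sets differ: {sorted(t.leaf_set ^ r.leaf_set)}"
        )
    return len(t.splits() ^ r.splits())


def max_rf_distance(n: int) -> int:
    """The maximum RF distance 2(n - 3) between binary trees on n leaves."""
    return 2 * (n - 3)


def is_isomorphic(t: Tree, r: Tree) -> bool:
    """Leaf-label-preserving isomorphism: equal leaf sets and Γ(t) = Γ(r)."""
    return t.splits() == r.splits()


def _resolve_side(s: Split, side) -> frozenset:
    if side == "a":
        return s.side_a
    if side == "b":
        return s.side_b
    side = frozenset(side)
    if side == s.side_a or side == s.side_b:
        return side
    raise TreeError(f"{sorted(side)} is not a side of split {s}")


def collapse_side(t: Tree, s: Split, side, fresh: str) -> Tree:
    """Replace the subtree on one side of split ``s`` by a single fresh leaf.

    ``side`` is ``"a"``, ``"b"``, or the leaf set of the side to collapse.
    Every split of the result is a split of ``t`` with the collapsed side's
    members replaced by ``fresh``.  The split must be non-trivial and
    ``fresh`` must not collide with a retained label.
    """
    if s not in t.splits():
        raise TreeError(f"split {s} is not a split of the tree")
    if s.is_trivial:
        raise TreeError("cannot collapse a side of a trivial split")
    collapsed = _resolve_side(s, side)
    kept = s.leaf_set - collapsed
    if fresh in kept:
        raise TreeError(f"fresh label {fresh!r} collides with a retained leaf")
    u, v = t.edge_of_split(s)
    cut = u if collapsed == s.side_a else v  # endpoint inside collapsed side
    keep_root = v if cut == u else u
    adj = t.adjacency()
    # keep the component of keep_root, drop the rest, hang the fresh leaf on it
    keep_nodes = set()
    stack = [keep_root]
    seen = {cut}
    while stack:
        w = stack.pop()
        if w in keep_nodes:
            continue
        keep_nodes.add(w)
        stack.extend(adj[w] - keep_nodes - seen)
    new_adj = {w: adj[w] & keep_nodes for w in keep_nodes}
    leaf_label = {w: lab for w, lab in t.leaf_labels().items() if w in keep_nodes}
    fresh_node = max(t.adjacency()) + 1
    new_adj[fresh_node] = {keep_root}
    new_adj[keep_root].add(fresh_node)
    leaf_label[fresh_node] = fresh
    return Tree(new_adj, leaf_label)


def expand_leaf(t: Tree, leaf: str, sub: PendantSubtree) -> Tree:
    """Replace the leaf ``leaf`` of ``t`` by the pendant subtree ``sub``.

    Split sets substitute cleanly: every split of the result is a split of
    ``t`` with ``leaf`` replaced by ``sub``'s leaf set, plus the internal
    splits of ``sub`` — so symmetric differences of split sets (and hence RF
    distances) are preserved when two trees expand the same leaf with the
    same subtree.  Expanding by a single-leaf subtree is a relabeling.
    """
    leaf_node = t.node_of(leaf)
    clash = sub.leaf_set & (t.leaf_set - {leaf})
    if clash:
        raise TreeError(f"subtree labels collide with tree labels: {sorted(clash)}")
    adj = t.adjacency()
    leaf_label = t.leaf_labels()
    if sub.n_leaves == 1:
        leaf_label[leaf_node] = next(iter(sub.leaf_label.values()))
        return Tree(adj, leaf_label)
    parent = next(iter(adj[leaf_node]))
    adj[parent].discard(leaf_node)
    del adj[leaf_node]
    del leaf_label[leaf_node]
    offset = max(adj) + 1
    for v, nbrs in sub.adj.items():
        adj[v + offset] = {u + offset for u in nbrs}
    for v, lab in sub.leaf_label.items():
        leaf_label[v + offset] = lab
    handle = sub.handle + offset
    adj[parent].add(handle)
    adj[handle].add(parent)
    return Tree(adj, leaf_label)


def induced_subtree(t: Tree, leaves: Iterable[str]) -> PendantSubtree:
    """The pendant subtree of ``t`` on the clade ``leaves``, with its handle.

    ``leaves`` must be a clade of ``t`` — a single leaf or one side of a
    split — so that the attachment (cut) point is unique; it is recorded as
    the subtree's handle.  The subtree's own splits are exactly the splits of
    ``t`` nested inside ``leaves``, restricted to it.
    """
    A = frozenset(leaves)
    if not A:
        raise TreeError("empty leaf set")
    if A == t.leaf_set:
        raise TreeError("induced subtree must be proper")
    missing = A - t.leaf_set
    if missing:
        raise TreeError(f"labels not in tree: {sorted(missing)}")
    if len(A) == 1:
        lab = next(iter(A))
        node = t.node_of(lab)
        return PendantSubtree(adj={node: set()}, leaf_label={node: lab}, handle=node)
    if not t.has_clade(A):
        raise TreeError(f"{sorted(A)} is not a clade (one side of a split) of the tree")
    s = next(sp for sp in t.splits() if sp.has_side(A))
    u, v = t.edge_of_split(s)
    root = u if s.side_a == A else v  # endpoint inside A's component
    other = v if root == u else u
    adj = t.adjacency()
    nodes = set()
    stack = [root]
    blocked = {other}
    while stack:
        w = stack.pop()
        if w in nodes:
            continue
        nodes.add(w)
        stack.extend(adj[w] - nodes - blocked)
    sub_adj = {w: adj[w] & nodes for w in nodes}
    sub_labels = {w: lab for w, lab in t.leaf_labels().items() if w in nodes}
    return PendantSubtree(adj=sub_adj, leaf_label=sub_labels, handle=root)


def fresh_label(existing: Iterable[str], stem: str = "x") -> str:
    """A label of the reserved form ``_<stem><i>`` absent from ``existing``."""
    taken = set(existing)
    i = 0
    while f"_{stem}{i}" in taken:
        i += 1
    return f"_{stem}{i}"
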