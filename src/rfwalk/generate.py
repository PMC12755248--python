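"""Seeded random tree generation.

Sequential leaf attachment: starting from the unique 3-leaf tree, each
subsequent leaf is attached to an edge drawn uniformly at random.  This
yields the uniform distribution over all (2n-5)!! unrooted binary
topologies on the given labels, and is fully deterministic given a seed.
"""

from __future__ import annotations

import random
from typing import Iterable, Optional

from .trees import Tree, UnsupportedSizeError

__all__ = ["random_tree"]


def random_tree(
    labels: Iterable[str],
    seed: Optional[int] = None,
    rng: Optional[random.Random] = None,
) -> Tree:
    """A uniformly random unrooted binary tree on ``labels``.

    Pass either a ``seed`` or an explicit ``rng`` (a ``random.Random``) to
    thread one generator through several draws; the same seed and labels
    always produce the same tree.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise UnsupportedSizeError(f"need at least 3 leaves, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if rng is None:
        rng = random.Random(seed)
    adj = {0: {1, 2, 3}, 1: {0}, 2: {0}, 3: {0}}
    leaf_label = {1: labels[0], 2: labels[1], 3: labels[2]}
    edges = [(0, 1), (0, 2), (0, 3)]
    nxt = 4
    for lab in labels[3:]:
        u, v = edges[rng.randrange(len(edges))]
        mid, leaf = nxt, nxt + 1
        nxt += 2
        adj[u].discard(v)
        adj[v].discard(u)
        adj[mid] = {u, v, leaf}
        adj[u].add(mid)
        adj[v].add(mid)
        adj[leaf] = {mid}
        leaf_label[leaf] = lab
        edges.remove((u, v))
        edges.extend([(u, mid), (mid, v), (mid, leaf)])
    return Tree(adj, leaf_label)
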