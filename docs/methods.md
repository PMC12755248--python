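# Methods

## Scope and objects

All trees are unrooted, binary (internal degree 3), with leaves bijectively
labeled by a taxon set `X`, `|X| = n ≥ 3`.  A tree is identified with its
split set `Γ(T)` (2n−3 bipartitions of `X`, one per edge, n of them
trivial); two trees are isomorphic iff their split sets are equal, and tree
equality/hashing in the package is defined that way.  The RF distance is
`|Γ(T) Δ Γ(R)|` over *all* splits; leaf sets are required to be equal, so
trivial splits cancel and the value coincides with the usual count over
internal edges.  Mismatched leaf sets are an error, never a
distance-on-restriction.

Splits are stored canonically — `side_a` is the smaller side, ties broken by
the side containing the lexicographically smallest label — which makes them
hashable and gives every tie-break in the package (shared-split choice,
cherry choice, prune-clade choice) a deterministic total order: by split
size, then lexicographically on the sorted `side_a`.  Rationale:
reproducibility; identical inputs always produce identical paths.

## Newick conventions

Parsing is delegated to dendropy; branch lengths and internal labels are
discarded (everything here is topology only), a top-level trifurcation is
the native encoding of an unrooted tree, and a rooted bifurcation is
accepted and unrooted by suppressing the root.  Duplicate labels, any other
degree-2 node, nodes of degree > 3, and fewer than 3 leaves are rejected.
Writing is canonical: the tree is rendered as a trifurcation at the internal
node adjacent to the smallest leaf, siblings ordered by smallest descendant
label, so isomorphic trees serialize identically and round-trip exactly.

## Moves

Moves are declarative and identified by splits, not node ids, so they
survive re-parsing.  An NNI move names an internal edge (a non-trivial
split) and one of the two non-identity exchanges across it; the two
subtrees at each endpoint are ordered by smallest contained label to make
the encoding canonical.  An SPR move names the pruned component by its leaf
set (one side of a split, leaving ≥ 2 leaves behind) and the regraft edge by
the split it induces in the remaining component.  A TBR move names the
bisection edge and one reattachment edge per component (`None` for a
single-leaf component, which reattaches at the leaf).  Degenerate SPR
regrafts onto the edge formed by suppressing the old attachment point are
legal applications (they recreate the source) but are excluded from
neighborhoods, since the rearrangement graphs have no self-loops.

NNI adjacency is decided by the contraction characterization: trees are
adjacent iff contracting one edge in each yields identical split sets,
which for binary trees on equal leaf sets is equivalent to
`|Γ(T) Δ Γ(R)| = 2`.  Tests cross-check this oracle against neighborhood
membership (exhaustively at n = 5, sampled at n = 6).

## The monotone NNI path

Recursive construction on n.  Base: distinct 4-leaf trees are one NNI move
apart.  If the trees share a non-trivial split, the shared split of minimum
size (lexicographic tie-break) is chosen; each of its sides is collapsed in
turn to a fresh leaf in both trees, the construction recurses on the two
smaller pairs, and the two sub-paths are lifted back by re-expanding the
collapsed leaf — with the *source* tree's subtree on the first side and the
*target* tree's subtree on the second — and concatenated.  Expansion
substitutes leaf-for-subtree inside every split, so symmetric differences
(hence RF profiles) are preserved by the lift, and the junction trees of the
two lifted paths have identical split sets.  That identity is asserted at
runtime rather than assumed; its failure would signal an implementation
bug, not a data condition.  Fresh labels are drawn from a reserved
`_<stem><i>` namespace checked against the current leaf set and are fully
eliminated by the lift; no emitted tree contains one.

If the trees share no non-trivial split (RF distance at its maximum
2(n−3)), the cherry walk applies: take the lexicographically smallest
cherry `(c1, c2)` of the target and repeatedly apply the NNI move on the
second edge of the current `c1→c2` path that swaps the `c2`-containing
component on the far side with `c1`'s sibling on the near side — shortening
the path by one edge per move — stopping at the *first* tree strictly
closer to the target (at the latest when the cherry is formed).  The wording
of the swap admits a second reading (moving `c1`'s side rather than the
`c2` component); both shorten the leaf path and keep the profile flat at the
maximum until the drop, and the implemented variant is the literal
"swap the `c2`-side component" one.  After the drop, a shared split exists
and the shared-split recursion takes over.

The profile can plateau, and sometimes must: exhaustive search over the 105
six-leaf trees finds ordered pairs — 3,630 of them, 3,180 at the maximum
distance 6 — where *no* NNI neighbor of the source is strictly closer to
the target.  Notably the search also returns qualifying pairs at distance
4, i.e. pairs that *do* share a split yet still admit no improving first
step; the search reports whatever qualifies rather than assuming the
maximum-distance class is the only one.

## The strict SPR path

Each step selects the minimum-size non-trivial split `A|B` of the target
absent from the current tree (ties lexicographic).  In the target, the edge
inducing `A|B` has two pendant clades `A1 ∪ A2 = A` below it; minimality
forces both to be pendant in the current tree as well (any smaller
non-trivial target split is already present, and single leaves are always
pendant).  The smaller of the two (tie lexicographic) is pruned and
regrafted onto the edge above the other, creating `A|B`.  Every split
changed by that move lies on the `A1`–`A2` path in the current tree and has
the form `A1∪X | A2∪Y`, none of which occur in the target — so the move
only rewrites splits already counted in the symmetric difference, at least
one of which (`A|B`) it fixes.  The RF distance to the target therefore
drops by ≥ 2 per step, giving path length ≤ d_RF/2; both the created-split
and strict-decrease conditions are asserted at runtime.  The construction
is applied from the current tree toward the target (the symmetric version
of modifying the target toward the source), so the emitted path runs
source → target without reversal.  Because every SPR move is expressible as
a TBR move (bisect at the prune edge, reattach at the suppressed-attachment
edge and the regraft edge), the same path is a strict TBR path.

## Exhaustive machinery and the random generator

Enumeration inserts leaves one at a time on every edge, generating each of
the `(2n−5)!!` topologies exactly once; it is capped at n ≤ 9 and the BFS
graph-distance oracles at n ≤ 7 — deliberately small, since exact
rearrangement distances are NP-hard and these exist only as independent
checks on the constructions.  The random generator attaches each successive
leaf to a uniformly chosen edge, which yields the uniform distribution over
labeled topologies; it is driven by an explicit `random.Random` so a single
seeded generator can be threaded through a whole experiment.  What these
synthetic inputs emulate is the full space of tree *topologies*; they carry
no branch lengths, no rooting, and no data-derived signal, so passing tests
say nothing about inference quality on real alignments — only about the
combinatorial guarantees of the path constructions, which is the point.

## Verification sizes and numerical choices

There is no floating point anywhere; all quantities are exact set
cardinalities, so no tolerances are involved.  Properties are verified
exhaustively where the space is small and by seeded sampling above that:
all 10,920 ordered 6-leaf pairs for both path constructions (with full
neighborhood membership checks for SPR at n = 6), exhaustive n = 5 in the
unit suites, seeded random pairs at n = 7–8 for NNI and 200/200/100 pairs
at n = 10/20/50 for SPR, 200 seeded pairs at n ∈ {8, 16, 32} against
dendropy's symmetric difference as the independent RF oracle, 30,000 draws
for the quartet uniformity check and 20,000 draws for 6-leaf topology
coverage (the probability of missing any topology at that size is
astronomically small).  These sizes were chosen to keep the full suite in
the low minutes while leaving every claim either exhaustive or sampled well
past the point of diminishing returns.

## Known limitations

Only unrooted binary trees: multifurcations exist transiently inside the
NNI contraction check but are not a supported input.  No branch-length- or
rooting-aware distances.  Constructed paths come with no optimality claim —
they are generally not shortest paths in their graphs (the relation between
monotone and shortest paths is open); the BFS oracle exists precisely to
keep that distinction measurable on small instances.  Enumeration and BFS
do not scale past the documented caps by design.
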