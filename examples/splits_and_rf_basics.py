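"""Splits, RF distance, and tree reconstruction from a split set.

Every edge of an unrooted binary tree on n leaves induces a bipartition
(split) of the leaf set; the 2n-3 splits determine the tree uniquely, and
the RF distance counts the splits in which two trees differ.
"""

from rfwalk import parse_newick, rf_distance, tree_from_splits

t = parse_newick("(((a,b),c),(d,(e,f)));")
r = parse_newick("(((a,d),c),(b,(e,f)));")

print(f"T = {t.newick()}")
print("non-trivial splits of T:")
for s in sorted(t.nontrivial_splits(), key=lambda s: s.sort_key()):
    print(f"  {s}  (size {s.size})")

print(f"\nR = {r.newick()}")
print("splits only in T:", [str(s) for s in t.splits() - r.splits()])
print("splits only in R:", [str(s) for s in r.splits() - t.splits()])
print(f"RF(T, R) = {rf_distance(t, r)}  (= total number of differing splits)")

rebuilt = tree_from_splits(t.splits())
print(f"\ntree rebuilt from T's split set: {rebuilt.newick()}")
print("identical to T:", rebuilt == t)
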