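"""Find tree pairs that admit no RF-improving NNI move.

Exhaustively enumerates all 105 unrooted binary trees on 6 leaves and
searches every ordered pair (T, R) for cases where every NNI neighbor of T
is at least as far from R as T itself.  Such pairs exist at the maximum RF
distance 6: from T, no single NNI move gets strictly closer to R, so no
strictly decreasing NNI path can exist — the monotone construction must go
through a plateau instead.
"""

from rfwalk import (
    find_nni_counterexamples,
    nni_monotone_path,
    nni_neighbors,
    rf_distance,
)

pairs = find_nni_counterexamples(6)
max_pairs = [(t, r) for t, r in pairs if rf_distance(t, r) == 6]
print(f"qualifying ordered pairs: {len(pairs)}, of which {len(max_pairs)} at RF 6")

t, r = max_pairs[0]
print(f"\nexample pair at the maximum distance:\n  T = {t.newick()}\n  R = {r.newick()}")
print("RF distances of T's six NNI neighbors to R:",
      [rf_distance(nb, r) for nb in nni_neighbors(t)])

profile = nni_monotone_path(t, r).rf_profile
print(f"\nmonotone NNI path profile for this pair: {profile}")
print("All neighbors sit at distance 6, so the first step cannot improve;")
print("the path above still reaches R because equal consecutive values are allowed.")
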