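# rfwalk

Rearrangement paths between phylogenetic trees that are monotone in
Robinson-Foulds distance.

## The problem

Phylogenetic treespace is commonly explored with tree rearrangement moves —
Nearest Neighbor Interchange (NNI), Subtree Prune and Regraft (SPR), Tree
Bisection and Reconnection (TBR) — while tree similarity is usually measured
with the efficiently computable Robinson-Foulds (RF) distance, because the
rearrangement-based graph distances are NP-hard.  These two views can
conflict: a single SPR move can connect trees at maximum RF distance.  A
natural question for anyone doing hill-climbing or MCMC in treespace is
whether the two are at least reconcilable along *some* path: given trees
`T` and `R`, is there a path of single rearrangements from `T` to `R` along
which the RF distance to `R` only goes down?

`rfwalk` answers this constructively for unrooted binary trees on a common
leaf set `X`:

* **NNI:** `nni_monotone_path(T, R)` returns a path
  `T = T0, T1, …, Tk = R` of NNI moves with
  `d_RF(T_{i+1}, R) ≤ d_RF(T_i, R)` for all `i`.  Strictness is impossible
  in general: `find_nni_counterexamples(6)` exhibits pairs at the maximum
  distance `2(n−3)` whose every NNI neighbor is just as far from `R`, so a
  plateau is sometimes forced.
* **SPR:** `spr_strict_path(T, R)` returns a path with
  `d_RF(T_{i+1}, R) < d_RF(T_i, R)` — each step drops the distance by at
  least 2, so the path has at most `d_RF(T, R)/2` moves.  Since every SPR
  move is a TBR move (`spr_move_as_tbr`), the same path is a strictly
  decreasing TBR path.

Here `d_RF(T, R) = |Γ(T) Δ Γ(R)|` with `Γ(T)` the set of splits
(bipartitions of `X`) induced by the edges of `T`.

Both constructions preserve every split shared by the endpoints — in
contrast with shortest SPR paths, which may break shared splits.

The package also provides the supporting toolkit: Newick I/O with a
canonical writer, split extraction and Buneman-style reconstruction of a
tree from its split set, RF distance, NNI/SPR/TBR application and
neighborhood enumeration, exhaustive enumeration of all `(2n−5)!!` trees on
small leaf sets, BFS graph-distance oracles, uniform random topologies, and
a path validator.

## A worked example

```python
from rfwalk import parse_newick, rf_distance, nni_monotone_path, validate_path

source = parse_newick("(a,(b,(c,(d,(e,f)))));")
target = parse_newick("((a,c),(e,(b,f)),d);")
print(rf_distance(source, target))          # 6  (the maximum for n = 6)

path = nni_monotone_path(source, target)
for tree, d in zip(path.trees, path.rf_profile):
    print(d, tree.newick())
print(validate_path(path).message())
```

prints

```
6
6 (a,b,(c,(d,(e,f))));
4 (a,(b,(d,(e,f))),c);
2 (a,((b,(e,f)),d),c);
0 (a,(((b,f),e),d),c);
path valid
```

— a path of three NNI moves whose RF distance to the target (first column)
never increases and ends at zero.  The `examples/` directory has similar
narrative scripts for the strict SPR path, the exhaustive counterexample
search, and the split/RF basics.

A thin CLI mirrors the library:

```sh
rfwalk rf "((a,b),(c,d));" "((a,c),(b,d));"       # prints 2
rfwalk spr-path t.nwk r.nwk --out path.nwk --profile path.tsv
rfwalk validate-path path.nwk --mode spr           # exit 0 iff valid
rfwalk find-counterexample 6
```

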