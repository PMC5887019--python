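# hyperroute

Ranked enumeration of chemical synthesis plans as shortest hyperpaths in a
directed hypergraph of reactions.

## The problem

Skeleton-level synthesis planning asks how to assemble a target molecule's
carbon skeleton from purchasable starting materials using *construction
reactions*: **affixations** (one new bond unites two precursors) and
**cyclizations** (one new bond closes a ring in a single molecule).  A
chosen **bond set** — the target bonds the plan will form — typically admits
many plans, differing in the order bonds are fixed and in how convergent the
route is, and the best plan under one yield assumption need not be best
under another.  `hyperroute` is for computational chemists and method
developers who want *all* (or the K best) plans, ranked, rather than one
heuristic route.

## The model

A synthesis plan is a DAG whose vertices are molecules and whose building
blocks are reactions.  Reversing every reaction into a B-hyperarc
(tail = reactants, head = product) and adding a dummy source *s* with an arc
to every starting material turns the available chemistry into a **hypergraph
of reactions (HoR)**; the plans for target *t* are exactly the hyperpaths
from *s* to *t*.  Plans are ranked by additive weight functions

&nbsp;&nbsp;&nbsp;&nbsp;W(π_st) = 1 if t = s, else Σ_{v ∈ T(p(t))} a_{v,p(t)} · W(π_sv),

whose chief instance is **TW**, the total weight of starting materials in
grams per gram of target: a_{v,e} is the *retro yield* r_{v,e} (grams of
reactant v per gram of product of e, with Σ_v r_{v,e} ≥ 1 by mass
conservation and r = 1 on dummy arcs).  The single shortest hyperpath is a
dynamic program over a topological order; the K best are found by deviation
branching on per-vertex predecessor choices, certified against an
independent exhaustive enumerator.  The classical convergency measure
**EPL** (external path length of the plan's tree expansion) is also
provided — together with a worked counterexample showing it is *not*
expressible as an additive weight function.

## Worked example

Decalin (bicyclo[4.4.0]decane: two fused six-rings, 10 carbons, 11 bonds)
with the bond set `{1, 3, 7, 9}`, which splits it into chain fragments of
6, 2 and 2 carbons:

```python
from hyperroute import (decalin, BondSet, build_hor_from_bond_set,
                        assign_retro_yields, k_shortest_hyperpaths)
import math

d = decalin()
hor = build_hor_from_bond_set(d, BondSet(d, frozenset({1, 3, 7, 9})))
r = assign_retro_yields(hor, rho_total=1.25)   # 80% yield per reaction
ranked = k_shortest_hyperpaths(hor.graph, r, hor.source, hor.target_vertex, math.inf)
print([round(w, 4) for w in ranked.weights()])
```

prints

```
[2.2656, 2.3438, 2.3438]
```

i.e. the plan that alternates affixation and cyclization needs 2.27 g of
starting material per gram of decalin at 80 % per-reaction yield, while the
two plans that postpone both ring closures need 2.34 g.  At 40 % yield
(`rho_total=2.5`) the same ranking gives 32.5 g vs 34.4 g.  The same thing
from the shell:

```sh
hyperroute build-hor --fixture decalin --bonds 1,3,7,9 --out hor.json
hyperroute rank --hor hor.json --rho 1.25
hyperroute survey --fixture decalin -k 4 --rho 1.25 --rho 2.5 --out report/
```

The survey command reports, among other things, that decalin has 92
non-isomorphic bond sets of size four admitting 1711 plans in total (at
most 38 for a single bond set), and writes a per-class CSV with ranked TW
lists at both yield levels and the first rank position at which the two
rankings disagree.

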