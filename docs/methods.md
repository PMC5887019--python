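# Methods

## Model and scope

`hyperroute` operates on the first phase of synthesis planning only: the
assembly of the target's skeleton by construction reactions, each adding
exactly one skeleton bond.  Molecules are connected simple graphs with atom
labels; bond orders, charges, stereochemistry and functionalization
chemistry are out of scope.  A plan is a DAG with unique molecule labels in
which every building block is a valid one-bond addition, the unique
in-degree-zero vertex is the target, and every leaf is a starting material.
Reversing reactions into B-hyperarcs and adding a dummy source yields the
hypergraph of reactions (HoR); plans for the target correspond one-to-one
to source-to-target hyperpaths, and the package's ranked search, validation
and measures all operate on that correspondence (it is exercised as an
explicit round-trip in the test suite).

A HoR built from a bond set is always acyclic — every reaction strictly
increases the number of bonds — and all its reaction arcs have one or two
tail occurrences, so size(H) = Σ(|T(e)|+1) ≤ 3|E|.

## Molecule identity: two modes

When the HoR is generated by recursively breaking the bonds of a bond set,
intermediate fragments must be compared for identity.  Two modes exist:

* **isomorphism** (default): fragments are the same vertex iff they are
  isomorphic as element-labeled graphs.  This implements the rule that
  vertices with the same molecule label are one vertex, and is the mode
  under which the decalin survey reproduces the published plan counts
  (total 1711, maximum 38).  A consequence worth knowing: isomorphic
  intermediates arising from *different* embeddings share a vertex, so the
  HoR also contains hybrid plans that no single order of bond additions on
  one embedding realizes.  The order-of-addition brute-force planner in the
  test suite therefore matches hyperpath enumeration exactly in embedding
  mode and is a subset in isomorphism mode.
* **embedding**: fragments are identical iff they occupy the same original
  target atoms *and* retain the same original bonds.  Keying on atoms alone
  would conflate intermediates that differ by an already-broken ring bond
  (a cyclization changes no atoms), hence the bond-id component.

Canonical identity uses BLISS canonical labeling (python-igraph) with atom
elements as vertex colors; the test suite cross-checks it against VF2
isomorphism on independently generated graph pairs.  Automorphism groups
(for bond-set orbit enumeration) come from VF2 self-isomorphisms; orbits of
k-subsets of bonds are enumerated explicitly by minimizing over group
images, with a Burnside-lemma count as an independent oracle.  The orbit
representative is the lexicographically least member set, so reports are
stable across runs.

## Measures

Retro yields are assigned per (arc, tail occurrence).  The
carbon-proportional scheme gives a cyclization its full per-reaction total
`rho_total` and splits an affixation's total between the reactants in
proportion to carbon counts; `rho_total` of 1.25 and 2.5 correspond to 80 %
and 40 % per-reaction yield.  `rho_total < 1` is rejected (mass
conservation).  Dummy arcs carry 1 unless per-gram prices are configured,
in which case TW becomes a price.  A repeated tail vertex (isomorphic
co-reactants merged into one vertex) carries one coefficient per
occurrence, and every size and weight computation counts multiplicity.

TW is computed by the additive recursion with memoization (each vertex of
the hyperpath evaluated once).  An intentionally independent oracle
(`tw_path_oracle`) instead enumerates every plain source-to-target path
inside the hyperpath and sums retro-yield products; the two agree to 1e-9
relative error across the whole decalin survey, which is the package's
evidence that the recursion implements the path-product definition.  With
carbon-proportional yields both collapse to the closed form
Σ_leaves (c_leaf/c_target)·rho^depth, also asserted in the tests.

EPL (sum over starting materials of their reaction distance to the target)
is defined — and computed — only on the unary-binary *tree expansion* of a
plan, its original habitat.  EPL cannot be written as an additive weight
function: the optimal sub-plan for a molecule under EPL depends on the
depth at which the molecule is used.  The test suite carries a concrete
counterexample (a molecule with a convergent 4-leaf/EPL-8 plan and a linear
2-leaf/EPL-11 plan, used at depths 1 and 2 of one host plan) in which the
EPL-optimal host mixes the two sub-plans.  Ranking in this package is
therefore done with TW-style measures; EPL is reported on trees only.

## Search

*Single shortest hyperpath*: dynamic programming over a topological order
of the projection graph (one standard edge per tail occurrence), keeping
for each vertex the cheapest allowed ingoing arc; ties break toward the
lowest arc id, making results deterministic.  Constraints are expressed as
banned arcs plus forced predecessor arcs (all other ingoing arcs of the
forced head ignored).

*K shortest hyperpaths*: best-first deviation branching.  Each search node
fixes the predecessor arc of one more vertex, taken in decreasing
topological order, which partitions the remaining hyperpath space exactly:
every hyperpath of a node's cell contains the node's forced arcs, so the
forced-arc DP solution is both a member of the cell and its exact minimum.
No candidate can be derived twice, the emitted list is non-decreasing in
weight, and the K-list is a prefix of the (K+1)-list.  A fix-prefix/ban-one
scheme that forces a predecessor only by deleting competing arcs was
evaluated first and rejected: its deviation cells overlap (a hyperpath that
omits a forced head entirely lies in several cells), so duplicate
suppression either loses hyperpaths or, if duplicates are re-branched,
multiplies subproblems by three orders of magnitude on 30-arc instances.
`enumerate_all_hyperpaths` is an independent recursive enumerator (choose
an ingoing arc per vertex in decreasing topological order); it serves both
as the K = ∞ API of last resort and as the oracle that certifies the ranked
search on every decalin bond set of size ≤ 4 and on batteries of random
acyclic B-hypergraphs.

## Numerical and reporting choices

Weights are double-precision floats; the decalin quantities are ratios of
small integers times powers of rho and are exact well beyond the printed
precision.  Values quoted at printed precision are rounded half away from
zero (decimal arithmetic), the convention that matches tabulated values
such as 15.625 → 15.63.  Degenerate inputs are defined, not errors: an
empty bond set makes the target its own starting material, the trivial
hyperpath has weight 1, and a single-leaf tree has EPL 0.

## Problem sizes

The bundled case study is deliberately desk-scale: decalin has 11 bonds,
C(11,4) = 330 subsets falling into 92 orbit classes, each HoR has tens of
vertices and arcs, and the full survey (both yield levels, K = ∞ per class)
runs in seconds.  The brute-force oracles (all-permutation bond addition,
path-product TW, exhaustive sub-hypergraph checks) are exponential by
design and are only ever run at these sizes.

## Limitations

Skeleton-level plans ignore functionalization, protective groups,
stereochemistry and reaction feasibility; a "plan" here is a combinatorial
object, not a validated route.  Yield models are per-reaction scalars with
carbon-proportional apportioning — real yields are neither uniform nor
mass-proportional.  Cyclic HoRs (which cannot arise from construction-only
chemistry but can from general reaction databases) are rejected rather than
supported.  Hypergraphs are B-hypergraphs throughout: reactions with more
than one product are out of scope.
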