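"""Quality measures for synthesis plans.

TW (total weight of starting materials) is the grams of starting materials
needed per gram of target.  On a hyperpath it is the sum, over all plain
source-to-target paths, of the products of per-arc *retro yields*
``r_{v,e}`` (grams of reactant v per gram of product of e); equivalently it
is the value of the additive weight recursion

    W(pi_st) = 1                                   if t = s
    W(pi_st) = sum_{v in T(p(t))} a_{v,p(t)} W(pi_sv)   otherwise

with coefficients ``a = r``.  Both formulations are implemented; the path
enumeration is kept as an independent oracle.

EPL (external path length) is the sum over starting materials of the number
of reactions separating them from the target, evaluated on the unary-binary
tree expansion of the plan (its original habitat).  EPL is *not* expressible
as an additive weight function — the optimal sub-plan for a molecule would
depend on where in the enclosing plan it sits — which is why ranking here is
done with TW-style measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .hor import AFFIXATION, CYCLIZATION, DUMMY, HoR, PlanTree
from .hypergraph import Hypergraph, Hyperpath, backtrack

__all__ = [
    "WeightFunction",
    "RetroYieldAssignment",
    "assign_retro_yields",
    "evaluate_weight",
    "tw",
    "tw_path_oracle",
    "epl",
    "round_printed",
]


def round_printed(x: float, ndigits: int) -> float:
    """Round the way tabulated values are printed (half away from zero),
    e.g. 15.625 -> 15.63 at two decimals."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class WeightFunction:
    """Non-negative coefficient per (hyperarc, tail occurrence).

    ``coeffs[arc_id]`` is a tuple aligned with the arc's tail tuple, so a
    vertex occurring twice in a tail carries two independent coefficients.
    """

    coeffs: dict[int, tuple[float, ...]]

    def __post_init__(self) -> None:
        for a, cs in self.coeffs.items():
            if any(c < 0 for c in cs):
                raise ValueError(f"negative coefficient on arc {a}")

    def coeff(self, arc_id: int, occurrence: int) -> float:
        try:
            return self.coeffs[arc_id][occurrence]
        except (KeyError, IndexError):
            raise KeyError(
                f"no coefficient for arc {arc_id} occurrence {occurrence}"
            ) from None

    @classmethod
    def ones(cls, h: Hypergraph) -> "WeightFunction":
        return cls({e.id: (1.0,) * len(e.tail) for e in h.arcs})


@dataclass
class RetroYieldAssignment(WeightFunction):
    """Retro yields: grams of each reactant per gram of product.

    For every reaction arc the occurrences sum to ``rho_total`` (mass
    conservation demands the sum be >= 1); dummy arcs carry 1 unless prices
    are configured.
    """

    rho_total: float = 1.0
    scheme: str = "carbon-proportional"


def assign_retro_yields(
    h: HoR,
    rho_total: float,
    scheme: str = "carbon-proportional",
    explicit: Mapping[int, tuple[float, ...]] | None = None,
    prices: Mapping[int, float] | None = None,
) -> RetroYieldAssignment:
    """Assign retro yields to every arc of a HoR.

    ``carbon-proportional``: a cyclization arc gets ``rho_total`` on its
    single tail occurrence; an affixation arc splits ``rho_total`` between
    its two occurrences in proportion to reactant carbon counts.  ``prices``
    optionally replaces the dummy-arc 1s with per-gram prices keyed by
    starting-material vertex.
    """
    if rho_total < 1:
        raise ValueError(
            f"rho_total={rho_total} violates mass conservation (must be >= 1)"
        )
    coeffs: dict[int, tuple[float, ...]] = {}
    for e in h.graph.arcs:
        kind = h.arc_kinds[e.id]
        if kind == DUMMY:
            price = 1.0 if prices is None else float(prices.get(e.head, 1.0))
            coeffs[e.id] = (price,)
        elif scheme == "explicit":
            if explicit is None or e.id not in explicit:
                raise ValueError(f"explicit scheme missing arc {e.id}")
            coeffs[e.id] = tuple(float(c) for c in explicit[e.id])
        elif scheme == "carbon-proportional":
            carbons = [h.molecules[v].carbon_count for v in e.tail]
            total = sum(carbons)
            if total == 0:
                raise ValueError(f"arc {e.id}: zero total carbons in tail")
            coeffs[e.id] = tuple(rho_total * c / total for c in carbons)
        else:
            raise ValueError(f"unknown yield scheme: {scheme!r}")
    return RetroYieldAssignment(coeffs, rho_total=rho_total, scheme=scheme)


def _graph_of(h: Hypergraph | HoR) -> Hypergraph:
    return h.graph if isinstance(h, HoR) else h


def evaluate_weight(
    h: Hypergraph | HoR, pi: Hyperpath, w: WeightFunction
) -> float:
    """Additive weight of a hyperpath: the memoized recursion over the
    unique sub-hyperpaths to each tail vertex (obtained by backtracking)."""
    g = _graph_of(h)
    if pi.target == pi.source:
        return 1.0
    pred = pi.predecessor(g)
    memo: dict[int, float] = {pi.source: 1.0}

    def value(v: int) -> float:
        if v in memo:
            return memo[v]
        e = g.arc(pred[v])
        total = 0.0
        for pos, u in enumerate(e.tail):
            total += w.coeff(e.id, pos) * value(u)
        memo[v] = total
        return total

    return value(pi.target)


def tw(h: Hypergraph | HoR, pi: Hyperpath, r: RetroYieldAssignment) -> float:
    """Total weight of starting materials, in grams per gram of target."""
    return evaluate_weight(h, pi, r)


def tw_path_oracle(
    h: Hypergraph | HoR, pi: Hyperpath, r: WeightFunction
) -> float:
    """Independent TW computation by explicit plain-path enumeration.

    Walks every plain source-to-target path inside the hyperpath (a vertex
    occurring twice in a tail yields one path per occurrence) and sums the
    retro-yield products.  Exponential and deliberately so: it shares no
    code path with the recursion it checks.
    """
    g = _graph_of(h)
    if pi.target == pi.source:
        return 1.0
    arcs = [g.arc(a) for a in pi.arcs]
    total = 0.0
    stack = [(pi.source, 1.0)]
    while stack:
        v, prod = stack.pop()
        if v == pi.target:
            total += prod
            continue
        for e in arcs:
            for pos, u in enumerate(e.tail):
                if u == v:
                    stack.append((e.head, prod * r.coeff(e.id, pos)))
    return total


def epl(tree: PlanTree) -> int:
    """External path length: sum over leaves of the root-to-leaf distance."""

    def walk(node: PlanTree, depth: int) -> int:
        if not node.children:
            return depth
        return sum(walk(c, depth + 1) for c in node.children)

    return walk(tree, 0)
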