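"""Shortest and K-shortest hyperpaths on acyclic B-hypergraphs.

The single shortest hyperpath under an additive weight function is a dynamic
program over a topological order of the projection graph (each vertex keeps
the cheapest allowed ingoing arc).  The K-shortest enumeration is a
Yen/Lawler-style deviation search: branch on the ways a hyperpath can
deviate from the best ones found so far, bounding each branch with the
single-shortest subroutine under that branch's constraints.  An independent
recursive enumerator doubles as the K = infinity API and as the test oracle.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import networkx as nx

from .hypergraph import Hyperarc, Hypergraph, Hyperpath, is_acyclic
from .measures import WeightFunction

__all__ = [
    "RankedPlanList",
    "shortest_hyperpath",
    "k_shortest_hyperpaths",
    "enumerate_all_hyperpaths",
]


@dataclass
class RankedPlanList:
    """Hyperpaths in non-decreasing weight order, pairwise distinct as arc
    sets; at most K entries."""

    entries: list[tuple[Hyperpath, float]]
    K: int | float

    def __post_init__(self) -> None:
        weights = [w for _, w in self.entries]
        if any(b < a - 1e-12 for a, b in zip(weights, weights[1:])):
            raise ValueError("weights not non-decreasing")
        sigs = [p.arc_set for p, _ in self.entries]
        if len(set(sigs)) != len(sigs):
            raise ValueError("duplicate hyperpaths in ranked list")

    def __len__(self) -> int:
        return len(self.entries)

    def weights(self) -> list[float]:
        return [w for _, w in self.entries]

    def hyperpaths(self) -> list[Hyperpath]:
        return [p for p, _ in self.entries]


def _topo_order(h: Hypergraph) -> dict[int, int]:
    order = list(nx.topological_sort(h.projection()))
    return {v: i for i, v in enumerate(order)}


def _in_arcs(h: Hypergraph) -> dict[int, list[Hyperarc]]:
    ins: dict[int, list[Hyperarc]] = {v: [] for v in h.vertices}
    for e in sorted(h.arcs, key=lambda a: a.id):
        ins[e.head].append(e)
    return ins


def _dp_shortest(
    h: Hypergraph,
    w: WeightFunction,
    s: int,
    t: int,
    topo: dict[int, int],
    ins: dict[int, list[Hyperarc]],
    banned: frozenset[int],
    forced: dict[int, int],
) -> tuple[Hyperpath, float] | None:
    if s == t:
        return Hyperpath(s, t, ()), 1.0
    best: dict[int, float] = {s: 1.0}
    pred: dict[int, int] = {}
    for v in sorted(h.vertices, key=topo.__getitem__):
        if v == s:
            continue
        for e in ins[v]:
            if e.id in banned:
                continue
            if v in forced and e.id != forced[v]:
                continue
            if any(u not in best for u in e.tail):
                continue
            val = sum(
                w.coeff(e.id, pos) * best[u] for pos, u in enumerate(e.tail)
            )
            if v not in best or val < best[v]:
                best[v] = val
                pred[v] = e.id
    if t not in best:
        return None
    needed = {t}
    stack = [t]
    arcs: set[int] = set()
    while stack:
        v = stack.pop()
        if v == s:
            continue
        e = h.arc(pred[v])
        if e.id in arcs:
            continue
        arcs.add(e.id)
        for u in e.tail:
            if u not in needed:
                needed.add(u)
                stack.append(u)
    seq = tuple(sorted(arcs, key=lambda a: topo[h.arc(a).head]))
    return Hyperpath(s, t, seq), best[t]


def shortest_hyperpath(
    h: Hypergraph,
    w: WeightFunction,
    s: int,
    t: int,
    banned: frozenset[int] = frozenset(),
    forced: dict[int, int] | None = None,
) -> tuple[Hyperpath, float] | None:
    """Cheapest hyperpath from ``s`` to ``t`` (or None if unreachable).

    ``banned`` arcs are removed; ``forced`` maps a vertex to the only
    ingoing arc it may use (how the K-shortest branching pins a prefix).
    Ties break toward the lowest arc id.
    """
    if not is_acyclic(h):
        raise ValueError("shortest_hyperpath requires an acyclic hypergraph")
    return _dp_shortest(
        h, w, s, t, _topo_order(h), _in_arcs(h), banned, forced or {}
    )


def k_shortest_hyperpaths(
    h: Hypergraph,
    w: WeightFunction,
    s: int,
    t: int,
    K: int | float = math.inf,
) -> RankedPlanList:
    """The K best hyperpaths by deviation branching with exact partitioning.

    Following the Yen/Lawler idea of recursively considering every way a
    hyperpath can deviate from the best ones found so far, the search tree
    branches on the predecessor-arc choice of one vertex at a time, taken in
    decreasing topological order.  Fixing a vertex's predecessor partitions
    the remaining hyperpath space exactly, so no candidate is ever derived
    twice; each branch is bounded by its cheapest completion, computed with
    the single-shortest dynamic program under the branch's forced arcs.
    With ``K = math.inf`` the queue runs to exhaustion, yielding every s-t
    hyperpath in non-decreasing weight order.
    """
    if not is_acyclic(h):
        raise ValueError("k_shortest_hyperpaths requires an acyclic hypergraph")
    if s == t:
        return RankedPlanList([(Hyperpath(s, t, ()), 1.0)], K)
    topo = _topo_order(h)
    ins = _in_arcs(h)
    emitted: list[tuple[Hyperpath, float]] = []
    counter = itertools.count()
    heap: list = []

    def push(assigned: dict[int, int], pending: frozenset[int]) -> None:
        sol = _dp_shortest(h, w, s, t, topo, ins, frozenset(), assigned)
        if sol is not None:
            pi, weight = sol
            heapq.heappush(
                heap, (weight, pi.arcs, next(counter), pi, assigned, pending)
            )

    push({}, frozenset({t}))
    while heap and len(emitted) < K:
        weight, _, _, pi, assigned, pending = heapq.heappop(heap)
        if not pending:
            emitted.append((pi, weight))
            continue
        v = max(pending, key=topo.__getitem__)
        rest = pending - {v}
        for e in ins[v]:
            new_assigned = dict(assigned)
            new_assigned[v] = e.id
            new_pending = rest
            for u in e.tail:
                if u != s and u not in new_assigned:
                    new_pending = new_pending | {u}
            push(new_assigned, new_pending)
    return RankedPlanList(emitted, K)


def enumerate_all_hyperpaths(h: Hypergraph, s: int, t: int) -> list[Hyperpath]:
    """All s-t hyperpaths by direct recursion, independent of the ranked
    search: resolve vertices in decreasing topological order, choosing an
    ingoing arc for each, so the exactly-one-predecessor condition holds by
    construction."""
    if not is_acyclic(h):
        raise ValueError("enumeration requires an acyclic hypergraph")
    if s == t:
        return [Hyperpath(s, t, ())]
    topo = _topo_order(h)
    ins = _in_arcs(h)
    out: list[Hyperpath] = []

    def rec(assigned: dict[int, int], pending: frozenset[int]) -> None:
        if not pending:
            seq = tuple(
                sorted(assigned.values(), key=lambda a: topo[h.arc(a).head])
            )
            out.append(Hyperpath(s, t, seq))
            return
        v = max(pending, key=topo.__getitem__)
        rest = pending - {v}
        for e in ins[v]:
            new_pending = rest
            for u in e.tail:
                if u != s and u not in assigned and u != v:
                    new_pending = new_pending | {u}
            if v in e.tail:  # self-referential tails cannot occur when acyclic
                continue
            assigned[v] = e.id
            rec(assigned, new_pending)
            del assigned[v]

    rec({}, frozenset({t}))
    unique = {p.arc_set: p for p in out}
    return sorted(unique.values(), key=lambda p: p.arcs)
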