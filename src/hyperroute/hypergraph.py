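"""Directed B-hypergraph core: types, acyclicity, size, hyperpath validation,
and sub-hyperpath extraction by backtracking.

A B-hyperarc has a non-empty tail multiset and a single head vertex.  A
hyperpath from ``s`` to ``t`` is a sub-hypergraph whose arcs can be ordered
``e_1..e_q`` such that (1) each tail is covered by ``{s}`` and earlier heads,
(2) ``t`` is the last head, (3) every vertex but ``t`` has an outgoing arc and
``t`` has none, and (4) every vertex but ``s`` has exactly one ingoing arc
(its *predecessor*) and ``s`` has none.  The degenerate ``s == t`` hyperpath
has no arcs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Hyperarc",
    "Hypergraph",
    "Hyperpath",
    "HyperpathReport",
    "is_acyclic",
    "hypergraph_size",
    "validate_hyperpath",
    "order_arc_set",
    "backtrack",
]


@dataclass(frozen=True)
class Hyperarc:
    """B-hyperarc: tail multiset (as an ordered tuple) and single head."""

    id: int
    tail: tuple[int, ...]
    head: int

    def __post_init__(self) -> None:
        if not self.tail:
            raise ValueError(f"arc {self.id}: empty tail")


@dataclass
class Hypergraph:
    """Directed B-hypergraph with integer vertex ids and string labels."""

    vertices: dict[int, str]
    arcs: list[Hyperarc] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.arcs:
            self._check_arc(e)
        if len({e.id for e in self.arcs}) != len(self.arcs):
            raise ValueError("duplicate arc ids")

    def _check_arc(self, e: Hyperarc) -> None:
        for v in (*e.tail, e.head):
            if v not in self.vertices:
                raise ValueError(f"arc {e.id} references missing vertex {v}")

    def arc(self, arc_id: int) -> Hyperarc:
        return self._arc_index()[arc_id]

    def _arc_index(self) -> dict[int, Hyperarc]:
        idx = getattr(self, "_arcs_by_id", None)
        if idx is None or len(idx) != len(self.arcs):
            idx = {e.id: e for e in self.arcs}
            object.__setattr__(self, "_arcs_by_id", idx)
        return idx

    def in_arcs(self, v: int) -> list[Hyperarc]:
        return [e for e in self.arcs if e.head == v]

    def projection(self) -> nx.MultiDiGraph:
        """Standard-graph projection: one edge tail-vertex -> head per arc."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.vertices)
        for e in self.arcs:
            for u in set(e.tail):
                g.add_edge(u, e.head, arc=e.id)
        return g

    def to_json(self, **header) -> str:
        doc = dict(header)
        doc["vertices"] = [
            {"id": v, "label": lbl} for v, lbl in sorted(self.vertices.items())
        ]
        doc["arcs"] = [
            {"id": e.id, "tail": list(e.tail), "head": e.head}
            for e in sorted(self.arcs, key=lambda a: a.id)
        ]
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str | Mapping) -> "Hypergraph":
        doc = json.loads(text) if isinstance(text, str) else text
        vertices = {int(v["id"]): str(v.get("label", "")) for v in doc["vertices"]}
        arcs = [
            Hyperarc(int(a["id"]), tuple(int(u) for u in a["tail"]), int(a["head"]))
            for a in doc["arcs"]
        ]
        return cls(vertices, arcs)

    def to_dot(self) -> str:
        """DOT rendering: vertices as boxes, hyperarcs as junction points."""
        lines = ["digraph H {", "  node [shape=box];"]
        for v, lbl in sorted(self.vertices.items()):
            text = lbl.replace('"', r"\"") if lbl else str(v)
            lines.append(f'  v{v} [label="{text}"];')
        for e in sorted(self.arcs, key=lambda a: a.id):
            lines.append(f'  e{e.id} [shape=point, label=""];')
            for u in e.tail:
                lines.append(f"  v{u} -> e{e.id} [arrowhead=none];")
            lines.append(f"  e{e.id} -> v{e.head};")
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class Hyperpath:
    """Hyperpath stored as an ordered predecessor assignment.

    ``arcs`` is the arc-id sequence ``e_1..e_q``; the predecessor of the
    vertex ``h(e_i)`` is ``e_i``.
    """

    source: int
    target: int
    arcs: tuple[int, ...]

    @property
    def arc_set(self) -> frozenset[int]:
        return frozenset(self.arcs)

    def predecessor(self, h: Hypergraph) -> dict[int, int]:
        return {h.arc(a).head: a for a in self.arcs}

    def vertices(self, h: Hypergraph) -> set[int]:
        out = {self.source, self.target}
        for a in self.arcs:
            e = h.arc(a)
            out.add(e.head)
            out.update(e.tail)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"source": self.source, "target": self.target, "arcs": list(self.arcs)}
        )

    @classmethod
    def from_json(cls, text: str | Mapping) -> "Hyperpath":
        doc = json.loads(text) if isinstance(text, str) else text
        return cls(int(doc["source"]), int(doc["target"]), tuple(doc["arcs"]))


@dataclass(frozen=True)
class HyperpathReport:
    """Per-condition verdicts of hyperpath validation."""

    ordering: bool  # condition (1): tails covered by s and earlier heads
    ends_at_target: bool  # condition (2)
    out_degrees: bool  # condition (3)
    unique_predecessor: bool  # condition (4)
    messages: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return (
            self.ordering
            and self.ends_at_target
            and self.out_degrees
            and self.unique_predecessor
        )


def hypergraph_size(h: Hypergraph) -> int:
    """size(H) = sum over arcs of |tail| + 1, counting tail multiplicity."""
    return sum(len(e.tail) + 1 for e in h.arcs)


def is_acyclic(h: Hypergraph) -> bool:
    """True iff no plain path returns to a tail vertex of its first arc,
    i.e. the standard-graph projection has no directed cycle."""
    return nx.is_directed_acyclic_graph(h.projection())


def order_arc_set(
    h: Hypergraph, source: int, arc_ids: Iterable[int]
) -> tuple[int, ...] | None:
    """Greedily order an arc set so each tail is covered by ``{s}`` and
    earlier heads; returns None if no such order exists.

    Greedy suffices: appending any currently-enabled arc never disables
    another (heads only accumulate).
    """
    remaining = {h.arc(a).id: h.arc(a) for a in arc_ids}
    produced = {source}
    order: list[int] = []
    while remaining:
        ready = [
            a for a, e in remaining.items() if set(e.tail) <= produced
        ]
        if not ready:
            return None
        nxt = min(ready)
        order.append(nxt)
        produced.add(remaining.pop(nxt).head)
    return tuple(order)


def validate_hyperpath(
    h: Hypergraph, candidate: Hyperpath, reorder: bool = False
) -> HyperpathReport:
    """Check the four hyperpath conditions separately.

    With ``reorder=True`` the candidate's arc sequence is treated as an
    unordered set and a feasible order is reconstructed greedily before
    condition (1) is checked.
    """
    msgs: list[str] = []
    s, t = candidate.source, candidate.target
    for v in (s, t):
        if v not in h.vertices:
            raise ValueError(f"hyperpath references missing vertex {v}")
    arcs = []
    for a in candidate.arcs:
        try:
            arcs.append(h.arc(a))
        except KeyError:
            raise ValueError(f"hyperpath references missing arc {a}") from None

    if s == t:
        ok = not arcs
        if not ok:
            msgs.append("source equals target but arc set is non-empty")
        return HyperpathReport(ok, ok, ok, ok, tuple(msgs))

    seq = candidate.arcs
    if reorder:
        ordered = order_arc_set(h, s, seq)
        if ordered is not None:
            seq = ordered
            arcs = [h.arc(a) for a in seq]

    produced = {s}
    ordering = True
    for e in arcs:
        if not set(e.tail) <= produced:
            ordering = False
            msgs.append(f"arc {e.id} tail {e.tail} not covered by earlier heads")
            break
        produced.add(e.head)

    ends_at_target = bool(arcs) and arcs[-1].head == t
    if not ends_at_target:
        msgs.append("last arc does not produce the target")

    verts = {s, t}
    for e in arcs:
        verts.add(e.head)
        verts.update(e.tail)
    out_deg = {v: 0 for v in verts}
    in_deg = {v: 0 for v in verts}
    for e in arcs:
        in_deg[e.head] += 1
        for u in set(e.tail):
            out_deg[u] += 1

    out_degrees = out_deg[t] == 0 and all(
        out_deg[v] >= 1 for v in verts if v != t
    )
    if not out_degrees:
        msgs.append("an interior vertex lacks an outgoing arc (or t has one)")

    unique_predecessor = in_deg[s] == 0 and all(
        in_deg[v] == 1 for v in verts if v != s
    )
    if not unique_predecessor:
        msgs.append("a vertex violates the exactly-one-ingoing-arc rule")

    return HyperpathReport(
        ordering, ends_at_target, out_degrees, unique_predecessor, tuple(msgs)
    )


def backtrack(h: Hypergraph, pi: Hyperpath, v: int) -> Hyperpath:
    """The unique sub-hyperpath of ``pi`` from its source to ``v``.

    Marks ``v``, then repeatedly pulls each marked non-source vertex's
    predecessor arc and marks its tail vertices; the output arc order
    inherits ``pi``'s order.
    """
    if v not in pi.vertices(h):
        raise ValueError(f"vertex {v} not in hyperpath")
    pred = pi.predecessor(h)
    marked = {v}
    frontier = [v]
    kept: set[int] = set()
    while frontier:
        u = frontier.pop()
        if u == pi.source:
            continue
        e = h.arc(pred[u])
        if e.id in kept:
            continue
        kept.add(e.id)
        for w in e.tail:
            if w not in marked:
                marked.add(w)
                frontier.append(w)
    arcs = tuple(a for a in pi.arcs if a in kept)
    return Hyperpath(pi.source, v, arcs)
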