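"""Hypergraph of Reactions: construction from a bond set or explicit
reactions, the plan <-> hyperpath bijection, and tree expansion of plans.

The HoR of a reaction set ``R`` and starting materials ``S`` has one vertex
per distinct molecule, one B-hyperarc per reaction (tail = reactants, head =
product), a dummy source vertex ``s``, and a dummy arc ``({s}, m)`` for every
starting material ``m``.  Synthesis plans for a target are exactly the
hyperpaths from ``s`` to the target vertex, which is what turns ranked plan
enumeration into a K-shortest-hyperpath computation.

Two molecule-identity modes are supported.  ``isomorphism`` follows the
same-label rule: isomorphic fragments are one vertex.  ``embedding`` keeps
fragments occupying different parts of the target distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

from .hypergraph import Hyperarc, Hypergraph, Hyperpath, is_acyclic, order_arc_set, validate_hyperpath
from .molecules import BondSet, MoleculeError, MoleculeGraph, canonical_key, remove_bonds

__all__ = [
    "HoR",
    "SynthesisPlan",
    "PlanTree",
    "build_hor_from_bond_set",
    "build_hor_from_reactions",
    "hyperpath_to_plan",
    "plan_to_hyperpath",
    "expand_to_tree",
]

DUMMY = "dummy"
CYCLIZATION = "cyclization"
AFFIXATION = "affixation"


@dataclass
class HoR:
    """A hypergraph of reactions with its bookkeeping.

    ``molecules`` holds one representative :class:`MoleculeGraph` per
    non-source vertex; ``arc_kinds`` classifies each arc as ``dummy``,
    ``cyclization`` (|tail| = 1) or ``affixation`` (|tail| = 2).
    """

    graph: Hypergraph
    source: int
    target_vertex: int
    starting_vertices: frozenset[int]
    molecules: dict[int, MoleculeGraph]
    arc_kinds: dict[int, str]
    mode: str = "isomorphism"

    def check(self) -> None:
        if not is_acyclic(self.graph):
            raise ValueError("HoR is not acyclic")
        for e in self.graph.arcs:
            if self.arc_kinds[e.id] != DUMMY and len(e.tail) not in (1, 2):
                raise ValueError(f"reaction arc {e.id} has |tail| = {len(e.tail)}")
        if any(e.head == self.source for e in self.graph.arcs):
            raise ValueError("source vertex has an ingoing arc")

    def dummy_arcs(self) -> list[Hyperarc]:
        return [e for e in self.graph.arcs if self.arc_kinds[e.id] == DUMMY]

    def to_json(self) -> str:
        import json

        doc = json.loads(
            self.graph.to_json(
                source=self.source,
                target=self.target_vertex,
                mode=self.mode,
            )
        )
        doc["starting_vertices"] = sorted(self.starting_vertices)
        for arc in doc["arcs"]:
            arc["kind"] = self.arc_kinds[arc["id"]]
        doc["molecules"] = {
            str(v): json.loads(m.to_json()) for v, m in self.molecules.items()
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "HoR":
        import json

        from .molecules import parse_molecule

        doc = json.loads(text)
        graph = Hypergraph.from_json(doc)
        return cls(
            graph,
            source=int(doc["source"]),
            target_vertex=int(doc["target"]),
            starting_vertices=frozenset(doc["starting_vertices"]),
            molecules={
                int(v): parse_molecule(m) for v, m in doc["molecules"].items()
            },
            arc_kinds={int(a["id"]): a["kind"] for a in doc["arcs"]},
            mode=doc.get("mode", "isomorphism"),
        )


@dataclass
class SynthesisPlan:
    """Plan DAG: unique molecule labels, directed product -> reactant edges.

    ``building_blocks`` maps each non-leaf vertex to its 1 or 2 children;
    vertices absent from the map are leaves (starting materials).
    """

    root: int
    building_blocks: dict[int, tuple[int, ...]]
    molecules: dict[int, MoleculeGraph]

    @property
    def leaves(self) -> list[int]:
        verts = self.vertex_set()
        return sorted(v for v in verts if v not in self.building_blocks)

    def vertex_set(self) -> set[int]:
        out = {self.root}
        for parent, kids in self.building_blocks.items():
            out.add(parent)
            out.update(kids)
        return out

    def signature(self) -> tuple:
        """Structure-only identity: root plus the set of building blocks."""
        return (
            self.root,
            frozenset(
                (p, tuple(sorted(kids))) for p, kids in self.building_blocks.items()
            ),
        )


@dataclass(frozen=True)
class PlanTree:
    """Rooted unary-binary tree; internal nodes are reactions, leaves are
    starting materials.  Labels are molecules (or any hashable stand-in)."""

    label: Any
    children: tuple["PlanTree", ...] = ()

    def __post_init__(self) -> None:
        if len(self.children) > 2:
            raise ValueError("plan trees are unary-binary")

    @property
    def n_nodes(self) -> int:
        return 1 + sum(c.n_nodes for c in self.children)

    def leaf_labels(self) -> list[Any]:
        if not self.children:
            return [self.label]
        out: list[Any] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out


# ---------------------------------------------------------------------------
# HoR construction


def _vertex_key(m: MoleculeGraph, mode: str) -> str:
    return canonical_key(m, mode).key


def _embedding_key(m: MoleculeGraph) -> tuple:
    return (frozenset(m.atom_provenance), frozenset(m.bond_provenance))


def build_hor_from_bond_set(
    target: MoleculeGraph, b: BondSet, mode: str = "isomorphism"
) -> HoR:
    """Build the HoR by recursively breaking the bond-set bonds of the target
    in all possible ways.

    Removing a present bond-set bond from a fragment yields either one
    still-connected molecule (a retro-cyclization arc) or two fragments (a
    retro-affixation arc).  Fragments containing no bond-set bond are the
    starting materials and receive dummy arcs from the source.  Every
    embedded fragment is expanded exactly once; vertices are merged under the
    chosen identity mode and duplicate reactions are stored once.
    """
    if b.target is not target and b.target.bonds != target.bonds:
        raise MoleculeError("bond set does not belong to the target")
    if target.atom_provenance is None or target.bond_provenance is None:
        target = target.with_identity_provenance()
    members = b.members

    vertices: dict[int, str] = {0: "s"}
    molecules: dict[int, MoleculeGraph] = {}
    key_to_vertex: dict[str, int] = {}
    arcs: list[Hyperarc] = []
    arc_kinds: dict[int, str] = {}
    arc_seen: set[tuple[int, tuple[int, ...]]] = set()
    starting: set[int] = set()
    expanded: set[tuple] = set()

    def get_vertex(m: MoleculeGraph) -> int:
        key = _vertex_key(m, mode)
        if key not in key_to_vertex:
            vid = len(vertices)
            vertices[vid] = key
            key_to_vertex[key] = vid
            molecules[vid] = m
        return key_to_vertex[key]

    def add_arc(tail: tuple[int, ...], head: int, kind: str) -> None:
        sig = (head, tuple(sorted(tail)))
        if sig in arc_seen:
            return
        arc_seen.add(sig)
        arc = Hyperarc(len(arcs), tail, head)
        arcs.append(arc)
        arc_kinds[arc.id] = kind

    def expand(m: MoleculeGraph) -> int:
        vid = get_vertex(m)
        emb = _embedding_key(m)
        if emb in expanded:
            return vid
        expanded.add(emb)
        active = [
            (orig, local)
            for local, orig in enumerate(m.bond_provenance)
            if orig in members
        ]
        if not active:
            if vid not in starting:
                starting.add(vid)
                add_arc((0,), vid, DUMMY)
            return vid
        for _orig, local in sorted(active):
            parts = remove_bonds(m, {local})
            if len(parts) == 1:
                child = expand(parts[0][0])
                add_arc((child,), vid, CYCLIZATION)
            else:
                kids = tuple(expand(frag) for frag, _amap in parts)
                add_arc(tuple(sorted(kids)), vid, AFFIXATION)
        return vid

    t_vertex = expand(target)
    hor = HoR(
        Hypergraph(vertices, arcs),
        source=0,
        target_vertex=t_vertex,
        starting_vertices=frozenset(starting),
        molecules=molecules,
        arc_kinds=arc_kinds,
        mode=mode,
    )
    hor.check()
    return hor


def _is_one_bond_addition(
    reactants: Sequence[MoleculeGraph], product: MoleculeGraph, mode: str
) -> bool:
    """Is the product obtained from the reactants by adding exactly one bond?"""
    want = sorted(_vertex_key(r, "isomorphism") for r in reactants)
    if product.n_atoms != sum(r.n_atoms for r in reactants):
        return False
    if len(product.bonds) != sum(len(r.bonds) for r in reactants) + 1:
        return False
    for drop in range(len(product.bonds)):
        try:
            parts = remove_bonds(product, {drop})
        except MoleculeError:
            continue
        if len(parts) != len(reactants):
            continue
        got = sorted(_vertex_key(f, "isomorphism") for f, _ in parts)
        if got == want:
            return True
    return False


def build_hor_from_reactions(
    reactions: Sequence[tuple[Sequence[MoleculeGraph], MoleculeGraph]],
    starting_materials: Sequence[MoleculeGraph],
    mode: str = "isomorphism",
    target: MoleculeGraph | None = None,
) -> HoR:
    """Build a HoR from an explicit reaction list and starting materials.

    Each reaction must be a construction reaction: one or two reactants whose
    union plus exactly one new bond is the product.  Vertices are
    deduplicated by canonical key under ``mode``.
    """
    vertices: dict[int, str] = {0: "s"}
    molecules: dict[int, MoleculeGraph] = {}
    key_to_vertex: dict[str, int] = {}

    def get_vertex(m: MoleculeGraph) -> int:
        key = _vertex_key(m, mode)
        if key not in key_to_vertex:
            vid = len(vertices)
            vertices[vid] = key
            key_to_vertex[key] = vid
            molecules[vid] = m
        return key_to_vertex[key]

    arcs: list[Hyperarc] = []
    arc_kinds: dict[int, str] = {}
    arc_seen: set[tuple[int, tuple[int, ...]]] = set()

    starting_ids = []
    for m in starting_materials:
        vid = get_vertex(m)
        if vid not in starting_ids:
            starting_ids.append(vid)
    for vid in starting_ids:
        arc = Hyperarc(len(arcs), (0,), vid)
        arcs.append(arc)
        arc_kinds[arc.id] = DUMMY

    tails_used: set[int] = set()
    for idx, (reactants, product) in enumerate(reactions):
        if len(reactants) not in (1, 2):
            raise ValueError(f"reaction {idx}: needs 1 or 2 reactants")
        if not _is_one_bond_addition(reactants, product, mode):
            raise ValueError(
                f"reaction {idx}: product is not reactants plus exactly one bond"
            )
        tail = tuple(sorted(get_vertex(r) for r in reactants))
        tails_used.update(tail)
        head = get_vertex(product)
        sig = (head, tail)
        if sig in arc_seen:
            continue
        arc_seen.add(sig)
        arc = Hyperarc(len(arcs), tail, head)
        arcs.append(arc)
        arc_kinds[arc.id] = CYCLIZATION if len(tail) == 1 else AFFIXATION

    if reactions:
        unused = [v for v in starting_ids if v not in tails_used]
        if unused:
            raise ValueError(
                f"starting materials never used as reactants: vertices {unused}"
            )

    if target is not None:
        t_vertex = get_vertex(target)
    else:
        heads = {e.head for e in arcs if arc_kinds[e.id] != DUMMY}
        tails = {u for e in arcs if arc_kinds[e.id] != DUMMY for u in e.tail}
        roots = sorted(heads - tails) or sorted(starting_ids)
        if len(roots) != 1:
            raise ValueError("ambiguous target; pass target= explicitly")
        t_vertex = roots[0]

    hor = HoR(
        Hypergraph(vertices, arcs),
        source=0,
        target_vertex=t_vertex,
        starting_vertices=frozenset(starting_ids),
        molecules=molecules,
        arc_kinds=arc_kinds,
        mode=mode,
    )
    hor.check()
    return hor


# ---------------------------------------------------------------------------
# Bijection between plans and hyperpaths


def hyperpath_to_plan(h: HoR, pi: Hyperpath) -> SynthesisPlan:
    """Map a hyperpath from ``s`` to the target vertex to its synthesis plan:
    drop the source and dummy arcs, reverse every hyperarc into a building
    block."""
    report = validate_hyperpath(h.graph, pi)
    if not report.valid:
        raise ValueError(f"invalid hyperpath: {report.messages}")
    if pi.source != h.source:
        raise ValueError("hyperpath does not start at the HoR source")
    blocks: dict[int, tuple[int, ...]] = {}
    for a in pi.arcs:
        if h.arc_kinds[a] == DUMMY:
            continue
        e = h.graph.arc(a)
        blocks[e.head] = e.tail
    plan = SynthesisPlan(
        root=pi.target,
        building_blocks=blocks,
        molecules={v: h.molecules[v] for v in _plan_vertices(pi.target, blocks)},
    )
    return plan


def _plan_vertices(root: int, blocks: dict[int, tuple[int, ...]]) -> set[int]:
    out = {root}
    stack = [root]
    while stack:
        v = stack.pop()
        for c in blocks.get(v, ()):
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


def plan_to_hyperpath(h: HoR, plan: SynthesisPlan) -> Hyperpath:
    """Inverse map: add dummy arcs below the leaves and order all arcs
    topologically (children before parents)."""
    arc_by_sig = {
        (e.head, tuple(sorted(e.tail))): e.id
        for e in h.graph.arcs
        if h.arc_kinds[e.id] != DUMMY
    }
    dummy_by_head = {e.head: e.id for e in h.dummy_arcs()}
    chosen: list[int] = []
    for parent, kids in plan.building_blocks.items():
        sig = (parent, tuple(sorted(kids)))
        if sig not in arc_by_sig:
            raise ValueError(f"plan reaction {sig} absent from the HoR")
        chosen.append(arc_by_sig[sig])
    for leaf in plan.leaves:
        if leaf not in dummy_by_head:
            raise ValueError(f"plan leaf {leaf} is not a HoR starting material")
        chosen.append(dummy_by_head[leaf])
    order = order_arc_set(h.graph, h.source, chosen)
    if order is None:
        raise ValueError("plan arcs admit no hyperpath ordering")
    return Hyperpath(h.source, plan.root, order)


def expand_to_tree(plan: SynthesisPlan) -> PlanTree:
    """Depth-first expansion of the plan DAG into a unary-binary tree,
    duplicating shared sub-plans; leaves are the starting materials with
    multiplicity."""

    def build(v: int) -> PlanTree:
        kids = plan.building_blocks.get(v, ())
        return PlanTree(plan.molecules.get(v, v), tuple(build(c) for c in kids))

    return build(plan.root)
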