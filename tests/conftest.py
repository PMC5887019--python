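"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass

import networkx as nx
import pytest

from hyperroute.hor import HoR, build_hor_from_bond_set
from hyperroute.hypergraph import Hyperarc, Hypergraph, Hyperpath
from hyperroute.ksh import enumerate_all_hyperpaths
from hyperroute.measures import WeightFunction
from hyperroute.molecules import BondSet, MoleculeGraph, decalin, enumerate_bond_set_classes


@pytest.fixture(scope="session")
def target() -> MoleculeGraph:
    return decalin()


@dataclass
class ClassRecord:
    bond_set: BondSet
    hor: HoR
    hyperpaths: list[Hyperpath]


def _survey_classes(target: MoleculeGraph, k: int) -> list[ClassRecord]:
    out = []
    for bs in enumerate_bond_set_classes(target, k):
        hor = build_hor_from_bond_set(target, bs)
        paths = enumerate_all_hyperpaths(hor.graph, hor.source, hor.target_vertex)
        out.append(ClassRecord(bs, hor, paths))
    return out


@pytest.fixture(scope="session")
def decalin_k4(target) -> list[ClassRecord]:
    """All 92 size-four bond-set classes with their HoRs and hyperpaths."""
    return _survey_classes(target, 4)


@pytest.fixture(scope="session")
def decalin_small_k(target) -> dict[int, list[ClassRecord]]:
    """Classes for bond-set sizes 0..3."""
    return {k: _survey_classes(target, k) for k in range(4)}


# ---------------------------------------------------------------------------
# Independent oracles


def brute_isomorphic(a: MoleculeGraph, b: MoleculeGraph) -> bool:
    """Element-labeled graph isomorphism via networkx VF2 (never the
    implementation's BLISS route)."""
    return nx.is_isomorphic(
        a.to_networkx(),
        b.to_networkx(),
        node_match=lambda x, y: x["element"] == y["element"],
    )


def burnside_orbit_count(target: MoleculeGraph, k: int) -> int:
    """Burnside's lemma on the bond-permutation action: the number of
    k-subset orbits is the group-average number of fixed k-subsets."""
    from hyperroute.molecules import bond_permutations

    perms = bond_permutations(target)
    nb = len(target.bonds)
    fixed = 0
    for p in perms:
        fixed += sum(
            1
            for sub in itertools.combinations(range(nb), k)
            if frozenset(p[b] for b in sub) == frozenset(sub)
        )
    return fixed // len(perms)


def random_bhypergraph(
    rng: random.Random, n_vertices: int = 7, n_arcs: int = 10
) -> tuple[Hypergraph, WeightFunction, int, int]:
    """Random acyclic B-hypergraph with random positive weights.

    Vertex 0 is the source; the highest-indexed head is the target.  Tails
    draw from strictly earlier vertices so acyclicity holds by construction;
    duplicate tail entries model isomorphic co-reactants.
    """
    vertices = {v: f"v{v}" for v in range(n_vertices)}
    arcs: list[Hyperarc] = []
    seen: set[tuple[int, tuple[int, ...]]] = set()
    while len(arcs) < n_arcs:
        head = rng.randrange(1, n_vertices)
        k = rng.choice([1, 1, 2])
        tail = tuple(sorted(rng.randrange(0, head) for _ in range(k)))
        sig = (head, tail)
        if sig in seen:
            continue
        seen.add(sig)
        arcs.append(Hyperarc(len(arcs), tail, head))
    h = Hypergraph(vertices, arcs)
    w = WeightFunction(
        {
            e.id: tuple(round(rng.uniform(0.2, 3.0), 3) for _ in e.tail)
            for e in arcs
        }
    )
    heads = sorted({e.head for e in arcs})
    return h, w, 0, heads[-1]


def brute_force_plans(
    target: MoleculeGraph, bond_set: BondSet, mode: str = "isomorphism"
) -> set:
    """All synthesis plans of a bond set by enumerating every order of bond
    additions, independent of the hypergraph machinery.

    Forward simulation: start from the components of the target minus the
    bond set; add the bonds in every permutation, merging molecules
    (affixation) or closing rings (cyclization); record each resulting plan
    DAG as a (root, building-block set) signature under the given identity
    mode.

    Under embedding identity this enumerates exactly the plans of the HoR.
    Under isomorphism identity the HoR may admit additional hybrid plans
    (isomorphic intermediates from different embeddings share a vertex, so
    predecessor choices can mix embeddings), hence there the simulation
    yields a subset.
    """
    from hyperroute.molecules import canonical_key, remove_bonds

    if target.atom_provenance is None:
        target = target.with_identity_provenance()
    members = sorted(bond_set.members)

    def fragment(atoms: frozenset[int], removed: frozenset[int]) -> MoleculeGraph:
        local = {a: i for i, a in enumerate(sorted(atoms))}
        bonds, prov = [], []
        for b, (i, j) in enumerate(target.bonds):
            if b in removed or i not in atoms or j not in atoms:
                continue
            bonds.append((local[i], local[j]))
            prov.append(b)
        return MoleculeGraph(
            tuple(target.elements[a] for a in sorted(atoms)),
            tuple(bonds),
            tuple(sorted(atoms)),
            tuple(prov),
        )

    base = remove_bonds(target, members)
    plans = set()
    for order in itertools.permutations(members):
        # live molecules: map frozenset(atoms) -> set of removed bond ids
        live: dict[frozenset[int], frozenset[int]] = {
            frozenset(amap.values()): frozenset(members) for _frag, amap in base
        }
        blocks = []
        for b in order:
            i, j = target.bonds[b]
            home = [atoms for atoms in live if i in atoms or j in atoms]
            if len(home) == 2:  # affixation unites two molecules
                a1, a2 = home
                reactants = [fragment(a1, live[a1]), fragment(a2, live[a2])]
                new_atoms = a1 | a2
                new_removed = (live.pop(a1) & live.pop(a2)) - {b}
            else:  # cyclization closes a ring within one molecule
                (a1,) = home
                reactants = [fragment(a1, live[a1])]
                new_atoms = a1
                new_removed = live.pop(a1) - {b}
            live[new_atoms] = new_removed
            product = fragment(new_atoms, new_removed)
            blocks.append(
                (
                    canonical_key(product, mode).key,
                    tuple(sorted(canonical_key(r, mode).key for r in reactants)),
                )
            )
        (root_atoms,) = live
        root_key = canonical_key(fragment(root_atoms, live[root_atoms]), mode).key
        plans.add((root_key, frozenset(blocks)))
    return plans


def hyperpath_plan_signature(hor: HoR, pi: Hyperpath) -> tuple:
    """The same (root, building-block set) signature, derived from a
    hyperpath of the HoR."""
    blocks = []
    for a in pi.arcs:
        if hor.arc_kinds[a] == "dummy":
            continue
        e = hor.graph.arc(a)
        blocks.append(
            (
                hor.graph.vertices[e.head],
                tuple(sorted(hor.graph.vertices[u] for u in e.tail)),
            )
        )
    return (hor.graph.vertices[pi.target], frozenset(blocks))
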