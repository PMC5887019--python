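"""Molecule graphs, canonical identity, bond sets, and orbit enumeration.

A molecule is modelled the way skeleton-level synthesis planning treats it: an
undirected, connected, simple graph whose vertices carry atom-type labels.
Bond orders, charges and stereochemistry are deliberately absent — the first
phase of synthesis planning fixes the carbon skeleton only.

Fragments produced by breaking bonds of a target carry *provenance*: the
original target atom indices and bond identifiers they embed.  Provenance is
what lets the package distinguish "the same abstract molecule" (isomorphism
identity) from "the same piece of the target" (embedding identity).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx

__all__ = [
    "MoleculeGraph",
    "CanonicalKey",
    "BondSet",
    "MoleculeError",
    "parse_molecule",
    "canonical_key",
    "remove_bonds",
    "enumerate_bond_set_classes",
    "automorphisms",
    "bond_permutations",
    "decalin",
]


class MoleculeError(ValueError):
    """Raised for invalid molecule input (disconnected, dangling bond, ...)."""


@dataclass(frozen=True)
class MoleculeGraph:
    """Connected simple graph of atoms and bonds.

    Parameters
    ----------
    elements:
        Atom-type symbol per atom; atom index is the position.
    bonds:
        Unordered atom-index pairs; the bond identifier is the position in
        this tuple (never renumbered).
    atom_provenance:
        Optional original-target atom index per local atom.
    bond_provenance:
        Optional original-target bond identifier per local bond.
    """

    elements: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    atom_provenance: tuple[int, ...] | None = None
    bond_provenance: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.elements)
        seen: set[tuple[int, int]] = set()
        norm = []
        for b, (i, j) in enumerate(self.bonds):
            if not (0 <= i < n and 0 <= j < n):
                raise MoleculeError(f"bond {b} references missing atom: ({i}, {j})")
            if i == j:
                raise MoleculeError(f"bond {b} is a self-loop on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise MoleculeError(f"bond {b} duplicates bond {key}")
            seen.add(key)
            norm.append(key)
        object.__setattr__(self, "bonds", tuple(norm))
        if self.atom_provenance is not None and len(self.atom_provenance) != n:
            raise MoleculeError("atom_provenance length mismatch")
        if self.bond_provenance is not None and len(self.bond_provenance) != len(self.bonds):
            raise MoleculeError("bond_provenance length mismatch")
        if n == 0:
            raise MoleculeError("empty molecule")
        if not self._is_connected():
            raise MoleculeError("molecule graph is not connected")

    def _is_connected(self) -> bool:
        n = len(self.elements)
        adj: dict[int, list[int]] = {i: [] for i in range(n)}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == n

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def carbon_count(self) -> int:
        return sum(1 for e in self.elements if e == "C")

    def with_identity_provenance(self) -> "MoleculeGraph":
        """Return a copy whose provenance maps atoms/bonds to themselves."""
        return MoleculeGraph(
            self.elements,
            self.bonds,
            tuple(range(self.n_atoms)),
            tuple(range(len(self.bonds))),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, e in enumerate(self.elements):
            g.add_node(i, element=e)
        for b, (i, j) in enumerate(self.bonds):
            g.add_edge(i, j, bond_id=b)
        return g

    def to_json(self) -> str:
        return json.dumps(
            {
                "atoms": [{"element": e} for e in self.elements],
                "bonds": [list(b) for b in self.bonds],
            }
        )


@dataclass(frozen=True)
class CanonicalKey:
    """Opaque identity string; equal keys mean identical molecules."""

    key: str

    def __lt__(self, other: "CanonicalKey") -> bool:
        return self.key < other.key


@dataclass(frozen=True)
class BondSet:
    """A set of target bonds to be fixed by the construction reactions."""

    target: MoleculeGraph
    members: frozenset[int]

    def __post_init__(self) -> None:
        bad = [b for b in self.members if not 0 <= b < len(self.target.bonds)]
        if bad:
            raise MoleculeError(f"bond set members not in target: {sorted(bad)}")

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Parsing


def parse_molecule(source: str | Mapping) -> MoleculeGraph:
    """Parse the JSON edge-list format (or, as sugar, a SMILES string).

    The normative format is ``{"atoms": [{"element": "C"}, ...],
    "bonds": [[i, j], ...]}`` with 0-based indices; the bond identifier is the
    position in the ``bonds`` list.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        text = source.strip()
        if text.startswith("{"):
            try:
                doc = json.loads(text)
            except json.JSONDecodeError as exc:
                raise MoleculeError(f"invalid molecule JSON: {exc}") from exc
        else:
            return _parse_smiles(text)
    try:
        atoms = doc["atoms"]
        bonds = doc["bonds"]
    except KeyError as exc:
        raise MoleculeError(f"molecule JSON missing key {exc}") from exc
    elements = []
    for idx, a in enumerate(atoms):
        if isinstance(a, Mapping):
            if "element" not in a:
                raise MoleculeError(f"atom {idx} missing 'element'")
            elements.append(str(a["element"]))
        else:
            elements.append(str(a))
    pairs = []
    for b, pair in enumerate(bonds):
        if len(pair) != 2:
            raise MoleculeError(f"bond {b} is not an atom-index pair: {pair!r}")
        pairs.append((int(pair[0]), int(pair[1])))
    return MoleculeGraph(tuple(elements), tuple(pairs))


def _parse_smiles(text: str) -> MoleculeGraph:
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - rdkit is an extra
        raise MoleculeError("SMILES input requires rdkit") from exc
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise MoleculeError(f"unparsable SMILES: {text!r}")
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    )
    return MoleculeGraph(elements, bonds)


def decalin() -> MoleculeGraph:
    """The decalin skeleton: two fused six-cycles, 10 carbons, 11 bonds.

    Atoms 0..5 form one ring, atoms 0,5,6..9 the other; bond (0, 5) is the
    ring-fusion bond.  Provenance is the identity so the molecule can serve
    directly as a fragmentation target.
    """
    bonds = (
        (0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5),
        (5, 6), (6, 7), (7, 8), (8, 9), (0, 9),
    )
    return MoleculeGraph(("C",) * 10, bonds).with_identity_provenance()


# ---------------------------------------------------------------------------
# Canonical identity


def _element_colors(elements: Sequence[str]) -> list[int]:
    table = sorted(set(elements))
    lookup = {e: i for i, e in enumerate(table)}
    return [lookup[e] for e in elements]


def _canonical_certificate(m: MoleculeGraph) -> str:
    g = ig.Graph(n=m.n_atoms, edges=list(m.bonds))
    colors = _element_colors(m.elements)
    perm = g.canonical_permutation(color=colors)
    relabeled = sorted(
        tuple(sorted((perm[i], perm[j]))) for i, j in m.bonds
    )
    new_elements = [""] * m.n_atoms
    for old, new in enumerate(perm):
        new_elements[new] = m.elements[old]
    return json.dumps([new_elements, relabeled], separators=(",", ":"))


def canonical_key(m: MoleculeGraph, mode: str = "isomorphism") -> CanonicalKey:
    """Identity key for a molecule under the chosen identity mode.

    ``isomorphism``: equal keys iff the element-labeled graphs are isomorphic
    (BLISS canonical form).  ``embedding``: equal keys iff the fragments embed
    the same original target atoms and bonds (requires provenance).
    """
    if mode == "isomorphism":
        return CanonicalKey("iso:" + _canonical_certificate(m))
    if mode == "embedding":
        if m.atom_provenance is None or m.bond_provenance is None:
            raise MoleculeError("embedding identity requires provenance")
        return CanonicalKey(
            "emb:a%s:b%s"
            % (sorted(m.atom_provenance), sorted(m.bond_provenance))
        )
    raise ValueError(f"unknown identity mode: {mode!r}")


# ---------------------------------------------------------------------------
# Fragmenting


def remove_bonds(
    m: MoleculeGraph, subset: Iterable[int]
) -> list[tuple[MoleculeGraph, dict[int, int]]]:
    """Connected components of ``m`` minus the given bonds.

    Returns ``(fragment, atom_map)`` pairs, where ``atom_map`` sends fragment
    atom indices to atom indices of ``m``; components are ordered by canonical
    key (ties broken by smallest mapped atom) for determinism.
    """
    subset = frozenset(subset)
    bad = [b for b in subset if not 0 <= b < len(m.bonds)]
    if bad:
        raise MoleculeError(f"unknown bond ids: {sorted(bad)}")
    g = m.to_networkx()
    for b in subset:
        g.remove_edge(*m.bonds[b])
    out = []
    for comp in nx.connected_components(g):
        atoms = sorted(comp)
        local = {a: i for i, a in enumerate(atoms)}
        elements = tuple(m.elements[a] for a in atoms)
        frag_bonds = []
        frag_bond_prov = []
        for b, (i, j) in enumerate(m.bonds):
            if b in subset or i not in comp:
                continue
            frag_bonds.append((local[i], local[j]))
            if m.bond_provenance is not None:
                frag_bond_prov.append(m.bond_provenance[b])
        atom_prov = (
            tuple(m.atom_provenance[a] for a in atoms)
            if m.atom_provenance is not None
            else None
        )
        frag = MoleculeGraph(
            elements,
            tuple(frag_bonds),
            atom_prov,
            tuple(frag_bond_prov) if m.bond_provenance is not None else None,
        )
        out.append((frag, {i: a for a, i in local.items()}))
    out.sort(key=lambda fa: (canonical_key(fa[0]).key, min(fa[1].values())))
    return out


# ---------------------------------------------------------------------------
# Automorphisms and bond-set orbits


def automorphisms(m: MoleculeGraph) -> list[tuple[int, ...]]:
    """All automorphisms of the element-labeled graph, as vertex images."""
    g = ig.Graph(n=m.n_atoms, edges=list(m.bonds))
    colors = _element_colors(m.elements)
    maps = g.get_isomorphisms_vf2(g, color1=colors, color2=colors)
    return sorted(tuple(p) for p in maps)


def bond_permutations(m: MoleculeGraph) -> list[tuple[int, ...]]:
    """The automorphism group's induced action on bond identifiers."""
    index = {frozenset(b): i for i, b in enumerate(m.bonds)}
    perms = set()
    for p in automorphisms(m):
        perms.add(
            tuple(index[frozenset((p[i], p[j]))] for i, j in m.bonds)
        )
    return sorted(perms)


def enumerate_bond_set_classes(target: MoleculeGraph, k: int) -> list[BondSet]:
    """One representative per orbit of k-subsets of bonds under Aut(target).

    The representative is the lexicographically least member set within its
    orbit; representatives are returned in lexicographic order.
    """
    nb = len(target.bonds)
    if not 0 <= k <= nb:
        raise MoleculeError(f"k={k} out of range 0..{nb}")
    perms = bond_permutations(target)
    reps: set[tuple[int, ...]] = set()
    for subset in itertools.combinations(range(nb), k):
        rep = min(tuple(sorted(p[b] for b in subset)) for p in perms)
        reps.add(rep)
    return [BondSet(target, frozenset(r)) for r in sorted(reps)]


def orbit_size(target: MoleculeGraph, members: frozenset[int]) -> int:
    """Number of distinct k-subsets in the orbit of ``members``."""
    perms = bond_permutations(target)
    return len({frozenset(p[b] for b in members) for p in perms})
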