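"""HoR construction, the plan <-> hyperpath bijection, and tree expansion."""

import json
import random

import pytest

from hyperroute.hor import (
    AFFIXATION,
    CYCLIZATION,
    DUMMY,
    HoR,
    PlanTree,
    build_hor_from_bond_set,
    build_hor_from_reactions,
    expand_to_tree,
    hyperpath_to_plan,
    plan_to_hyperpath,
)
from hyperroute.hypergraph import hypergraph_size, is_acyclic
from hyperroute.ksh import enumerate_all_hyperpaths
from hyperroute.molecules import BondSet, MoleculeGraph, decalin, remove_bonds

from conftest import brute_force_plans, hyperpath_plan_signature


@pytest.fixture(scope="module")
def fig_hor():
    """HoR of the three-plan bond set with 6+2+2-carbon chain fragments."""
    d = decalin()
    return build_hor_from_bond_set(d, BondSet(d, frozenset({1, 3, 7, 9})))


class TestBuildFromBondSet:
    def test_empty_bond_set_is_trivial(self):
        d = decalin()
        hor = build_hor_from_bond_set(d, BondSet(d, frozenset()))
        assert set(hor.graph.vertices) == {0, 1}
        assert [hor.arc_kinds[e.id] for e in hor.graph.arcs] == [DUMMY]
        assert len(enumerate_all_hyperpaths(hor.graph, 0, 1)) == 1

    def test_three_fragment_bond_set_arc_roles(self):
        """Three pairwise non-isomorphic fragments: every plan uses
        2 affixations, 2 cyclizations, and 3 dummy arcs."""
        d = decalin()
        assert len(remove_bonds(d, {1, 2, 4, 8})) == 3
        hor = build_hor_from_bond_set(d, BondSet(d, frozenset({1, 2, 4, 8})))
        paths = enumerate_all_hyperpaths(hor.graph, hor.source, hor.target_vertex)
        assert len(paths) >= 1
        for pi in paths:
            kinds = sorted(hor.arc_kinds[a] for a in pi.arcs)
            assert kinds == [AFFIXATION] * 2 + [CYCLIZATION] * 2 + [DUMMY] * 3

    def test_isomorphic_fragments_share_a_vertex(self, fig_hor):
        """The 6+2+2 bond set has two isomorphic 2-carbon chains: one HoR
        vertex fed by one dummy arc, consumed by two different affixations."""
        paths = enumerate_all_hyperpaths(
            fig_hor.graph, fig_hor.source, fig_hor.target_vertex
        )
        assert len(paths) == 3
        for pi in paths:
            kinds = sorted(fig_hor.arc_kinds[a] for a in pi.arcs)
            assert kinds == [AFFIXATION] * 2 + [CYCLIZATION] * 2 + [DUMMY] * 2
            affix_tails = [
                fig_hor.graph.arc(a).tail
                for a in pi.arcs
                if fig_hor.arc_kinds[a] == AFFIXATION
            ]
            two_carbon = {
                v
                for t in affix_tails
                for v in t
                if fig_hor.molecules[v].carbon_count == 2
            }
            assert len(two_carbon) == 1  # the same vertex in both tails

    def test_twin_halves_give_doubled_tail(self):
        """Cutting decalin into two isomorphic 5-chains: affixation arcs
        carry the merged vertex twice in their tail multiset."""
        d = decalin()
        hor = build_hor_from_bond_set(d, BondSet(d, frozenset({4, 5, 10})))
        doubled = [
            e
            for e in hor.graph.arcs
            if len(e.tail) == 2 and e.tail[0] == e.tail[1]
        ]
        assert doubled
        assert all(hor.molecules[e.tail[0]].carbon_count == 5 for e in doubled)

    def test_every_hor_invariant(self, decalin_k4):
        for rec in decalin_k4:
            g = rec.hor.graph
            assert is_acyclic(g)
            assert hypergraph_size(g) <= 3 * len(g.arcs)
            for e in g.arcs:
                if rec.hor.arc_kinds[e.id] != DUMMY:
                    assert len(e.tail) in (1, 2)
            for v in rec.hor.starting_vertices:
                dummies = [
                    e for e in g.arcs
                    if e.head == v and rec.hor.arc_kinds[e.id] == DUMMY
                ]
                assert len(dummies) == 1

    def test_foreign_bond_set_rejected(self):
        d = decalin()
        other = MoleculeGraph(("C", "C"), ((0, 1),))
        with pytest.raises(Exception, match="target"):
            build_hor_from_bond_set(d, BondSet(other, frozenset({0})))

    def test_json_round_trip(self, fig_hor):
        clone = HoR.from_json(fig_hor.to_json())
        assert clone.graph.vertices == fig_hor.graph.vertices
        assert clone.graph.arcs == fig_hor.graph.arcs
        assert clone.arc_kinds == fig_hor.arc_kinds
        assert clone.target_vertex == fig_hor.target_vertex
        for v, m in fig_hor.molecules.items():
            assert clone.molecules[v].carbon_count == m.carbon_count


class TestBuildFromReactions:
    def test_single_affixation(self):
        a = MoleculeGraph(("C",), ())
        b = MoleculeGraph(("C", "C"), ((0, 1),))
        t = MoleculeGraph(("C", "C", "C"), ((0, 1), (1, 2)))
        hor = build_hor_from_reactions([([a, b], t)], [a, b])
        assert len(enumerate_all_hyperpaths(hor.graph, hor.source, hor.target_vertex)) == 1

    def test_two_bond_addition_rejected(self):
        a = MoleculeGraph(("C",), ())
        square = MoleculeGraph(("C",) * 4, ((0, 1), (1, 2), (2, 3), (0, 3)))
        chain = MoleculeGraph(("C", "C", "C"), ((0, 1), (1, 2)))
        with pytest.raises(ValueError, match="exactly one bond"):
            build_hor_from_reactions([([a, chain], square)], [a, chain])

    def test_unused_starting_material_rejected(self):
        a = MoleculeGraph(("C",), ())
        b = MoleculeGraph(("C", "C"), ((0, 1),))
        with pytest.raises(ValueError, match="never used"):
            build_hor_from_reactions([([a, a], b)], [a, b])

    def test_combined_plans_rebuild_the_same_hor(self, fig_hor):
        """Merging the reactions of all three plans reproduces a HoR with
        exactly three hyperpaths."""
        paths = enumerate_all_hyperpaths(
            fig_hor.graph, fig_hor.source, fig_hor.target_vertex
        )
        reactions, starting = [], {}
        for pi in paths:
            plan = hyperpath_to_plan(fig_hor, pi)
            for parent, kids in plan.building_blocks.items():
                reactions.append(
                    ([plan.molecules[c] for c in kids], plan.molecules[parent])
                )
            for leaf in plan.leaves:
                starting[leaf] = plan.molecules[leaf]
        rebuilt = build_hor_from_reactions(
            reactions, list(starting.values())
        )
        again = enumerate_all_hyperpaths(
            rebuilt.graph, rebuilt.source, rebuilt.target_vertex
        )
        assert len(again) == 3


class TestBijection:
    def test_round_trip_is_identity(self, fig_hor, decalin_k4):
        sample = [rec.hor for rec in decalin_k4[::9]] + [fig_hor]
        for hor in sample:
            for pi in enumerate_all_hyperpaths(hor.graph, hor.source, hor.target_vertex):
                plan = hyperpath_to_plan(hor, pi)
                back = plan_to_hyperpath(hor, plan)
                assert back.arc_set == pi.arc_set
                assert back.target == pi.target

    def test_map_is_injective(self, decalin_k4):
        for rec in decalin_k4[::7]:
            sigs = {
                hyperpath_to_plan(rec.hor, pi).signature()
                for pi in rec.hyperpaths
            }
            assert len(sigs) == len(rec.hyperpaths)

    def test_trivial_hyperpath_gives_single_vertex_plan(self):
        d = decalin()
        hor = build_hor_from_bond_set(d, BondSet(d, frozenset()))
        [pi] = enumerate_all_hyperpaths(hor.graph, hor.source, hor.target_vertex)
        plan = hyperpath_to_plan(hor, pi)
        assert plan.building_blocks == {} and plan.leaves == [plan.root]

    def test_foreign_plan_rejected(self, fig_hor):
        d = decalin()
        other = build_hor_from_bond_set(d, BondSet(d, frozenset({0, 1, 2, 4})))
        pi = enumerate_all_hyperpaths(other.graph, other.source, other.target_vertex)[0]
        plan = hyperpath_to_plan(other, pi)
        with pytest.raises(ValueError, match="absent from the HoR"):
            plan_to_hyperpath(fig_hor, plan)


class TestBruteForcePlanner:
    @pytest.mark.parametrize("members", [
        frozenset({1, 3, 7, 9}),
        frozenset({0, 1, 3, 4}),
        frozenset({5}),
        frozenset({0, 2, 4}),
    ])
    def test_bond_addition_orders_give_identical_plan_set(self, members):
        """Under embedding identity, enumerating every order of bond
        additions and deduplicating plan DAGs yields exactly the
        hyperpath-derived plan set."""
        d = decalin()
        bs = BondSet(d, members)
        hor = build_hor_from_bond_set(d, bs, "embedding")
        via_hyperpaths = {
            hyperpath_plan_signature(hor, pi)
            for pi in enumerate_all_hyperpaths(hor.graph, hor.source, hor.target_vertex)
        }
        assert via_hyperpaths == brute_force_plans(d, bs, "embedding")

    def test_isomorphism_identity_admits_hybrid_plans(self):
        """Merging isomorphic intermediates can only enlarge the plan set:
        every order-of-addition plan survives, and hybrid plans mixing
        sub-plans of different embeddings may appear on top."""
        d = decalin()
        bs = BondSet(d, frozenset({0, 1, 2, 4}))
        hor = build_hor_from_bond_set(d, bs)
        via_hyperpaths = {
            hyperpath_plan_signature(hor, pi)
            for pi in enumerate_all_hyperpaths(hor.graph, hor.source, hor.target_vertex)
        }
        ordered = brute_force_plans(d, bs)
        assert ordered < via_hyperpaths  # 16 realizable orders, 36 plans


class TestTreeExpansion:
    def test_unshared_plan_tree_matches_dag(self):
        """With pairwise non-isomorphic fragments nothing is shared, so the
        tree is the DAG and leaves map 1-1 to starting materials."""
        d = decalin()
        hor = build_hor_from_bond_set(d, BondSet(d, frozenset({1, 2, 4, 8})))
        for pi in enumerate_all_hyperpaths(hor.graph, hor.source, hor.target_vertex):
            plan = hyperpath_to_plan(hor, pi)
            tree = expand_to_tree(plan)
            assert tree.n_nodes == len(plan.vertex_set())
            assert sorted(m.carbon_count for m in tree.leaf_labels()) == sorted(
                plan.molecules[v].carbon_count for v in plan.leaves
            )

    def test_shared_leaf_is_duplicated_in_tree(self, fig_hor):
        """The merged 4-carbon chain appears once in the DAG but twice in
        the expanded tree."""
        for pi in enumerate_all_hyperpaths(
            fig_hor.graph, fig_hor.source, fig_hor.target_vertex
        ):
            plan = hyperpath_to_plan(fig_hor, pi)
            tree = expand_to_tree(plan)
            assert len(plan.leaves) == 2 and len(tree.leaf_labels()) == 3
            assert tree.n_nodes == len(plan.vertex_set()) + 1

    def test_shared_subplan_is_duplicated(self):
        """A 4-carbon target built from two identical 2-carbon halves: the
        shared half's sub-plan appears twice in the tree."""
        d = MoleculeGraph(("C",) * 4, ((0, 1), (1, 2), (2, 3), (0, 3)))
        d = d.with_identity_provenance()
        hor = build_hor_from_bond_set(d, BondSet(d, frozenset({0, 1, 2, 3})))
        paths = enumerate_all_hyperpaths(hor.graph, hor.source, hor.target_vertex)
        shared = []
        for pi in paths:
            plan = hyperpath_to_plan(hor, pi)
            tree = expand_to_tree(plan)
            if tree.n_nodes > len(plan.vertex_set()):
                shared.append((plan, tree))
        assert shared, "expected at least one plan with a shared intermediate"
        for plan, tree in shared:
            dup = tree.n_nodes - len(plan.vertex_set())
            assert dup > 0
            assert len(tree.leaf_labels()) == len(
                [l for l in _leaves_with_multiplicity(plan)]
            )


def _leaves_with_multiplicity(plan):
    out = []

    def walk(v):
        kids = plan.building_blocks.get(v, ())
        if not kids:
            out.append(v)
        for c in kids:
            walk(c)

    walk(plan.root)
    return out
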