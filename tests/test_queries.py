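"""Tests for the five neighborhood queries, against an independent BFS oracle."""

import random

import pytest

from conftest import bfs_distance_oracle, shared_pool_adjacency
from smda import MetabolicNetwork, ValidationError
from smda.fixtures import FixtureSpec, make_random_network
from smda.queries import (
    StepMetric,
    metabolites_within_steps,
    pathways_within_steps,
    reactions_involving_metabolite,
    reactions_within_steps_in_network,
    reactions_within_steps_in_pathway,
)


def linear_pathway_network():
    """A -> r1 -> B -> r2 -> C -> r3 -> D, all in one pathway."""
    net = MetabolicNetwork()
    cyt = net.add_compartment("cyt", "cytosol")
    pools = {}
    for m in "abcd":
        net.add_metabolite(m, m.upper())
        pools[m] = net.get_or_create_pool(m, cyt)
    net.add_reaction("r1", "step one", [(pools["a"], "substrate"), (pools["b"], "product")])
    net.add_reaction("r2", "step two", [(pools["b"], "substrate"), (pools["c"], "product")])
    net.add_reaction("r3", "step three", [(pools["c"], "substrate"), (pools["d"], "product")])
    net.add_pathway("pw", "Linear Pathway", ["r1", "r2", "r3"])
    return net


class TestPathwaysWithinSteps:
    def test_distance_zero_means_shared_reaction(self, urea_network):
        net = urea_network
        assert pathways_within_steps(net, "Urea Cycle", 0) == []

    def test_urea_neighbours_at_one_step(self, urea_network):
        result = pathways_within_steps(urea_network, "Urea Cycle", 1)
        assert [(p.name, d) for p, d in result] == [
            ("Purine Biosynthesis", 1),
            ("Pyrimidine Biosynthesis", 1),
        ]

    def test_large_n_reaches_the_whole_component(self, urea_network):
        result = pathways_within_steps(urea_network, "Urea Cycle", 99)
        assert len(result) == 2

    def test_negative_n_rejected(self, urea_network):
        with pytest.raises(ValidationError):
            pathways_within_steps(urea_network, "Urea Cycle", -1)

    def test_shared_reaction_is_distance_zero(self):
        net = linear_pathway_network()
        net.add_pathway("pw2", "Overlapping Pathway", ["r2"])
        result = pathways_within_steps(net, "Linear Pathway", 0)
        assert [(p.name, d) for p, d in result] == [("Overlapping Pathway", 0)]


class TestReactionsWithinSteps:
    def test_source_is_excluded_at_n_zero(self):
        net = linear_pathway_network()
        assert reactions_within_steps_in_pathway(net, "step two", "Linear Pathway", 0) == []
        assert reactions_within_steps_in_network(net, "step two", 0) == []

    def test_middle_reaction_sees_both_neighbours(self):
        net = linear_pathway_network()
        result = reactions_within_steps_in_pathway(net, "step two", "Linear Pathway", 1)
        assert [(r.id, d) for r, d in result] == [("r1", 1), ("r3", 1)]

    def test_membership_is_enforced(self):
        net = linear_pathway_network()
        net.add_metabolite("x", "X")
        net.add_metabolite("y", "Y")
        px = net.get_or_create_pool("x", "cytosol")
        py = net.get_or_create_pool("y", "cytosol")
        net.add_reaction("r4", "stray", [(px, "substrate"), (py, "product")])
        with pytest.raises(ValidationError):
            reactions_within_steps_in_pathway(net, "stray", "Linear Pathway", 1)

    def test_pathway_results_are_a_subset_of_network_results(self, urea_network):
        for rxn in urea_network.pathways["urea_cycle"].reactions:
            for n in (1, 2):
                inside = {
                    r.id
                    for r, _ in reactions_within_steps_in_pathway(
                        urea_network, rxn, "Urea Cycle", n
                    )
                }
                everywhere = {
                    r.id
                    for r, _ in reactions_within_steps_in_network(urea_network, rxn, n)
                }
                assert inside <= everywhere

    def test_otc_neighbours_in_urea_fixture(self, urea_network):
        result = reactions_within_steps_in_network(
            urea_network, "ornithine transcarbamoylase", 1
        )
        assert {r.id for r, _ in result} == {
            "cps1", "orn_transport", "cit_transport", "atcase",
        }

    def test_bfs_oracle_agreement_on_random_networks(self):
        for seed in range(60):
            rng = random.Random(seed)
            net = make_random_network(
                FixtureSpec(seed=seed, n_reactions=rng.randint(3, 10),
                            n_metabolites=rng.randint(4, 11))
            )
            adjacency = shared_pool_adjacency(net)
            src = rng.choice(sorted(net.reactions))
            n = rng.randint(0, 4)
            expected = {
                rid: d
                for rid, d in bfs_distance_oracle(adjacency, [src]).items()
                if d <= n and rid != src
            }
            got = {
                r.id: d for r, d in reactions_within_steps_in_network(net, src, n)
            }
            assert got == expected, seed

    def test_results_grow_monotonically_with_n(self, urea_network):
        previous = set()
        for n in range(5):
            current = {
                r.id
                for r, _ in reactions_within_steps_in_network(
                    urea_network, "arginase", n
                )
            }
            assert previous <= current
            previous = current


class TestRoleQuery:
    def test_substrate_and_product_roles_are_disjoint_here(self, urea_network):
        subs = reactions_involving_metabolite(
            urea_network, "Ornithine", "substrate", "Urea Cycle"
        )
        prods = reactions_involving_metabolite(
            urea_network, "Ornithine", "product", "Urea Cycle"
        )
        assert {r.id for r in subs} == {"otc", "orn_transport"}
        assert {r.id for r in prods} == {"orn_transport", "arg1"}

    def test_any_role_is_the_union(self, urea_network):
        union = set()
        for role in ("substrate", "product", "activator", "inhibitor"):
            union |= {
                r.id
                for r in reactions_involving_metabolite(
                    urea_network, "L-Aspartate", role, "Urea Cycle"
                )
            }
        any_role = {
            r.id
            for r in reactions_involving_metabolite(
                urea_network, "L-Aspartate", "any", "Urea Cycle"
            )
        }
        assert any_role == union

    def test_absent_metabolite_yields_empty(self, urea_network):
        assert reactions_involving_metabolite(urea_network, "IMP", "any", "Urea Cycle") == []

    def test_unknown_role_rejected(self, urea_network):
        with pytest.raises(ValidationError):
            reactions_involving_metabolite(urea_network, "Urea", "catalyst", "Urea Cycle")


class TestMetabolitesWithinSteps:
    def test_one_reaction_hop(self):
        net = linear_pathway_network()
        result = metabolites_within_steps(net, "A", 1)
        assert [(m.name, d) for m, d in result] == [("B", 1)]
        back = metabolites_within_steps(net, "B", 1)
        assert ("A", 1) in [(m.name, d) for m, d in back]

    def test_n_below_one_rejected(self):
        net = linear_pathway_network()
        with pytest.raises(ValidationError):
            metabolites_within_steps(net, "A", 0)

    def test_bfs_oracle_agreement(self):
        for seed in range(40):
            rng = random.Random(1000 + seed)
            net = make_random_network(
                FixtureSpec(seed=seed, n_reactions=rng.randint(3, 9),
                            n_metabolites=rng.randint(4, 10))
            )
            met = net.metabolites[rng.choice(sorted(net.metabolites))]
            n = rng.randint(1, 3)
            # oracle over the bipartite graph, counted in reaction hops
            adjacency = {}
            for rxn in net.reactions.values():
                for pool in rxn.pools():
                    adjacency.setdefault(("R", rxn.id), set()).add(("P", pool.id))
                    adjacency.setdefault(("P", pool.id), set()).add(("R", rxn.id))
            sources = [
                ("P", p.id) for p in net.pools.values() if p.metabolite is met
            ]
            dist = bfs_distance_oracle(adjacency, sources)
            expected = {}
            for (kind, eid), d in dist.items():
                if kind != "P":
                    continue
                other = net.pools[eid].metabolite
                if other is met:
                    continue
                hops = (d + 1) // 2
                if hops <= n:
                    expected[other.id] = min(expected.get(other.id, hops), hops)
            got = {m.id: d for m, d in metabolites_within_steps(net, met, n)}
            assert got == expected, seed


class TestCurrencyExclusion:
    def make_hub_network(self):
        net = MetabolicNetwork()
        cyt = net.add_compartment("cyt", "cytosol")
        for m in ("a", "b", "c", "d"):
            net.add_metabolite(m, m.upper())
        net.add_metabolite("atp", "ATP")
        pools = {m: net.get_or_create_pool(m, cyt) for m in ("a", "b", "c", "d", "atp")}
        # r1 and r2 share only ATP; r2 and r3 share C
        net.add_reaction("r1", "alpha", [(pools["a"], "substrate"), (pools["b"], "product"),
                                         (pools["atp"], "substrate")])
        net.add_reaction("r2", "beta", [(pools["c"], "substrate"), (pools["atp"], "substrate"),
                                        (pools["d"], "product")])
        net.add_reaction("r3", "gamma", [(pools["b"], "substrate"), (pools["c"], "product")])
        return net

    def test_exclusion_removes_cofactor_shortcuts(self):
        net = self.make_hub_network()
        with_atp = {r.id for r, _ in reactions_within_steps_in_network(net, "alpha", 1)}
        metric = StepMetric(frozenset({"ATP"}))
        without = {r.id for r, _ in reactions_within_steps_in_network(net, "alpha", 1, metric)}
        assert "r2" in with_atp
        assert "r2" not in without
        assert without < with_atp

    def test_exclusion_never_adds_results(self):
        for seed in range(20):
            net = make_random_network(FixtureSpec(seed=seed, n_reactions=7, n_metabolites=8))
            metric = StepMetric(frozenset({"metabolite 0", "metabolite 1"}))
            src = sorted(net.reactions)[0]
            for n in (1, 2, 3):
                full = {r.id for r, _ in reactions_within_steps_in_network(net, src, n)}
                reduced = {
                    r.id
                    for r, _ in reactions_within_steps_in_network(net, src, n, metric)
                }
                assert reduced <= full

    def test_unknown_exclusion_names_rejected(self, urea_network):
        with pytest.raises(ValidationError):
            reactions_within_steps_in_network(
                urea_network, "arginase", 1, StepMetric(frozenset({"Unobtainium"}))
            )
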