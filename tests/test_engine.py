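"""Unit and property tests for the scenario-enumeration engine."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from smda import (
    CapacityError,
    MetabolicNetwork,
    Observation,
    EnzymeObservation,
    PoolLabel,
    ReferenceRange,
    Scenario,
    SMDAConfig,
    SMDAEngine,
    TruthValue,
    ValidationError,
    brute_force_scenarios,
    enumerate_scenarios,
    expand,
    is_consistent,
    label_from_concentration,
    merge,
    select_subnetwork,
)
from smda.engine import (
    ACTIVE_FORWARD,
    INACTIVE,
    Conj,
    Disj,
    FlowGraph,
    Neg,
    PoolAtLeast,
    ReactionStatus,
    Direction,
    evaluate_condition,
    reaction_activation,
)
from smda.errors import NoReferenceRangeError
from smda.fixtures import make_random_case


def chain_network(boundary_a=False):
    """One irreversible reaction A -> B in a single compartment."""
    net = MetabolicNetwork("chain")
    cyt = net.add_compartment("cyt", "cytosol")
    net.add_metabolite("a", "A")
    net.add_metabolite("b", "B")
    pa = net.get_or_create_pool("a", cyt)
    pb = net.get_or_create_pool("b", cyt)
    net.add_reaction("r", "conversion", [(pa, "substrate"), (pb, "product")])
    sub = select_subnetwork(net, reactions=["r"], boundary=[pa] if boundary_a else [])
    return net, sub, pa, pb


class TestConcentrationLabeling:
    RANGE = ReferenceRange("X", 1.0, 5.0, 10.0)

    @pytest.mark.parametrize(
        "conc,expected",
        [
            (0.0, PoolLabel.UNAVAILABLE),
            (0.999, PoolLabel.UNAVAILABLE),
            (1.0, PoolLabel.AVAILABLE),   # lower bound inclusive
            (5.0, PoolLabel.AVAILABLE),   # upper bound inclusive
            (7.0, PoolLabel.ACCUMULATED),
            (10.0, PoolLabel.ACCUMULATED),
            (10.001, PoolLabel.SEVERELY_ACCUMULATED),
        ],
    )
    def test_threshold_table(self, conc, expected):
        assert label_from_concentration(conc, self.RANGE) is expected

    def test_unit_mismatch_is_rejected(self):
        with pytest.raises(ValidationError):
            label_from_concentration(2.0, self.RANGE, units="umol/L")

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            label_from_concentration(-1.0, self.RANGE)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValidationError):
            ReferenceRange("X", 5.0, 5.0, 10.0)

    def test_missing_range_raises_explicit_error(self):
        from smda import ReferenceRangeTable

        net, sub, pa, _ = chain_network()
        obs = Observation(pool=pa, concentration=2.0)
        with pytest.raises(NoReferenceRangeError):
            obs.resolve(ReferenceRangeTable([]))

    def test_labels_are_totally_ordered(self):
        labels = list(PoolLabel)
        assert labels == sorted(labels)
        assert PoolLabel.UNAVAILABLE < PoolLabel.AVAILABLE < PoolLabel.ACCUMULATED \
            < PoolLabel.SEVERELY_ACCUMULATED


class TestKleeneLogic:
    TV = [TruthValue.FALSE, TruthValue.UNKNOWN, TruthValue.TRUE]

    @given(st.sampled_from(TV), st.sampled_from(TV))
    def test_connectives_are_commutative(self, x, y):
        assert (x & y) is (y & x)
        assert (x | y) is (y | x)

    @given(st.sampled_from(TV), st.sampled_from(TV), st.sampled_from(TV))
    def test_connectives_are_associative(self, x, y, z):
        assert ((x & y) & z) is (x & (y & z))
        assert ((x | y) | z) is (x | (y | z))

    def test_false_absorbs_unknown(self):
        assert (TruthValue.FALSE & TruthValue.UNKNOWN) is TruthValue.FALSE
        assert (TruthValue.TRUE | TruthValue.UNKNOWN) is TruthValue.TRUE
        assert (~TruthValue.UNKNOWN) is TruthValue.UNKNOWN

    def test_atoms_over_unlabeled_pools_are_unknown(self):
        fg = FlowGraph(pool_labels={"p1": PoolLabel.ACCUMULATED})
        assert evaluate_condition(PoolAtLeast("p1", PoolLabel.AVAILABLE), fg) is TruthValue.TRUE
        assert evaluate_condition(PoolAtLeast("p2", PoolLabel.AVAILABLE), fg) is TruthValue.UNKNOWN
        cond = Conj((PoolAtLeast("p1", PoolLabel.AVAILABLE), PoolAtLeast("p2", PoolLabel.AVAILABLE)))
        assert evaluate_condition(cond, fg) is TruthValue.UNKNOWN
        cond = Conj((Neg(PoolAtLeast("p1", PoolLabel.AVAILABLE)), PoolAtLeast("p2", PoolLabel.AVAILABLE)))
        assert evaluate_condition(cond, fg) is TruthValue.FALSE
        assert evaluate_condition(Disj(()), fg) is TruthValue.FALSE

    def test_malformed_condition_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_condition("not a condition", FlowGraph())


class TestReactionActivation:
    def test_unavailable_enzyme_deactivates_regardless_of_labels(self, tca_input):
        sub, _, eobs = tca_input
        cs = sub.network.reactions["cs"]
        fg = FlowGraph(pool_labels={p.id: PoolLabel.AVAILABLE for p in cs.pools()})
        assert reaction_activation(cs, fg, eobs) is TruthValue.FALSE

    def test_available_substrates_suffice(self):
        net, sub, pa, pb = chain_network()
        fg = FlowGraph(pool_labels={pa.id: PoolLabel.AVAILABLE})
        assert reaction_activation(net.reactions["r"], fg) is TruthValue.TRUE

    def test_unlabeled_substrate_leaves_activation_unknown(self, urea_network):
        otc = urea_network.reactions["otc"]
        fg = FlowGraph(pool_labels={otc.substrates[0].id: PoolLabel.AVAILABLE})
        assert reaction_activation(otc, fg) is TruthValue.UNKNOWN

    def test_blocking_inhibitor_deactivates(self):
        net = MetabolicNetwork()
        cyt = net.add_compartment("cyt", "cytosol")
        for m in ("a", "b", "i"):
            net.add_metabolite(m, m.upper())
        pa, pb, pi = (net.get_or_create_pool(m, cyt) for m in ("a", "b", "i"))
        rxn = net.add_reaction(
            "r", "inhibited", [(pa, "substrate"), (pb, "product"), (pi, "inhibitor")]
        )
        fg = FlowGraph(pool_labels={pa.id: PoolLabel.AVAILABLE, pi.id: PoolLabel.ACCUMULATED})
        assert reaction_activation(rxn, fg) is TruthValue.FALSE
        fg.pool_labels[pi.id] = PoolLabel.AVAILABLE
        assert reaction_activation(rxn, fg) is TruthValue.TRUE


class TestConsistency:
    def test_everything_off_is_consistent(self):
        net, sub, pa, pb = chain_network()
        scenario = Scenario(
            reaction_status={"r": INACTIVE},
            pool_labels={pa.id: PoolLabel.UNAVAILABLE, pb.id: PoolLabel.UNAVAILABLE},
        )
        assert is_consistent(scenario, sub)

    def test_active_reaction_with_unavailable_substrate_is_inconsistent(self):
        net, sub, pa, pb = chain_network()
        scenario = Scenario(
            reaction_status={"r": ACTIVE_FORWARD},
            pool_labels={pa.id: PoolLabel.UNAVAILABLE, pb.id: PoolLabel.AVAILABLE},
        )
        assert not is_consistent(scenario, sub)

    def test_boundary_input_feeding_accumulation_is_consistent(self):
        net, sub, pa, pb = chain_network(boundary_a=True)
        scenario = Scenario(
            reaction_status={"r": ACTIVE_FORWARD},
            pool_labels={pa.id: PoolLabel.AVAILABLE, pb.id: PoolLabel.ACCUMULATED},
        )
        assert is_consistent(scenario, sub)

    def test_partial_scenario_rejected(self):
        net, sub, pa, pb = chain_network()
        scenario = Scenario(reaction_status={"r": INACTIVE}, pool_labels={})
        with pytest.raises(ValidationError):
            is_consistent(scenario, sub)

    def test_exhaustive_singleton_reaction_census(self):
        """Hand enumeration of all 2*4*4 assignments of the A -> B chain.

        Without a boundary flag the consumer-needs-producer rule forbids any
        active scenario (A has no producer), and inactive scenarios allow only
        unavailable/available on each side: exactly 4 consistent assignments.
        With A flagged as a boundary input there are 8 inactive ones
        (A free, B in {unavailable, available}) plus 9 active ones
        (A and B each in the three labels at or above available).
        """
        for boundary, expected in ((False, 4), (True, 17)):
            net, sub, pa, pb = chain_network(boundary_a=boundary)
            consistent = []
            for status in (INACTIVE, ACTIVE_FORWARD):
                for la in PoolLabel:
                    for lb in PoolLabel:
                        sc = Scenario(
                            reaction_status={"r": status},
                            pool_labels={pa.id: la, pb.id: lb},
                        )
                        if is_consistent(sc, sub):
                            consistent.append(sc)
            assert len(consistent) == expected
            assert {s.key() for s in consistent} == {
                s.key() for s in brute_force_scenarios(sub)
            }


class TestExpansionAndMerge:
    def test_expand_with_empty_frontier_is_a_no_op(self):
        net, sub, pa, pb = chain_network()
        fg = FlowGraph(
            pool_labels={pa.id: PoolLabel.AVAILABLE, pb.id: PoolLabel.AVAILABLE},
            reaction_status={"r": ACTIVE_FORWARD},
        )
        assert expand(fg, sub) == [fg]

    def test_unavailable_substrates_leave_only_the_inactive_branch(self):
        net, sub, pa, pb = chain_network()
        fg = FlowGraph(
            pool_labels={pa.id: PoolLabel.UNAVAILABLE},
            frontier=[("R", "r")],
        )
        children = expand(fg, sub)
        assert [c.reaction_status["r"] for c in children] == [INACTIVE]

    def test_pool_next_to_inactive_producer_cannot_accumulate(self):
        net, sub, pa, pb = chain_network()
        fg = FlowGraph(reaction_status={"r": INACTIVE}, frontier=[("P", pb.id)])
        children = expand(fg, sub)
        labels = {c.pool_labels[pb.id] for c in children}
        assert labels == {PoolLabel.UNAVAILABLE, PoolLabel.AVAILABLE}

    def test_merge_unions_disjoint_graphs(self):
        g1 = FlowGraph(pool_labels={"p1": PoolLabel.AVAILABLE})
        g2 = FlowGraph(reaction_status={"r1": INACTIVE})
        merged = merge([g1, g2])
        assert len(merged) == 1
        assert merged[0].pool_labels == {"p1": PoolLabel.AVAILABLE}
        assert merged[0].reaction_status == {"r1": INACTIVE}

    def test_merge_keeps_disagreeing_graphs_apart(self):
        g1 = FlowGraph(pool_labels={"p1": PoolLabel.AVAILABLE})
        g2 = FlowGraph(pool_labels={"p1": PoolLabel.UNAVAILABLE})
        assert len(merge([g1, g2])) == 2

    def test_merge_is_order_independent_on_disjoint_triples(self):
        g1 = FlowGraph(pool_labels={"p1": PoolLabel.AVAILABLE})
        g2 = FlowGraph(pool_labels={"p2": PoolLabel.ACCUMULATED})
        g3 = FlowGraph(reaction_status={"r1": ACTIVE_FORWARD})
        reference = None
        for perm in itertools.permutations([g1, g2, g3]):
            result = sorted(fg.key() for fg in merge(list(perm)))
            reference = reference or result
            assert result == reference
        assert len(reference) == 1


class TestEngineStepping:
    def test_first_step_builds_one_flow_graph_per_observation(self, tca_input):
        sub, obs, eobs = tca_input
        net = sub.network
        more_obs = obs + [
            Observation(pool=net.pool_of("suc", "mitochondrion"), label=PoolLabel.AVAILABLE)
        ]
        engine = SMDAEngine(sub, more_obs, eobs)
        engine.step()
        assert len(engine.population) == len(more_obs)
        for fg in engine.population:
            assert len(fg.pool_labels) == 1 and not fg.reaction_status

    def test_step_counter_increases_until_finish_then_freezes(self, tca_input):
        sub, obs, eobs = tca_input
        engine = SMDAEngine(sub, obs, eobs)
        counts = []
        while not engine.finished:
            engine.step()
            counts.append(engine.step_count)
        assert counts == list(range(1, len(counts) + 1))
        frozen = engine.step_count
        engine.step()
        assert engine.step_count == frozen

    def test_stepwise_execution_matches_one_shot_enumeration(self, tca_input):
        sub, obs, eobs = tca_input
        engine = SMDAEngine(sub, obs, eobs)
        while not engine.finished:
            engine.step()
        stepped = [s.key() for s in engine.scenarios()]
        oneshot = [s.key() for s in enumerate_scenarios(sub, obs, eobs)]
        assert stepped == oneshot


class TestEnumeration:
    def test_matches_brute_force_on_seeded_random_inputs(self):
        for seed in range(30):
            sub, obs, eobs = make_random_case(seed)
            fast = {s.key() for s in enumerate_scenarios(sub, obs, eobs,
                                                         config=SMDAConfig(cap=100_000))}
            slow = {s.key() for s in brute_force_scenarios(sub, obs, eobs)}
            assert fast == slow, f"seed {seed}"

    def test_enzyme_observation_deactivates_its_reaction(self, tca_input):
        sub, obs, eobs = tca_input
        scenarios = enumerate_scenarios(sub, obs, eobs)
        assert scenarios
        assert all(s.reaction_status["cs"].flux == 0 for s in scenarios)

    def test_every_scenario_is_total_with_binary_flux(self, tca_input):
        sub, obs, eobs = tca_input
        rids = {r.id for r in sub.reactions}
        pids = {p.id for p in sub.pools}
        for s in enumerate_scenarios(sub, obs, eobs):
            assert set(s.reaction_status) == rids
            assert set(s.pool_labels) == pids
            assert all(st.flux in (0, 1) for st in s.reaction_status.values())
            assert all(lab in PoolLabel for lab in s.pool_labels.values())

    def test_adding_an_observation_never_adds_scenarios(self):
        checked = 0
        for seed in range(12):
            sub, obs, eobs = make_random_case(seed)
            base = enumerate_scenarios(sub, obs, eobs, config=SMDAConfig(cap=100_000))
            if not base:
                continue
            observed = {o.pool.id for o in obs}
            template = base[seed % len(base)]
            extra_pid = next(
                pid for pid in sorted(template.pool_labels) if pid not in observed
            )
            extra = Observation(
                pool=sub.network.pools[extra_pid],
                label=template.pool_labels[extra_pid],
            )
            refined = enumerate_scenarios(
                sub, obs + [extra], eobs, config=SMDAConfig(cap=100_000)
            )
            assert {s.key() for s in refined} <= {s.key() for s in base}
            assert len(refined) <= len(base)
            checked += 1
        assert checked >= 3

    def test_strategies_agree(self, tca_input):
        sub, obs, eobs = tca_input
        bfs = enumerate_scenarios(sub, obs, eobs, config=SMDAConfig(strategy="breadth_first"))
        dfs = enumerate_scenarios(
            sub, obs, eobs, config=SMDAConfig(strategy="depth_first", seed=7)
        )
        assert [s.key() for s in bfs] == [s.key() for s in dfs]

    def test_deterministic_output(self, tca_input):
        from smda.io import scenarios_to_json

        sub, obs, eobs = tca_input
        cfg = SMDAConfig(strategy="depth_first", seed=11)
        a = scenarios_to_json(enumerate_scenarios(sub, obs, eobs, config=cfg))
        b = scenarios_to_json(enumerate_scenarios(sub, obs, eobs, config=cfg))
        assert a == b

    def test_cap_overflow_names_the_cap(self, tca_input):
        sub, obs, eobs = tca_input
        with pytest.raises(CapacityError, match="cap of 17"):
            enumerate_scenarios(sub, obs, eobs, config=SMDAConfig(cap=17))

    def test_conflicting_observations_rejected(self, tca_input):
        sub, obs, eobs = tca_input
        conflict = obs + [Observation(pool=obs[0].pool, label=PoolLabel.UNAVAILABLE)]
        with pytest.raises(ValidationError):
            enumerate_scenarios(sub, conflict, eobs)

    def test_disconnected_subnetwork_warns_but_runs(self):
        net = MetabolicNetwork()
        cyt = net.add_compartment("cyt", "cytosol")
        for m in ("a", "b", "c", "d"):
            net.add_metabolite(m, m.upper())
        pa, pb, pc, pd = (net.get_or_create_pool(m, cyt) for m in ("a", "b", "c", "d"))
        net.add_reaction("r1", "one", [(pa, "substrate"), (pb, "product")])
        net.add_reaction("r2", "two", [(pc, "substrate"), (pd, "product")])
        sub = select_subnetwork(net, reactions=["r1", "r2"])
        with pytest.warns(UserWarning, match="not connected"):
            scenarios = enumerate_scenarios(sub)
        assert {s.key() for s in scenarios} == {
            s.key() for s in brute_force_scenarios(sub)
        }


class TestBruteForceGuard:
    def test_oversized_subnetwork_rejected(self):
        from smda.fixtures import FixtureSpec, make_random_network

        net = make_random_network(FixtureSpec(seed=1, n_reactions=16, n_metabolites=18))
        sub = select_subnetwork(net, reactions=sorted(net.reactions))
        with pytest.raises(CapacityError):
            brute_force_scenarios(sub)

    def test_empty_subnetwork_rejected(self, urea_network):
        from smda.model import Subnetwork

        with pytest.raises(ValidationError):
            brute_force_scenarios(Subnetwork(network=urea_network, reactions=[]))

    def test_observation_pinning_filters_the_unpinned_set(self):
        net, sub, pa, pb = chain_network(boundary_a=True)
        free = brute_force_scenarios(sub)
        pinned = brute_force_scenarios(
            sub, [Observation(pool=pa, label=PoolLabel.AVAILABLE)]
        )
        assert {s.key() for s in pinned} < {s.key() for s in free}

    def test_reversible_reaction_directions_are_distinct_scenarios(self):
        net = MetabolicNetwork()
        cyt = net.add_compartment("cyt", "cytosol")
        net.add_metabolite("a", "A")
        net.add_metabolite("b", "B")
        pa = net.get_or_create_pool("a", cyt)
        pb = net.get_or_create_pool("b", cyt)
        net.add_reaction(
            "r", "isomerase", [(pa, "substrate"), (pb, "product")], reversible=True
        )
        sub = select_subnetwork(net, reactions=["r"], boundary=[pa, pb])
        scenarios = brute_force_scenarios(sub)
        directions = {
            (s.reaction_status["r"].flux, s.reaction_status["r"].direction)
            for s in scenarios
        }
        assert (1, Direction.FORWARD) in directions
        assert (1, Direction.BACKWARD) in directions
        assert {s.key() for s in scenarios} == {
            s.key() for s in enumerate_scenarios(sub)
        }
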