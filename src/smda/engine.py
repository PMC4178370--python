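"""Steady-state metabolic dynamics analysis (SMDA).

Given an open metabolic subnetwork and a set of metabolite/enzyme
observations, the engine enumerates every *scenario*: a total assignment of a
binary activity status (flux 0 or 1, plus a direction for active reversible
reactions) to each reaction and one of four ordered labels -- ``unavailable <
available < accumulated < severely_accumulated`` -- to each metabolite pool,
such that the assignment is consistent with the observations and a set of
steady-state biochemistry rules.

The rule set (R1-R6 below) instantiates the activation-condition-set idea as
explicit, overridable data:

R1  an active reaction has every direction-appropriate substrate labeled at or
    above the substrate-availability threshold (default: available);
R2  a reaction whose catalysing enzyme is observed unavailable is inactive;
R3  an active reaction has no inhibitor labeled at or above the blocking
    threshold (default: accumulated);
R4  a pool labeled unavailable has no active producer;
R5  a pool labeled accumulated or higher has at least one active producer,
    unless it is a boundary pool of the open subnetwork;
R6  a non-boundary pool that is consumed by an active reaction and labeled
    available or higher has at least one active producer.

Optionally (off by default) an active reaction that has activator participants
must see at least one activator labeled available or higher.

Enumeration runs as an iteration of two phases, Expansion and Merge: partial
assignments (*flow graphs*) start as one single-pool graph per observation,
are merged, and then repeatedly extended one frontier entity at a time,
branching over every label/status whose partial assignment is not already
definitely inconsistent (three-valued reasoning: only a definitely-false rule
prunes a branch).  A brute-force enumerator over total assignments serves as
an independent oracle on small inputs.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Mapping, Optional, Sequence

from .errors import CapacityError, NoReferenceRangeError, ValidationError
from .model import MetabolitePool, Reaction, Role, Subnetwork

__all__ = [
    "PoolLabel",
    "TruthValue",
    "Direction",
    "ReactionStatus",
    "ReferenceRange",
    "ReferenceRangeTable",
    "Observation",
    "EnzymeObservation",
    "ReactionRules",
    "ActivationConditionSet",
    "SMDAConfig",
    "FlowGraph",
    "Scenario",
    "SMDAEngine",
    "label_from_concentration",
    "evaluate_condition",
    "reaction_activation",
    "is_consistent",
    "expand",
    "merge",
    "enumerate_scenarios",
    "brute_force_scenarios",
    "PoolAtLeast",
    "Conj",
    "Disj",
    "Neg",
]


class PoolLabel(IntEnum):
    """Ordered categorical summary of a pool's concentration."""

    UNAVAILABLE = 0
    AVAILABLE = 1
    ACCUMULATED = 2
    SEVERELY_ACCUMULATED = 3

    def __str__(self) -> str:
        return self.name.lower()

    @classmethod
    def coerce(cls, value: "PoolLabel | str") -> "PoolLabel":
        if isinstance(value, PoolLabel):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValidationError(f"unknown pool label {value!r}") from None


class TruthValue(Enum):
    """Strong Kleene three-valued logic."""

    FALSE = 0
    UNKNOWN = 1
    TRUE = 2

    def __and__(self, other: "TruthValue") -> "TruthValue":
        if TruthValue.FALSE in (self, other):
            return TruthValue.FALSE
        if TruthValue.UNKNOWN in (self, other):
            return TruthValue.UNKNOWN
        return TruthValue.TRUE

    def __or__(self, other: "TruthValue") -> "TruthValue":
        if TruthValue.TRUE in (self, other):
            return TruthValue.TRUE
        if TruthValue.UNKNOWN in (self, other):
            return TruthValue.UNKNOWN
        return TruthValue.FALSE

    def __invert__(self) -> "TruthValue":
        if self is TruthValue.UNKNOWN:
            return TruthValue.UNKNOWN
        return TruthValue.TRUE if self is TruthValue.FALSE else TruthValue.FALSE

    @staticmethod
    def of(flag: bool) -> "TruthValue":
        return TruthValue.TRUE if flag else TruthValue.FALSE


class Direction(str, Enum):
    FORWARD = "forward"
    BACKWARD = "backward"


@dataclass(frozen=True)
class ReactionStatus:
    """Binary activity of a reaction; direction matters only for active reversibles."""

    flux: int
    direction: Direction = Direction.FORWARD

    def __post_init__(self) -> None:
        if self.flux not in (0, 1):
            raise ValidationError(f"flux must be 0 or 1, got {self.flux!r}")

    @property
    def active(self) -> bool:
        return self.flux == 1


INACTIVE = ReactionStatus(0, Direction.FORWARD)
ACTIVE_FORWARD = ReactionStatus(1, Direction.FORWARD)
ACTIVE_BACKWARD = ReactionStatus(1, Direction.BACKWARD)


@dataclass(frozen=True)
class ReferenceRange:
    """Normal/abnormal concentration cut-points for one metabolite.

    Stands in for an HMDB-style lookup: below ``low`` the pool is unavailable,
    within [low, high] available, within (high, severe_high] accumulated, and
    above ``severe_high`` severely accumulated.
    """

    metabolite: str
    low: float
    high: float
    severe_high: float
    units: str = "mmol/L"

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high < self.severe_high):
            raise ValidationError(
                f"reference range for {self.metabolite!r} must satisfy 0 < low < high < severe_high"
            )


class ReferenceRangeTable:
    """Case-insensitive reference-range lookup by metabolite name."""

    def __init__(self, ranges: Iterable[ReferenceRange] = ()) -> None:
        self._by_name: dict[str, ReferenceRange] = {}
        for rng in ranges:
            self._by_name[rng.metabolite.lower()] = rng

    def lookup(self, metabolite_name: str) -> ReferenceRange:
        rng = self._by_name.get(metabolite_name.lower())
        if rng is None:
            raise NoReferenceRangeError(
                f"no reference range for metabolite {metabolite_name!r}; "
                "supply an explicit label instead"
            )
        return rng

    def __len__(self) -> int:
        return len(self._by_name)


def label_from_concentration(concentration: float, reference_range: ReferenceRange,
                             units: Optional[str] = None) -> PoolLabel:
    """Map a measured concentration onto the four-label scale."""
    if concentration < 0:
        raise ValidationError("concentration must be non-negative")
    if units is not None and units != reference_range.units:
        raise ValidationError(
            f"units {units!r} do not match reference range units {reference_range.units!r}"
        )
    if concentration < reference_range.low:
        return PoolLabel.UNAVAILABLE
    if concentration <= reference_range.high:
        return PoolLabel.AVAILABLE
    if concentration <= reference_range.severe_high:
        return PoolLabel.ACCUMULATED
    return PoolLabel.SEVERELY_ACCUMULATED


@dataclass(frozen=True)
class Observation:
    """A measured metabolite pool: either a concentration or an explicit label."""

    pool: MetabolitePool
    concentration: Optional[float] = None
    units: Optional[str] = None
    label: Optional[PoolLabel] = None

    def __post_init__(self) -> None:
        if (self.concentration is None) == (self.label is None):
            raise ValidationError(
                "an observation carries exactly one of concentration or label"
            )

    def resolve(self, ranges: Optional[ReferenceRangeTable]) -> PoolLabel:
        if self.label is not None:
            return PoolLabel.coerce(self.label)
        if ranges is None:
            raise NoReferenceRangeError(
                f"observation of {self.pool.name} has a concentration but no "
                "reference-range table was provided"
            )
        rng = ranges.lookup(self.pool.metabolite.name)
        return label_from_concentration(self.concentration, rng, self.units)


@dataclass(frozen=True)
class EnzymeObservation:
    enzyme: str
    availability: str  # "available" | "unavailable"

    def __post_init__(self) -> None:
        if self.availability not in ("available", "unavailable"):
            raise ValidationError(
                f"enzyme availability must be 'available' or 'unavailable', got {self.availability!r}"
            )


@dataclass(frozen=True)
class ReactionRules:
    """Per-reaction activation-rule parameters."""

    substrate_threshold: PoolLabel = PoolLabel.AVAILABLE
    inhibitor_threshold: PoolLabel = PoolLabel.ACCUMULATED
    require_activator: bool = False


@dataclass(frozen=True)
class ActivationConditionSet:
    """Rule bundle deciding reaction activability from labels and regulators.

    ``default`` applies to ordinary reactions, ``transport`` to transport
    reactions (identical unless overridden); ``overrides`` maps reaction ids
    to bespoke rules.
    """

    default: ReactionRules = ReactionRules()
    transport: Optional[ReactionRules] = None
    overrides: Mapping[str, ReactionRules] = field(default_factory=dict)

    def rules_for(self, reaction: Reaction) -> ReactionRules:
        if reaction.id in self.overrides:
            return self.overrides[reaction.id]
        if reaction.is_transport and self.transport is not None:
            return self.transport
        return self.default


DEFAULT_ACS = ActivationConditionSet()


@dataclass(frozen=True)
class SMDAConfig:
    """Engine settings: frontier strategy, scenario cap, tie-break seed."""

    strategy: str = "breadth_first"
    cap: int = 10_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strategy not in ("breadth_first", "depth_first"):
            raise ValidationError(f"unknown iteration strategy {self.strategy!r}")
        if self.cap < 1:
            raise ValidationError("scenario cap must be >= 1")


# -- condition language ----------------------------------------------------


@dataclass(frozen=True)
class PoolAtLeast:
    """Atom: the pool's label is at or above a threshold."""

    pool_id: str
    threshold: PoolLabel


@dataclass(frozen=True)
class Conj:
    terms: tuple = ()


@dataclass(frozen=True)
class Disj:
    terms: tuple = ()


@dataclass(frozen=True)
class Neg:
    term: object = None


Condition = "PoolAtLeast | Conj | Disj | Neg"


def evaluate_condition(condition, flowgraph: "FlowGraph") -> TruthValue:
    """Kleene-evaluate a label condition over a (partial) flow graph.

    Atoms over unlabeled pools evaluate to unknown; unknown propagates through
    the connectives per the strong Kleene tables (false absorbs in AND, true
    in OR).
    """
    if isinstance(condition, TruthValue):
        return condition
    if isinstance(condition, PoolAtLeast):
        label = flowgraph.pool_labels.get(condition.pool_id)
        if label is None:
            return TruthValue.UNKNOWN
        return TruthValue.of(label >= condition.threshold)
    if isinstance(condition, Conj):
        out = TruthValue.TRUE
        for term in condition.terms:
            out = out & evaluate_condition(term, flowgraph)
            if out is TruthValue.FALSE:
                return out
        return out
    if isinstance(condition, Disj):
        out = TruthValue.FALSE
        for term in condition.terms:
            out = out | evaluate_condition(term, flowgraph)
            if out is TruthValue.TRUE:
                return out
        return out
    if isinstance(condition, Neg):
        return ~evaluate_condition(condition.term, flowgraph)
    raise ValidationError(f"malformed condition node: {condition!r}")


# -- flow graphs and scenarios ---------------------------------------------


@dataclass
class FlowGraph:
    """A partial assignment of pool labels and reaction statuses.

    ``frontier`` lists unassigned entities adjacent to assigned ones, in
    discovery order; entities are keyed ``("P", pool_id)`` / ``("R", rid)``.
    """

    pool_labels: dict[str, PoolLabel] = field(default_factory=dict)
    reaction_status: dict[str, ReactionStatus] = field(default_factory=dict)
    frontier: list[tuple[str, str]] = field(default_factory=list)

    def copy(self) -> "FlowGraph":
        return FlowGraph(
            pool_labels=dict(self.pool_labels),
            reaction_status=dict(self.reaction_status),
            frontier=list(self.frontier),
        )

    def assigned(self, entity: tuple[str, str]) -> bool:
        kind, eid = entity
        return eid in (self.pool_labels if kind == "P" else self.reaction_status)

    def key(self) -> tuple:
        return (
            tuple(sorted((k, int(v)) for k, v in self.pool_labels.items())),
            tuple(
                sorted(
                    (k, v.flux, v.direction.value)
                    for k, v in self.reaction_status.items()
                )
            ),
        )

    def compatible(self, other: "FlowGraph") -> bool:
        """True if the two assignments agree on their domain overlap."""
        for rid, st in self.reaction_status.items():
            ot = other.reaction_status.get(rid)
            if ot is not None and ot != st:
                return False
        for pid, lab in self.pool_labels.items():
            ol = other.pool_labels.get(pid)
            if ol is not None and ol != lab:
                return False
        return True

    def union(self, other: "FlowGraph") -> "FlowGraph":
        merged = self.copy()
        merged.pool_labels.update(other.pool_labels)
        merged.reaction_status.update(other.reaction_status)
        seen = set(merged.frontier)
        for entity in other.frontier:
            if entity not in seen:
                merged.frontier.append(entity)
                seen.add(entity)
        merged.frontier = [e for e in merged.frontier if not merged.assigned(e)]
        return merged


@dataclass(frozen=True)
class Scenario:
    """A complete consistent assignment over one subnetwork."""

    reaction_status: Mapping[str, ReactionStatus]
    pool_labels: Mapping[str, PoolLabel]

    def key(self) -> tuple:
        return (
            tuple(
                sorted(
                    (k, v.flux, v.direction.value)
                    for k, v in self.reaction_status.items()
                )
            ),
            tuple(sorted((k, int(v)) for k, v in self.pool_labels.items())),
        )

    def to_dict(self, subnetwork: Optional[Subnetwork] = None) -> dict:
        return {
            "reactions": {
                rid: {"flux": st.flux, "direction": st.direction.value}
                for rid, st in sorted(self.reaction_status.items())
            },
            "pools": {pid: str(lab) for pid, lab in sorted(self.pool_labels.items())},
        }


# -- the compiled problem --------------------------------------------------


class _Problem:
    """Precomputed adjacency, rule and observation tables for one analysis."""

    def __init__(
        self,
        subnetwork: Subnetwork,
        observations: Sequence[Observation],
        enzyme_obs: Sequence[EnzymeObservation],
        acs: ActivationConditionSet,
        ranges: Optional[ReferenceRangeTable],
    ) -> None:
        self.subnetwork = subnetwork
        self.reactions: dict[str, Reaction] = {r.id: r for r in subnetwork.reactions}
        self.pools: dict[str, MetabolitePool] = {p.id: p for p in subnetwork.pools}
        self.boundary = subnetwork.boundary_pools()
        self.acs = acs
        self.rules: dict[str, ReactionRules] = {
            rid: acs.rules_for(r) for rid, r in self.reactions.items()
        }
        unavailable = {
            o.enzyme for o in enzyme_obs if o.availability == "unavailable"
        }
        self.enzyme_blocked: set[str] = {
            rid
            for rid, r in self.reactions.items()
            if r.enzymes & unavailable
        }
        # observation labels, checked for conflicts
        self.obs_labels: dict[str, PoolLabel] = {}
        for obs in observations:
            if obs.pool.id not in self.pools:
                raise ValidationError(
                    f"observation references pool {obs.pool.name} outside the subnetwork"
                )
            label = obs.resolve(ranges)
            prior = self.obs_labels.get(obs.pool.id)
            if prior is not None and prior != label:
                raise ValidationError(
                    f"conflicting observations for pool {obs.pool.name}: "
                    f"{prior} vs {label}"
                )
            self.obs_labels[obs.pool.id] = label
        # adjacency
        self.substrate_pools: dict[str, list[str]] = {}
        self.product_pools: dict[str, list[str]] = {}
        self.inhibitor_pools: dict[str, list[str]] = {}
        self.activator_pools: dict[str, list[str]] = {}
        self.neighbors: dict[tuple[str, str], list[tuple[str, str]]] = {}
        self.potential_producers: dict[str, list[tuple[str, Direction]]] = {
            pid: [] for pid in self.pools
        }
        self.potential_consumers: dict[str, list[tuple[str, Direction]]] = {
            pid: [] for pid in self.pools
        }
        for rid, rxn in self.reactions.items():
            subs = [p.id for p in rxn.substrates]
            prods = [p.id for p in rxn.products]
            self.substrate_pools[rid] = subs
            self.product_pools[rid] = prods
            self.inhibitor_pools[rid] = [p.id for p in rxn.inhibitors]
            self.activator_pools[rid] = [p.id for p in rxn.activators]
            for pid in prods:
                self.potential_producers[pid].append((rid, Direction.FORWARD))
            for pid in subs:
                self.potential_consumers[pid].append((rid, Direction.FORWARD))
                if rxn.reversible:
                    self.potential_producers[pid].append((rid, Direction.BACKWARD))
            if rxn.reversible:
                for pid in prods:
                    self.potential_consumers[pid].append((rid, Direction.BACKWARD))
            rkey = ("R", rid)
            pool_ids = sorted({p.id for p in rxn.pools()}, key=self._pool_sort_key)
            self.neighbors[rkey] = [("P", pid) for pid in pool_ids]
        for pid in self.pools:
            rxns = sorted(
                {r.id for r in self.reactions.values() if pid in {p.id for p in r.pools()}},
                key=self._reaction_sort_key,
            )
            self.neighbors[("P", pid)] = [("R", rid) for rid in rxns]
        self.entities: list[tuple[str, str]] = sorted(
            [("P", pid) for pid in self.pools] + [("R", rid) for rid in self.reactions],
            key=self.entity_sort_key,
        )

    def _pool_sort_key(self, pid: str) -> tuple[str, str]:
        return (self.pools[pid].name, pid)

    def _reaction_sort_key(self, rid: str) -> tuple[str, str]:
        return (self.reactions[rid].name, rid)

    def entity_sort_key(self, entity: tuple[str, str]) -> tuple[str, str, str]:
        kind, eid = entity
        name = self.pools[eid].name if kind == "P" else self.reactions[eid].name
        return (name, kind, eid)

    def total(self, fg: FlowGraph) -> bool:
        return len(fg.pool_labels) == len(self.pools) and len(
            fg.reaction_status
        ) == len(self.reactions)

    # -- direction helpers -------------------------------------------------

    def dir_substrates(self, rid: str, direction: Direction) -> list[str]:
        return (
            self.substrate_pools[rid]
            if direction is Direction.FORWARD
            else self.product_pools[rid]
        )

    def dir_products(self, rid: str, direction: Direction) -> list[str]:
        return (
            self.product_pools[rid]
            if direction is Direction.FORWARD
            else self.substrate_pools[rid]
        )

    def status_candidates(self, rid: str) -> list[ReactionStatus]:
        out = [INACTIVE, ACTIVE_FORWARD]
        if self.reactions[rid].reversible:
            out.append(ACTIVE_BACKWARD)
        return out

    def label_candidates(self, pid: str) -> list[PoolLabel]:
        pinned = self.obs_labels.get(pid)
        return [pinned] if pinned is not None else list(PoolLabel)

    # -- partial (three-valued) rule checks --------------------------------

    def reaction_ok(self, fg: FlowGraph, rid: str) -> bool:
        """False only when a rule touching this assigned reaction is definitely violated."""
        st = fg.reaction_status[rid]
        if not st.active:
            return True
        if rid in self.enzyme_blocked:  # R2
            return False
        rules = self.rules[rid]
        for pid in self.dir_substrates(rid, st.direction):  # R1
            lab = fg.pool_labels.get(pid)
            if lab is not None and lab < rules.substrate_threshold:
                return False
        for pid in self.inhibitor_pools[rid]:  # R3
            lab = fg.pool_labels.get(pid)
            if lab is not None and lab >= rules.inhibitor_threshold:
                return False
        if rules.require_activator and self.activator_pools[rid]:
            labs = [fg.pool_labels.get(pid) for pid in self.activator_pools[rid]]
            if all(l is not None for l in labs) and not any(
                l >= PoolLabel.AVAILABLE for l in labs
            ):
                return False
        return True

    def pool_ok(self, fg: FlowGraph, pid: str) -> bool:
        """False only when a rule touching this labeled pool is definitely violated."""
        lab = fg.pool_labels[pid]
        pinned = self.obs_labels.get(pid)
        if pinned is not None and lab != pinned:
            return False
        producers = self.potential_producers[pid]
        if lab == PoolLabel.UNAVAILABLE:  # R4
            for rid, d in producers:
                st = fg.reaction_status.get(rid)
                if st is not None and st.active and st.direction is d:
                    return False
        if pid in self.boundary:
            return True
        has_active_producer = any(
            (st := fg.reaction_status.get(rid)) is not None
            and st.active
            and st.direction is d
            for rid, d in producers
        )
        all_producers_decided = all(
            fg.reaction_status.get(rid) is not None for rid, _ in producers
        )
        if lab >= PoolLabel.ACCUMULATED:  # R5
            if all_producers_decided and not has_active_producer:
                return False
        if lab >= PoolLabel.AVAILABLE:  # R6
            has_active_consumer = any(
                (st := fg.reaction_status.get(rid)) is not None
                and st.active
                and st.direction is d
                for rid, d in self.potential_consumers[pid]
            )
            if has_active_consumer and all_producers_decided and not has_active_producer:
                return False
        return True

    def assignment_ok(self, fg: FlowGraph, entity: tuple[str, str]) -> bool:
        """Local three-valued consistency check after assigning *entity*."""
        kind, eid = entity
        if kind == "R":
            if not self.reaction_ok(fg, eid):
                return False
            for pid in {p.id for p in self.reactions[eid].pools()}:
                if pid in fg.pool_labels and not self.pool_ok(fg, pid):
                    return False
            return True
        if not self.pool_ok(fg, eid):
            return False
        for _, rid in self.neighbors[("P", eid)]:
            if rid in fg.reaction_status and not self.reaction_ok(fg, rid):
                return False
        return True

    def sweep_ok(self, fg: FlowGraph) -> bool:
        """Full three-valued sweep over every assigned entity."""
        return all(self.reaction_ok(fg, rid) for rid in fg.reaction_status) and all(
            self.pool_ok(fg, pid) for pid in fg.pool_labels
        )


def _build_problem(
    subnetwork: Subnetwork,
    observations: Sequence[Observation] = (),
    enzyme_obs: Sequence[EnzymeObservation] = (),
    acs: Optional[ActivationConditionSet] = None,
    reference_ranges: Optional[ReferenceRangeTable] = None,
) -> _Problem:
    if not subnetwork.reactions:
        raise ValidationError("the subnetwork contains no reactions")
    return _Problem(
        subnetwork, list(observations), list(enzyme_obs), acs or DEFAULT_ACS, reference_ranges
    )


# -- public rule evaluation -------------------------------------------------


def reaction_activation(
    reaction: Reaction,
    flowgraph: FlowGraph,
    enzyme_obs: Sequence[EnzymeObservation] = (),
    acs: Optional[ActivationConditionSet] = None,
) -> TruthValue:
    """Three-valued activability of a reaction under a partial labeling.

    Conjunction of substrate availability (forward for irreversible reactions,
    forward-or-backward for reversible ones), enzyme availability, inhibitor
    non-blocking and, if enabled, the activator requirement.
    """
    acs = acs or DEFAULT_ACS
    rules = acs.rules_for(reaction)
    unavailable = {o.enzyme for o in enzyme_obs if o.availability == "unavailable"}
    if reaction.enzymes & unavailable:
        return TruthValue.FALSE
    sub_fwd = Conj(
        tuple(PoolAtLeast(p.id, rules.substrate_threshold) for p in reaction.substrates)
    )
    if reaction.reversible:
        sub_bwd = Conj(
            tuple(PoolAtLeast(p.id, rules.substrate_threshold) for p in reaction.products)
        )
        substrate_part = Disj((sub_fwd, sub_bwd))
    else:
        substrate_part = sub_fwd
    inhibitor_part = Conj(
        tuple(
            Neg(PoolAtLeast(p.id, rules.inhibitor_threshold))
            for p in reaction.inhibitors
        )
    )
    terms: list = [substrate_part, inhibitor_part]
    if rules.require_activator and reaction.activators:
        terms.append(
            Disj(tuple(PoolAtLeast(p.id, PoolLabel.AVAILABLE) for p in reaction.activators))
        )
    return evaluate_condition(Conj(tuple(terms)), flowgraph)


def is_consistent(
    scenario: Scenario,
    subnetwork: Subnetwork,
    observations: Sequence[Observation] = (),
    enzyme_obs: Sequence[EnzymeObservation] = (),
    acs: Optional[ActivationConditionSet] = None,
    reference_ranges: Optional[ReferenceRangeTable] = None,
) -> bool:
    """Check a total assignment against rules R1-R6 and the observations."""
    problem = _build_problem(subnetwork, observations, enzyme_obs, acs, reference_ranges)
    fg = FlowGraph(
        pool_labels=dict(scenario.pool_labels),
        reaction_status=dict(scenario.reaction_status),
    )
    if not problem.total(fg):
        raise ValidationError("scenario is not total over the subnetwork")
    for rid, st in fg.reaction_status.items():
        if st.active and st.direction is Direction.BACKWARD and not problem.reactions[rid].reversible:
            return False
    return problem.sweep_ok(fg)


# -- expansion / merge ------------------------------------------------------


def _surviving_values(fg: FlowGraph, problem: _Problem, entity: tuple[str, str]) -> list:
    """Candidate values for a frontier entity that pass the local rule check."""
    kind, eid = entity
    raw = problem.label_candidates(eid) if kind == "P" else problem.status_candidates(eid)
    out = []
    for value in raw:
        if kind == "P":
            fg.pool_labels[eid] = value
        else:
            fg.reaction_status[eid] = value
        if problem.assignment_ok(fg, entity):
            out.append(value)
        if kind == "P":
            del fg.pool_labels[eid]
        else:
            del fg.reaction_status[eid]
    return out


def _pick_frontier_index(
    fg: FlowGraph, problem: _Problem, config: SMDAConfig, rng: Optional[random.Random]
) -> int:
    """Choose the next frontier entity to expand.

    Minimum-remaining-values: the entity with the fewest locally viable
    assignments goes first, so forced assignments (one candidate) and dead
    ends (zero) propagate before any true branching, keeping the live
    population close to the final scenario count.  Ties fall to the oldest
    frontier entry under breadth-first and the newest under depth-first (or a
    seeded random tie-break in depth-first mode).
    """
    counts = []
    for i, entity in enumerate(fg.frontier):
        n = len(_surviving_values(fg, problem, entity))
        if n <= 1:
            return i  # forced or dead: expand immediately
        counts.append((n, i))
    best = min(n for n, _ in counts)
    tied = [i for n, i in counts if n == best]
    if config.strategy == "breadth_first":
        return tied[0]
    if rng is not None:
        return rng.choice(tied)
    return tied[-1]


def _expand_one(
    fg: FlowGraph,
    problem: _Problem,
    config: SMDAConfig,
    rng: Optional[random.Random] = None,
) -> list[FlowGraph]:
    """Expand a single flow graph by its next frontier entity."""
    fg.frontier = [e for e in fg.frontier if not fg.assigned(e)]
    if not fg.frontier:
        if problem.total(fg):
            return [fg]
        # disconnected remainder: reseed with the first unassigned entity
        for entity in problem.entities:
            if not fg.assigned(entity):
                fg.frontier.append(entity)
                break
    idx = _pick_frontier_index(fg, problem, config, rng)
    entity = fg.frontier.pop(idx)
    kind, eid = entity
    children: list[FlowGraph] = []
    if kind == "P":
        values = problem.label_candidates(eid)
    else:
        values = problem.status_candidates(eid)
    seen = set(fg.frontier)
    additions = [n for n in problem.neighbors[entity] if not fg.assigned(n) and n not in seen]
    if rng is not None and config.strategy == "depth_first":
        rng.shuffle(additions)  # drawn once per parent so siblings share one frontier
    for value in values:
        child = fg.copy()
        if kind == "P":
            child.pool_labels[eid] = value
        else:
            child.reaction_status[eid] = value
        if not problem.assignment_ok(child, entity):
            continue
        child.frontier.extend(additions)
        children.append(child)
    return children


def expand(
    flowgraph: FlowGraph,
    subnetwork: Subnetwork,
    observations: Sequence[Observation] = (),
    enzyme_obs: Sequence[EnzymeObservation] = (),
    acs: Optional[ActivationConditionSet] = None,
    config: Optional[SMDAConfig] = None,
    reference_ranges: Optional[ReferenceRangeTable] = None,
) -> list[FlowGraph]:
    """One expansion step: branch the next frontier entity over its viable values.

    With an empty frontier (and nothing left to assign) the input is returned
    unchanged.  Only branches whose partial assignment is already definitely
    inconsistent are pruned.
    """
    config = config or SMDAConfig()
    problem = _build_problem(subnetwork, observations, enzyme_obs, acs, reference_ranges)
    fg = flowgraph.copy()
    fg.frontier = [e for e in fg.frontier if not fg.assigned(e)]
    if not fg.frontier and problem.total(fg):
        return [flowgraph]
    rng = random.Random(config.seed) if config.seed is not None else None
    return _expand_one(fg, problem, config, rng)


def merge(flowgraphs: Iterable[FlowGraph]) -> list[FlowGraph]:
    """Union flow graphs that agree on their overlap; keep disagreeing ones apart.

    Pairs whose assignments agree on every shared entity are replaced by their
    union (identical graphs therefore collapse to one); incompatible graphs
    survive unmerged.  Pairs are examined in canonical order, greedily, until
    no compatible pair remains.
    """
    pool = sorted((fg.copy() for fg in flowgraphs), key=lambda f: f.key())
    changed = True
    while changed:
        changed = False
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if pool[i].compatible(pool[j]):
                    merged = pool[i].union(pool[j])
                    del pool[j]
                    del pool[i]
                    pool.append(merged)
                    pool.sort(key=lambda f: f.key())
                    changed = True
                    break
            if changed:
                break
    return pool


def _canonical_scenario_key(problem: _Problem, key: tuple) -> tuple:
    """Sort key: lexicographic over reaction names' statuses, then pool labels."""
    status_part, label_part = key
    by_name_status = tuple(
        (problem.reactions[rid].name, flux, direction)
        for rid, flux, direction in sorted(
            status_part, key=lambda t: problem._reaction_sort_key(t[0])
        )
    )
    by_name_labels = tuple(
        (problem.pools[pid].name, lab)
        for pid, lab in sorted(label_part, key=lambda t: problem._pool_sort_key(t[0]))
    )
    return (by_name_status, by_name_labels)


def _engine_merge(population: Iterable[FlowGraph]) -> list[FlowGraph]:
    """Merge step as used inside the engine.

    A population of partial flow graphs denotes the union of their consistent
    completions, so unioning two graphs is only meaning-preserving when their
    domains are equal (then compatible means identical: deduplication) or
    disjoint (the initial join of single-observation graphs, where the
    intended semantics is conjunction).  Partially overlapping compatible
    graphs are left side by side.
    """
    groups: dict[tuple, dict[tuple, FlowGraph]] = {}
    for fg in population:
        sig = (frozenset(fg.pool_labels), frozenset(fg.reaction_status))
        groups.setdefault(sig, {}).setdefault(fg.key(), fg.copy())
    sigs = sorted(groups, key=lambda s: (sorted(s[0]), sorted(s[1])))
    # join groups with pairwise disjoint domains (the initial observation join)
    merged = True
    while merged and len(sigs) > 1:
        merged = False
        for i in range(len(sigs)):
            for j in range(i + 1, len(sigs)):
                a, b = sigs[i], sigs[j]
                if (a[0] & b[0]) or (a[1] & b[1]):
                    continue
                joined = {
                    u.key(): u
                    for ga in groups[a].values()
                    for gb in groups[b].values()
                    for u in [ga.union(gb)]
                }
                sig = (a[0] | b[0], a[1] | b[1])
                for s in (a, b):
                    del groups[s]
                groups.setdefault(sig, {}).update(joined)
                sigs = sorted(groups, key=lambda s: (sorted(s[0]), sorted(s[1])))
                merged = True
                break
            if merged:
                break
    return [fg for sig in sigs for _, fg in sorted(groups[sig].items())]


# -- the engine -------------------------------------------------------------


class SMDAEngine:
    """Step-wise Expansion/Merge enumeration of steady-state scenarios.

    Phases: ``init`` (build one single-pool flow graph per observation, or a
    single empty graph when there are none), then alternating ``merge`` and
    ``expand`` until every flow graph is total, then ``done``.  Each call to
    :meth:`step` performs exactly one phase; :meth:`run` iterates to
    quiescence.
    """

    def __init__(
        self,
        subnetwork: Subnetwork,
        observations: Sequence[Observation] = (),
        enzyme_obs: Sequence[EnzymeObservation] = (),
        acs: Optional[ActivationConditionSet] = None,
        config: Optional[SMDAConfig] = None,
        reference_ranges: Optional[ReferenceRangeTable] = None,
    ) -> None:
        self.config = config or SMDAConfig()
        self.problem = _build_problem(
            subnetwork, observations, enzyme_obs, acs, reference_ranges
        )
        self._rng = (
            random.Random(self.config.seed) if self.config.seed is not None else None
        )
        self.population: list[FlowGraph] = []
        self.phase = "init"
        self.step_count = 0

    @property
    def finished(self) -> bool:
        return self.phase == "done"

    def step(self) -> "SMDAEngine":
        """Perform one expansion-or-merge step; a finished engine is a no-op."""
        if self.finished:
            return self
        if self.phase == "init":
            self._init_population()
            self.phase = "merge"
        elif self.phase == "merge":
            self.population = [
                fg for fg in _engine_merge(self.population) if self.problem.sweep_ok(fg)
            ]
            self.phase = (
                "done"
                if all(self.problem.total(fg) for fg in self.population)
                else "expand"
            )
        else:  # expand
            nxt: list[FlowGraph] = []
            for fg in self.population:
                if self.problem.total(fg):
                    nxt.append(fg)
                else:
                    nxt.extend(_expand_one(fg, self.problem, self.config, self._rng))
            self.population = nxt
            self.phase = "merge"
        self.step_count += 1
        if len(self.population) > self.config.cap:
            raise CapacityError(
                f"live scenario count {len(self.population)} exceeds the configured "
                f"cap of {self.config.cap}"
            )
        return self

    def run(self) -> "SMDAEngine":
        while not self.finished:
            self.step()
        return self

    def scenarios(self) -> list[Scenario]:
        """Extract the consistent scenarios from a finished engine, in canonical order."""
        if not self.finished:
            self.run()
        out: dict[tuple, Scenario] = {}
        for fg in self.population:
            status = {
                rid: (INACTIVE if not st.active else st)
                for rid, st in fg.reaction_status.items()
            }
            scenario = Scenario(
                reaction_status=status, pool_labels=dict(fg.pool_labels)
            )
            if self.problem.sweep_ok(
                FlowGraph(pool_labels=dict(scenario.pool_labels),
                          reaction_status=dict(scenario.reaction_status))
            ):
                out[scenario.key()] = scenario
        return [out[k] for k in sorted(out, key=self._canonical_key)]

    def _canonical_key(self, key: tuple) -> tuple:
        return _canonical_scenario_key(self.problem, key)

    def _init_population(self) -> None:
        obs_items = sorted(
            self.problem.obs_labels.items(),
            key=lambda kv: self.problem._pool_sort_key(kv[0]),
        )
        if obs_items:
            for pid, label in obs_items:
                fg = FlowGraph(pool_labels={pid: label})
                fg.frontier = [
                    n for n in self.problem.neighbors[("P", pid)] if not fg.assigned(n)
                ]
                self.population.append(fg)
        else:
            fg = FlowGraph()
            fg.frontier = [self.problem.entities[0]]
            self.population = [fg]


def enumerate_scenarios(
    subnetwork: Subnetwork,
    observations: Sequence[Observation] = (),
    enzyme_obs: Sequence[EnzymeObservation] = (),
    acs: Optional[ActivationConditionSet] = None,
    config: Optional[SMDAConfig] = None,
    reference_ranges: Optional[ReferenceRangeTable] = None,
) -> list[Scenario]:
    """All scenarios consistent with the observations, in canonical order."""
    try:
        if not subnetwork.is_connected():
            warnings.warn(
                "the selected subnetwork is not connected; scenarios are still "
                "enumerated over all components",
                stacklevel=2,
            )
    except ValidationError:
        pass  # empty subnetwork: the engine raises its own error below
    engine = SMDAEngine(
        subnetwork, observations, enzyme_obs, acs, config, reference_ranges
    )
    return engine.run().scenarios()


# -- brute-force oracle ------------------------------------------------------

_BRUTE_FORCE_LIMIT = 15


def brute_force_scenarios(
    subnetwork: Subnetwork,
    observations: Sequence[Observation] = (),
    enzyme_obs: Sequence[EnzymeObservation] = (),
    acs: Optional[ActivationConditionSet] = None,
    reference_ranges: Optional[ReferenceRangeTable] = None,
) -> list[Scenario]:
    """Enumerate and filter every total assignment (testing oracle).

    Iterates all reaction-status combinations; for each, derives the per-pool
    admissible label sets implied by the rules, takes their product, and keeps
    the assignments accepted by :func:`is_consistent`.  Guarded to small
    subnetworks (<= 15 reactions and <= 15 pools).
    """
    problem = _build_problem(subnetwork, observations, enzyme_obs, acs, reference_ranges)
    n_r, n_p = len(problem.reactions), len(problem.pools)
    if n_r > _BRUTE_FORCE_LIMIT or n_p > _BRUTE_FORCE_LIMIT:
        raise CapacityError(
            f"brute-force oracle is limited to {_BRUTE_FORCE_LIMIT} reactions and "
            f"pools (got {n_r} reactions, {n_p} pools)"
        )
    rids = sorted(problem.reactions, key=problem._reaction_sort_key)
    pids = sorted(problem.pools, key=problem._pool_sort_key)
    out: dict[tuple, Scenario] = {}
    import itertools

    for statuses in itertools.product(*(problem.status_candidates(r) for r in rids)):
        status_map = dict(zip(rids, statuses))
        if any(
            st.active and rid in problem.enzyme_blocked
            for rid, st in status_map.items()
        ):
            continue
        allowed: list[list[PoolLabel]] = []
        feasible = True
        for pid in pids:
            labels = _allowed_labels(problem, pid, status_map)
            if not labels:
                feasible = False
                break
            allowed.append(labels)
        if not feasible:
            continue
        for labels in itertools.product(*allowed):
            fg = FlowGraph(
                pool_labels=dict(zip(pids, labels)), reaction_status=status_map
            )
            if problem.sweep_ok(fg):
                sc = Scenario(reaction_status=dict(status_map),
                              pool_labels=dict(zip(pids, labels)))
                out[sc.key()] = sc
    return [
        out[k]
        for k in sorted(out, key=lambda k: _canonical_scenario_key(problem, k))
    ]


def count_scenarios(
    subnetwork: Subnetwork,
    observations: Sequence[Observation] = (),
    enzyme_obs: Sequence[EnzymeObservation] = (),
    acs: Optional[ActivationConditionSet] = None,
    reference_ranges: Optional[ReferenceRangeTable] = None,
) -> int:
    """Count consistent scenarios without materializing them.

    Given a fixed reaction-status assignment the rules decompose per pool, so
    the count is a sum over status combinations of the product of admissible
    label-set sizes.  Exact whenever no reaction has the activator requirement
    enabled (the default); with it enabled this is an upper bound, because the
    at-least-one-activator disjunction couples pools.
    """
    problem = _build_problem(subnetwork, observations, enzyme_obs, acs, reference_ranges)
    rids = sorted(problem.reactions, key=problem._reaction_sort_key)
    pids = sorted(problem.pools, key=problem._pool_sort_key)
    import itertools

    total = 0
    for statuses in itertools.product(*(problem.status_candidates(r) for r in rids)):
        status_map = dict(zip(rids, statuses))
        if any(
            st.active and rid in problem.enzyme_blocked
            for rid, st in status_map.items()
        ):
            continue
        prod = 1
        for pid in pids:
            prod *= len(_allowed_labels(problem, pid, status_map))
            if prod == 0:
                break
        total += prod
    return total


def _allowed_labels(
    problem: _Problem, pid: str, status_map: Mapping[str, ReactionStatus]
) -> list[PoolLabel]:
    """Label values for one pool admissible under a fixed status assignment."""
    pinned = problem.obs_labels.get(pid)
    candidates = [pinned] if pinned is not None else list(PoolLabel)
    has_producer = any(
        status_map[rid].active and status_map[rid].direction is d
        for rid, d in problem.potential_producers[pid]
    )
    has_consumer = any(
        status_map[rid].active and status_map[rid].direction is d
        for rid, d in problem.potential_consumers[pid]
    )
    boundary = pid in problem.boundary
    out = []
    for lab in candidates:
        if lab == PoolLabel.UNAVAILABLE and has_producer:
            continue  # R4
        if not boundary and not has_producer:
            if lab >= PoolLabel.ACCUMULATED:
                continue  # R5
            if lab >= PoolLabel.AVAILABLE and has_consumer:
                continue  # R6
        ok = True
        for rid, d in problem.potential_consumers[pid]:
            st = status_map[rid]
            if st.active and st.direction is d and lab < problem.rules[rid].substrate_threshold:
                ok = False  # R1
                break
        if ok:
            for rid in problem.reactions:
                st = status_map[rid]
                if (
                    st.active
                    and pid in problem.inhibitor_pools[rid]
                    and lab >= problem.rules[rid].inhibitor_threshold
                ):
                    ok = False  # R3
                    break
        if ok:
            out.append(lab)
    return out
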