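"""Compartmentalized metabolic-network data model.

The model mirrors how curated metabolic databases organise their content: a
*compartment hierarchy* (organ -> cytosol -> organelle), *metabolites* with
synonym lists, *metabolite pools* (a metabolite situated in exactly one
compartment -- the entity that observations and reaction participation attach
to), *reactions* with role-typed participants (substrate / product / activator
/ inhibitor) plus catalysing enzyme names, and *pathways* grouping reactions.

All cross-references are held as object references; serialization (module
:mod:`smda.io`) flattens them to string ids.  :meth:`MetabolicNetwork.validate`
sweeps the whole registry for referential integrity and is cheap enough to run
after every mutation batch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

from .errors import UnknownEntityError, ValidationError

__all__ = [
    "Role",
    "Compartment",
    "Metabolite",
    "MetabolitePool",
    "Participant",
    "Reaction",
    "Pathway",
    "MetabolicNetwork",
    "Subnetwork",
    "get_or_create_pool",
    "reactions_of_pathway",
    "pools_of_reaction",
    "connected_pathways",
    "collapse_pathway",
    "select_subnetwork",
    "is_connected",
    "stats",
    "validate",
]


class Role(str, Enum):
    """Role a metabolite pool plays in a reaction."""

    SUBSTRATE = "substrate"
    PRODUCT = "product"
    ACTIVATOR = "activator"
    INHIBITOR = "inhibitor"

    @classmethod
    def coerce(cls, value: "Role | str") -> "Role":
        if isinstance(value, Role):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValidationError(f"unknown participant role: {value!r}") from None


@dataclass(eq=False)
class Compartment:
    """A cellular or anatomical location; may be nested inside a parent."""

    id: str
    name: str
    parent: Optional["Compartment"] = None

    def ancestors(self, include_self: bool = True) -> Iterator["Compartment"]:
        """Yield the containment chain from this compartment to the root."""
        node = self if include_self else self.parent
        seen = set()
        while node is not None:
            if id(node) in seen:
                raise ValidationError(f"compartment parent chain of {self.id!r} is cyclic")
            seen.add(id(node))
            yield node
            node = node.parent

    def path(self) -> str:
        """Slash-separated name path from the root, e.g. ``liver cell/cytosol``."""
        return "/".join(c.name for c in reversed(list(self.ancestors())))

    def contains(self, other: "Compartment") -> bool:
        """True if *other* lies at or below this compartment in the hierarchy."""
        return any(c is self for c in other.ancestors())

    def __repr__(self) -> str:
        return f"Compartment({self.id!r}, {self.name!r})"


@dataclass(eq=False)
class Metabolite:
    id: str
    name: str
    synonyms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("metabolite name must be non-empty")
        self.synonyms = set(self.synonyms)
        lowered = {s.lower() for s in self.synonyms}
        if len(lowered) != len(self.synonyms) or self.name.lower() in lowered:
            raise ValidationError(
                f"metabolite {self.id!r}: synonyms must be pairwise distinct "
                "and distinct from the primary name (case-insensitive)"
            )

    def __repr__(self) -> str:
        return f"Metabolite({self.id!r}, {self.name!r})"


@dataclass(eq=False)
class MetabolitePool:
    """A metabolite situated in one compartment -- the node observations attach to."""

    id: str
    metabolite: Metabolite
    compartment: Compartment

    @property
    def name(self) -> str:
        return f"{self.metabolite.name}[{self.compartment.name}]"

    def __repr__(self) -> str:
        return f"MetabolitePool({self.id!r}, {self.name})"


@dataclass(frozen=True)
class Participant:
    pool: MetabolitePool
    role: Role


@dataclass(eq=False)
class Reaction:
    id: str
    name: str
    reversible: bool = False
    participants: list[Participant] = field(default_factory=list)
    enzymes: set[str] = field(default_factory=set)
    #: id of the pathway this reaction lumps, for collapsed synthetic reactions
    collapsed_from: Optional[str] = None

    def pools_with_role(self, role: Role) -> list[MetabolitePool]:
        return [p.pool for p in self.participants if p.role is role]

    @property
    def substrates(self) -> list[MetabolitePool]:
        return self.pools_with_role(Role.SUBSTRATE)

    @property
    def products(self) -> list[MetabolitePool]:
        return self.pools_with_role(Role.PRODUCT)

    @property
    def activators(self) -> list[MetabolitePool]:
        return self.pools_with_role(Role.ACTIVATOR)

    @property
    def inhibitors(self) -> list[MetabolitePool]:
        return self.pools_with_role(Role.INHIBITOR)

    @property
    def is_transport(self) -> bool:
        """Derived: substrate and product pools span two or more compartments."""
        comps = {
            p.pool.compartment.id
            for p in self.participants
            if p.role in (Role.SUBSTRATE, Role.PRODUCT)
        }
        return len(comps) >= 2

    def pools(self) -> list[MetabolitePool]:
        """All participant pools, deduplicated, in participant order."""
        seen: dict[str, MetabolitePool] = {}
        for p in self.participants:
            seen.setdefault(p.pool.id, p.pool)
        return list(seen.values())

    def __repr__(self) -> str:
        return f"Reaction({self.id!r}, {self.name!r})"


@dataclass(eq=False)
class Pathway:
    id: str
    name: str
    reactions: list[Reaction] = field(default_factory=list)
    #: compartments in which the pathway is instantiated (a pathway can exist
    #: in more than one compartment; reactions are not duplicated per copy)
    compartments: set[Compartment] = field(default_factory=set)

    def __repr__(self) -> str:
        return f"Pathway({self.id!r}, {self.name!r})"


def _name_key(entity) -> tuple[str, str]:
    return (entity.name, entity.id)


class MetabolicNetwork:
    """Registry of compartments, metabolites, pools, reactions and pathways.

    Mutation goes through the ``add_*`` methods, which keep the secondary
    indices (name/synonym lookup, pool uniqueness, pool->reactions,
    reaction->pathways) consistent with the collections.
    """

    def __init__(self, name: str = "network") -> None:
        self.name = name
        self.compartments: dict[str, Compartment] = {}
        self.metabolites: dict[str, Metabolite] = {}
        self.pools: dict[str, MetabolitePool] = {}
        self.reactions: dict[str, Reaction] = {}
        self.pathways: dict[str, Pathway] = {}
        self._pool_by_pair: dict[tuple[str, str], MetabolitePool] = {}
        self._metabolite_by_name: dict[str, Metabolite] = {}
        self._reactions_by_pool: dict[str, list[Reaction]] = {}
        self._pathways_by_reaction: dict[str, list[Pathway]] = {}

    # -- registration -----------------------------------------------------

    def add_compartment(
        self, id: str, name: str, parent: "Compartment | str | None" = None
    ) -> Compartment:
        if id in self.compartments:
            raise ValidationError(f"duplicate compartment id {id!r}")
        parent_obj = self._resolve_compartment(parent) if parent is not None else None
        comp = Compartment(id=id, name=name, parent=parent_obj)
        list(comp.ancestors())  # raises on a cycle
        self.compartments[id] = comp
        return comp

    def add_metabolite(self, id: str, name: str, synonyms: Iterable[str] = ()) -> Metabolite:
        if id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {id!r}")
        met = Metabolite(id=id, name=name, synonyms=set(synonyms))
        for key in self._metabolite_keys(met):
            other = self._metabolite_by_name.get(key)
            if other is not None and other is not met:
                raise ValidationError(
                    f"metabolite name/synonym {key!r} already used by {other.id!r}"
                )
        self.metabolites[id] = met
        for key in self._metabolite_keys(met):
            self._metabolite_by_name[key] = met
        return met

    def get_or_create_pool(
        self,
        metabolite: "Metabolite | str",
        compartment: "Compartment | str",
        pool_id: Optional[str] = None,
    ) -> MetabolitePool:
        """Return the pool for (metabolite, compartment), creating it if absent.

        Idempotent: at most one pool ever exists per pair.  Mirrors the
        automatic pool creation a curation editor performs when a reaction
        references a metabolite in a new compartment.
        """
        met = self._resolve_metabolite(metabolite)
        comp = self._resolve_compartment(compartment)
        key = (met.id, comp.id)
        pool = self._pool_by_pair.get(key)
        if pool is not None:
            return pool
        pid = pool_id or f"pool:{met.id}@{comp.id}"
        if pid in self.pools:
            raise ValidationError(f"duplicate pool id {pid!r}")
        pool = MetabolitePool(id=pid, metabolite=met, compartment=comp)
        self.pools[pid] = pool
        self._pool_by_pair[key] = pool
        self._reactions_by_pool.setdefault(pid, [])
        return pool

    def add_reaction(
        self,
        id: str,
        name: str,
        participants: Sequence["Participant | tuple[MetabolitePool, Role | str]"],
        reversible: bool = False,
        enzymes: Iterable[str] = (),
        collapsed_from: Optional[str] = None,
    ) -> Reaction:
        if id in self.reactions:
            raise ValidationError(f"duplicate reaction id {id!r}")
        parts: list[Participant] = []
        seen_roles: set[tuple[str, Role]] = set()
        for item in participants:
            part = item if isinstance(item, Participant) else Participant(item[0], Role.coerce(item[1]))
            if part.pool.id not in self.pools:
                raise UnknownEntityError(
                    f"reaction {id!r} references unregistered pool {part.pool.id!r}"
                )
            key = (part.pool.id, part.role)
            if key in seen_roles:
                raise ValidationError(
                    f"reaction {id!r}: pool {part.pool.id!r} appears twice as {part.role.value}"
                )
            seen_roles.add(key)
            parts.append(part)
        rxn = Reaction(
            id=id,
            name=name,
            reversible=reversible,
            participants=parts,
            enzymes=set(enzymes),
            collapsed_from=collapsed_from,
        )
        if not rxn.substrates or not rxn.products:
            raise ValidationError(f"reaction {id!r} needs at least one substrate and one product")
        self.reactions[id] = rxn
        for pool in rxn.pools():
            self._reactions_by_pool.setdefault(pool.id, []).append(rxn)
        self._pathways_by_reaction.setdefault(id, [])
        return rxn

    def add_pathway(
        self,
        id: str,
        name: str,
        reactions: Sequence["Reaction | str"],
        compartments: Optional[Iterable["Compartment | str"]] = None,
    ) -> Pathway:
        if id in self.pathways:
            raise ValidationError(f"duplicate pathway id {id!r}")
        rxns: list[Reaction] = []
        for r in reactions:
            rxn = self._resolve_reaction(r)
            if rxn not in rxns:
                rxns.append(rxn)
        if not rxns:
            raise ValidationError(f"pathway {id!r} must contain at least one reaction")
        if compartments is None:
            comps = {p.compartment for r in rxns for p in r.pools()}
        else:
            comps = {self._resolve_compartment(c) for c in compartments}
        if not comps:
            raise ValidationError(f"pathway {id!r} must be instantiated in >=1 compartment")
        pw = Pathway(id=id, name=name, reactions=rxns, compartments=comps)
        self.pathways[id] = pw
        for rxn in rxns:
            self._pathways_by_reaction.setdefault(rxn.id, []).append(pw)
        return pw

    # -- lookup -----------------------------------------------------------

    def find_metabolite(self, name: str) -> Metabolite:
        """Case-insensitive lookup by primary name or synonym."""
        met = self._metabolite_by_name.get(name.lower())
        if met is None:
            raise UnknownEntityError(f"unknown metabolite {name!r}")
        return met

    def find_compartment_by_path(self, path: str) -> Compartment:
        """Resolve a slash-separated name path; a bare unique name also works."""
        names = [p for p in path.split("/") if p]
        if not names:
            raise UnknownEntityError("empty compartment path")
        matches = [
            c
            for c in self.compartments.values()
            if c.name.lower() == names[-1].lower()
            and _path_suffix_matches(c, names)
        ]
        if not matches:
            raise UnknownEntityError(f"no compartment matches path {path!r}")
        if len(matches) > 1:
            raise ValidationError(f"compartment path {path!r} is ambiguous")
        return matches[0]

    def pool_of(self, metabolite: "Metabolite | str", compartment: "Compartment | str") -> MetabolitePool:
        met = self._resolve_metabolite(metabolite)
        comp = self._resolve_compartment(compartment)
        pool = self._pool_by_pair.get((met.id, comp.id))
        if pool is None:
            raise UnknownEntityError(
                f"no pool for metabolite {met.name!r} in compartment {comp.name!r}"
            )
        return pool

    def reactions_using_pool(self, pool: "MetabolitePool | str") -> list[Reaction]:
        pool = self._resolve_pool(pool)
        return sorted(self._reactions_by_pool.get(pool.id, []), key=_name_key)

    def pathways_of_reaction(self, reaction: "Reaction | str") -> list[Pathway]:
        rxn = self._resolve_reaction(reaction)
        return sorted(self._pathways_by_reaction.get(rxn.id, []), key=_name_key)

    # -- resolution helpers ------------------------------------------------

    def _resolve_compartment(self, value: "Compartment | str") -> Compartment:
        if isinstance(value, Compartment):
            if self.compartments.get(value.id) is not value:
                raise UnknownEntityError(f"compartment {value.id!r} is not registered here")
            return value
        if value in self.compartments:
            return self.compartments[value]
        return self.find_compartment_by_path(value)

    def _resolve_metabolite(self, value: "Metabolite | str") -> Metabolite:
        if isinstance(value, Metabolite):
            if self.metabolites.get(value.id) is not value:
                raise UnknownEntityError(f"metabolite {value.id!r} is not registered here")
            return value
        if value in self.metabolites:
            return self.metabolites[value]
        return self.find_metabolite(value)

    def _resolve_pool(self, value: "MetabolitePool | str") -> MetabolitePool:
        if isinstance(value, MetabolitePool):
            if self.pools.get(value.id) is not value:
                raise UnknownEntityError(f"pool {value.id!r} is not registered here")
            return value
        if value not in self.pools:
            raise UnknownEntityError(f"unknown pool {value!r}")
        return self.pools[value]

    def _resolve_reaction(self, value: "Reaction | str") -> Reaction:
        if isinstance(value, Reaction):
            if self.reactions.get(value.id) is not value:
                raise UnknownEntityError(f"reaction {value.id!r} is not registered here")
            return value
        if value in self.reactions:
            return self.reactions[value]
        for rxn in self.reactions.values():
            if rxn.name.lower() == value.lower():
                return rxn
        raise UnknownEntityError(f"unknown reaction {value!r}")

    def _resolve_pathway(self, value: "Pathway | str") -> Pathway:
        if isinstance(value, Pathway):
            if self.pathways.get(value.id) is not value:
                raise UnknownEntityError(f"pathway {value.id!r} is not registered here")
            return value
        if value in self.pathways:
            return self.pathways[value]
        for pw in self.pathways.values():
            if pw.name.lower() == value.lower():
                return pw
        raise UnknownEntityError(f"unknown pathway {value!r}")

    @staticmethod
    def _metabolite_keys(met: Metabolite) -> set[str]:
        return {met.name.lower()} | {s.lower() for s in met.synonyms}

    # -- integrity ---------------------------------------------------------

    def reindex(self) -> None:
        """Rebuild all secondary indices from the primary collections."""
        self._pool_by_pair = {}
        self._metabolite_by_name = {}
        self._reactions_by_pool = {pid: [] for pid in self.pools}
        self._pathways_by_reaction = {rid: [] for rid in self.reactions}
        for met in self.metabolites.values():
            for key in self._metabolite_keys(met):
                self._metabolite_by_name[key] = met
        for pool in self.pools.values():
            self._pool_by_pair[(pool.metabolite.id, pool.compartment.id)] = pool
        for rxn in self.reactions.values():
            for pool in rxn.pools():
                self._reactions_by_pool.setdefault(pool.id, []).append(rxn)
        for pw in self.pathways.values():
            for rxn in pw.reactions:
                self._pathways_by_reaction.setdefault(rxn.id, []).append(pw)

    def validate(self) -> None:
        """Raise :class:`ValidationError` unless the whole registry is consistent."""
        problems: list[str] = []
        for comp in self.compartments.values():
            try:
                chain = list(comp.ancestors())
            except ValidationError as exc:
                problems.append(str(exc))
                continue
            for anc in chain:
                if self.compartments.get(anc.id) is not anc:
                    problems.append(
                        f"compartment {comp.id!r} has unregistered ancestor {anc.id!r}"
                    )
        seen_pairs: set[tuple[str, str]] = set()
        for pool in self.pools.values():
            if self.metabolites.get(pool.metabolite.id) is not pool.metabolite:
                problems.append(f"pool {pool.id!r} references dangling metabolite")
            if self.compartments.get(pool.compartment.id) is not pool.compartment:
                problems.append(f"pool {pool.id!r} references dangling compartment")
            pair = (pool.metabolite.id, pool.compartment.id)
            if pair in seen_pairs:
                problems.append(f"duplicate pool for pair {pair}")
            seen_pairs.add(pair)
        for rxn in self.reactions.values():
            if not rxn.substrates or not rxn.products:
                problems.append(f"reaction {rxn.id!r} lacks a substrate or a product")
            role_seen: set[tuple[str, Role]] = set()
            for part in rxn.participants:
                if self.pools.get(part.pool.id) is not part.pool:
                    problems.append(f"reaction {rxn.id!r} references dangling pool {part.pool.id!r}")
                key = (part.pool.id, part.role)
                if key in role_seen:
                    problems.append(
                        f"reaction {rxn.id!r}: pool {part.pool.id!r} duplicated in role {part.role.value}"
                    )
                role_seen.add(key)
        for pw in self.pathways.values():
            if not pw.reactions:
                problems.append(f"pathway {pw.id!r} has no reactions")
            if not pw.compartments:
                problems.append(f"pathway {pw.id!r} has no compartments")
            for rxn in pw.reactions:
                if self.reactions.get(rxn.id) is not rxn:
                    problems.append(f"pathway {pw.id!r} references dangling reaction {rxn.id!r}")
            for comp in pw.compartments:
                if self.compartments.get(comp.id) is not comp:
                    problems.append(f"pathway {pw.id!r} references dangling compartment {comp.id!r}")
        # index consistency
        for pool in self.pools.values():
            expected = [r for r in self.reactions.values() if pool in r.pools()]
            actual = self._reactions_by_pool.get(pool.id, [])
            if {r.id for r in expected} != {r.id for r in actual}:
                problems.append(f"pool->reactions index stale for {pool.id!r}")
        if problems:
            raise ValidationError("; ".join(problems))

    def stats(self) -> dict[str, int]:
        return {
            "pathways": len(self.pathways),
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "pools": len(self.pools),
            "compartments": len(self.compartments),
        }

    def __repr__(self) -> str:
        s = self.stats()
        return (
            f"MetabolicNetwork({self.name!r}, {s['pathways']} pathways, "
            f"{s['reactions']} reactions, {s['metabolites']} metabolites)"
        )


def _path_suffix_matches(comp: Compartment, names: list[str]) -> bool:
    chain = [c.name.lower() for c in comp.ancestors()]  # leaf -> root
    wanted = [n.lower() for n in reversed(names)]  # leaf -> root
    if len(wanted) > len(chain):
        return False
    return chain[: len(wanted)] == wanted


@dataclass(eq=False)
class Subnetwork:
    """A selected, possibly open, part of a network.

    ``reactions`` is the explicit selection; ``pools`` is always derived from
    it.  ``boundary`` holds pool ids explicitly flagged by the caller as open
    inputs/outputs; :meth:`boundary_pools` adds every pool that is also touched
    by a network reaction outside the selection, since such a pool can be
    produced or consumed by the unselected surroundings.
    """

    network: MetabolicNetwork
    reactions: list[Reaction] = field(default_factory=list)
    boundary: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = set()
        unique: list[Reaction] = []
        for rxn in self.reactions:
            if self.network.reactions.get(rxn.id) is not rxn:
                raise UnknownEntityError(f"reaction {rxn.id!r} is not registered in the network")
            if rxn.id not in ids:
                ids.add(rxn.id)
                unique.append(rxn)
        self.reactions = unique

    @property
    def pools(self) -> list[MetabolitePool]:
        seen: dict[str, MetabolitePool] = {}
        for rxn in self.reactions:
            for pool in rxn.pools():
                seen.setdefault(pool.id, pool)
        return sorted(seen.values(), key=_name_key)

    def boundary_pools(self) -> set[str]:
        selected = {r.id for r in self.reactions}
        out = set(self.boundary)
        for pool in self.pools:
            for rxn in self.network._reactions_by_pool.get(pool.id, []):
                if rxn.id not in selected and pool.id in {
                    q.id for q in rxn.substrates + rxn.products
                }:
                    out.add(pool.id)
                    break
        return out

    def is_connected(self) -> bool:
        """Connectivity of the bipartite pool/reaction graph.

        Participation edges only (substrate/product); regulator edges do not
        make a subnetwork connected, and regulator-only pools are not counted
        as nodes.
        """
        if not self.reactions:
            raise ValidationError("connectivity is undefined for an empty subnetwork")
        g = nx.Graph()
        for rxn in self.reactions:
            g.add_node(("R", rxn.id))
            for pool in rxn.substrates + rxn.products:
                g.add_edge(("R", rxn.id), ("P", pool.id))
        return nx.is_connected(g)


# -- module-level operation surface ---------------------------------------


def validate(network: MetabolicNetwork) -> None:
    network.validate()


def stats(network: MetabolicNetwork) -> dict[str, int]:
    return network.stats()


def get_or_create_pool(
    network: MetabolicNetwork,
    metabolite: "Metabolite | str",
    compartment: "Compartment | str",
) -> MetabolitePool:
    return network.get_or_create_pool(metabolite, compartment)


def reactions_of_pathway(network: MetabolicNetwork, pathway: "Pathway | str") -> list[Reaction]:
    """Reactions of a pathway in their curated (insertion) order."""
    return list(network._resolve_pathway(pathway).reactions)


def pools_of_reaction(
    network: MetabolicNetwork,
    reaction: "Reaction | str",
    compartment: "Compartment | str",
) -> list[MetabolitePool]:
    """Participant pools of *reaction* located at or below *compartment*.

    Containment uses subtree semantics: a pool in the mitochondrion also counts
    when asking at the level of the enclosing cell.  A reaction that does not
    occur in the given compartment yields an empty list, not an error.
    """
    rxn = network._resolve_reaction(reaction)
    comp = network._resolve_compartment(compartment)
    return sorted(
        (pool for pool in rxn.pools() if comp.contains(pool.compartment)),
        key=_name_key,
    )


def connected_pathways(network: MetabolicNetwork, pathway: "Pathway | str") -> list[Pathway]:
    """Pathways sharing at least one metabolite pool with the given pathway.

    Sharing is at pool granularity: the same metabolite in two different
    compartments does not connect two pathways.
    """
    src = network._resolve_pathway(pathway)
    src_pools = {pool.id for rxn in src.reactions for pool in rxn.pools()}
    out = []
    for other in network.pathways.values():
        if other is src:
            continue
        other_pools = {pool.id for rxn in other.reactions for pool in rxn.pools()}
        if src_pools & other_pools:
            out.append(other)
    return sorted(out, key=_name_key)


def collapse_pathway(
    network: MetabolicNetwork,
    pathway: "Pathway | str",
    input_pools: Iterable["MetabolitePool | str"],
    output_pools: Iterable["MetabolitePool | str"],
    compartment: "Compartment | str",
    reaction_id: Optional[str] = None,
) -> Reaction:
    """Lump a whole pathway into one synthetic irreversible reaction.

    The new reaction consumes ``input_pools`` and produces ``output_pools``
    (e.g. glycolysis collapsed to D-Glucose -> Pyruvate), carries no enzymes,
    and is tagged with the pathway it stands for.  The original pathway is left
    untouched.  Self-loop collapses (a pool on both sides) are rejected.
    """
    pw = network._resolve_pathway(pathway)
    comp = network._resolve_compartment(compartment)
    ins = [network._resolve_pool(p) for p in input_pools]
    outs = [network._resolve_pool(p) for p in output_pools]
    if not ins or not outs:
        raise ValidationError("collapse requires non-empty input and output pool sets")
    if {p.id for p in ins} & {p.id for p in outs}:
        raise ValidationError("collapse input and output pools must be disjoint")
    for pool in itertools.chain(ins, outs):
        if not comp.contains(pool.compartment):
            raise ValidationError(
                f"pool {pool.name} lies outside compartment {comp.name!r}"
            )
    rid = reaction_id or f"collapsed:{pw.id}"
    participants: list[tuple[MetabolitePool, Role]] = [(p, Role.SUBSTRATE) for p in ins]
    participants += [(p, Role.PRODUCT) for p in outs]
    return network.add_reaction(
        id=rid,
        name=f"{pw.name} (collapsed)",
        participants=participants,
        reversible=False,
        enzymes=(),
        collapsed_from=pw.id,
    )


def select_subnetwork(
    network: MetabolicNetwork,
    pathways: Iterable["Pathway | str"] = (),
    reactions: Iterable["Reaction | str"] = (),
    collapsed: Iterable["Reaction | str"] = (),
    boundary: Iterable["MetabolitePool | str"] = (),
) -> Subnetwork:
    """Union the reactions of chosen pathways, stand-alone and collapsed reactions."""
    chosen: list[Reaction] = []
    for pw in pathways:
        chosen.extend(network._resolve_pathway(pw).reactions)
    for r in itertools.chain(reactions, collapsed):
        chosen.append(network._resolve_reaction(r))
    if not chosen:
        raise ValidationError("nothing selected: provide at least one pathway or reaction")
    boundary_ids = {network._resolve_pool(p).id for p in boundary}
    return Subnetwork(network=network, reactions=chosen, boundary=boundary_ids)


def is_connected(subnetwork: Subnetwork) -> bool:
    return subnetwork.is_connected()
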