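"""Neighborhood queries over the metabolic-network graph.

Five built-in queries find pathways, reactions and metabolites within *n*
reaction steps of another entity.  Two reactions are adjacent when they share
at least one metabolite pool; traversal ignores edge direction (reversibility
makes directed distance ill-defined), and distances are computed over pools,
not metabolites -- the same metabolite in two compartments does not connect
anything.  A :class:`StepMetric` can exclude currency metabolites (ATP, NADH,
water...) from the adjacency so that distances reflect the carbon backbone
rather than cofactor hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .errors import ValidationError
from .model import MetabolicNetwork, Metabolite, Pathway, Reaction, Role

__all__ = [
    "StepMetric",
    "reaction_graph",
    "pathways_within_steps",
    "reactions_within_steps_in_pathway",
    "reactions_within_steps_in_network",
    "reactions_involving_metabolite",
    "metabolites_within_steps",
]


@dataclass(frozen=True)
class StepMetric:
    """Adjacency rule for step queries: shared-pool adjacency with optional
    currency-metabolite exclusion (by metabolite name, case-insensitive)."""

    exclude_currency: frozenset[str] = frozenset()

    def excluded(self, metabolite: Metabolite) -> bool:
        lowered = {s.lower() for s in self.exclude_currency}
        names = {metabolite.name.lower()} | {s.lower() for s in metabolite.synonyms}
        return bool(names & lowered)


def _metric(metric: Optional[StepMetric], network: MetabolicNetwork) -> StepMetric:
    metric = metric or StepMetric()
    known = {m.name.lower() for m in network.metabolites.values()} | {
        s.lower() for m in network.metabolites.values() for s in m.synonyms
    }
    unknown = {name for name in metric.exclude_currency if name.lower() not in known}
    if unknown:
        raise ValidationError(
            f"currency-exclusion names not in the network: {sorted(unknown)}"
        )
    return metric


def reaction_graph(network: MetabolicNetwork, metric: Optional[StepMetric] = None) -> nx.Graph:
    """Undirected reaction graph: nodes are reaction ids, edges join reactions
    sharing at least one (non-excluded) metabolite pool."""
    metric = _metric(metric, network)
    g = nx.Graph()
    g.add_nodes_from(network.reactions)
    by_pool: dict[str, list[str]] = {}
    for rxn in network.reactions.values():
        for pool in rxn.pools():
            if metric.excluded(pool.metabolite):
                continue
            by_pool.setdefault(pool.id, []).append(rxn.id)
    for rids in by_pool.values():
        for i, a in enumerate(rids):
            for b in rids[i + 1 :]:
                g.add_edge(a, b)
    return g


def _bfs_distances(g: nx.Graph, sources: list[str], cutoff: int) -> dict[str, int]:
    dist: dict[str, int] = {s: 0 for s in sources}
    frontier = list(sources)
    d = 0
    while frontier and d < cutoff:
        d += 1
        nxt = []
        for node in frontier:
            for nb in g.neighbors(node):
                if nb not in dist:
                    dist[nb] = d
                    nxt.append(nb)
        frontier = nxt
    return dist


def pathways_within_steps(
    network: MetabolicNetwork,
    pathway: "Pathway | str",
    n: int,
    metric: Optional[StepMetric] = None,
) -> list[tuple[Pathway, int]]:
    """Pathways with a reaction at most *n* steps from any reaction of the source.

    Distance 0 means sharing a reaction with the source pathway; the source
    itself is excluded.  Each pathway is reported with its minimal distance,
    ordered by (distance, name).
    """
    if n < 0:
        raise ValidationError("step count n must be >= 0")
    src = network._resolve_pathway(pathway)
    g = reaction_graph(network, metric)
    dist = _bfs_distances(g, [r.id for r in src.reactions], cutoff=n)
    out = []
    for other in network.pathways.values():
        if other is src:
            continue
        hits = [dist[r.id] for r in other.reactions if r.id in dist]
        if hits:
            out.append((other, min(hits)))
    return sorted(out, key=lambda t: (t[1], t[0].name, t[0].id))


def _reactions_within(
    network: MetabolicNetwork,
    g: nx.Graph,
    source: Reaction,
    n: int,
) -> list[tuple[Reaction, int]]:
    dist = _bfs_distances(g, [source.id], cutoff=n)
    out = [
        (network.reactions[rid], d)
        for rid, d in dist.items()
        if rid != source.id
    ]
    return sorted(out, key=lambda t: (t[1], t[0].name, t[0].id))


def reactions_within_steps_in_network(
    network: MetabolicNetwork,
    reaction: "Reaction | str",
    n: int,
    metric: Optional[StepMetric] = None,
) -> list[tuple[Reaction, int]]:
    """Reactions at most *n* pool-sharing steps from the source (source excluded)."""
    if n < 0:
        raise ValidationError("step count n must be >= 0")
    src = network._resolve_reaction(reaction)
    return _reactions_within(network, reaction_graph(network, metric), src, n)


def reactions_within_steps_in_pathway(
    network: MetabolicNetwork,
    reaction: "Reaction | str",
    pathway: "Pathway | str",
    n: int,
    metric: Optional[StepMetric] = None,
) -> list[tuple[Reaction, int]]:
    """As the network-wide query, but traversal is restricted to the pathway."""
    if n < 0:
        raise ValidationError("step count n must be >= 0")
    src = network._resolve_reaction(reaction)
    pw = network._resolve_pathway(pathway)
    member_ids = {r.id for r in pw.reactions}
    if src.id not in member_ids:
        raise ValidationError(
            f"reaction {src.name!r} is not part of pathway {pw.name!r}"
        )
    g = reaction_graph(network, metric).subgraph(member_ids).copy()
    return _reactions_within(network, g, src, n)


def reactions_involving_metabolite(
    network: MetabolicNetwork,
    metabolite: "Metabolite | str",
    role: "Role | str",
    pathway: "Pathway | str",
) -> list[Reaction]:
    """Reactions of a pathway with a pool of the metabolite in the given role.

    ``role`` may be any of the four participant roles or ``"any"``.
    """
    met = network._resolve_metabolite(metabolite)
    pw = network._resolve_pathway(pathway)
    roles = list(Role) if str(role).lower() == "any" else [Role.coerce(role)]
    out = []
    for rxn in pw.reactions:
        for part in rxn.participants:
            if part.pool.metabolite is met and part.role in roles:
                out.append(rxn)
                break
    return sorted(out, key=lambda r: (r.name, r.id))


def metabolites_within_steps(
    network: MetabolicNetwork,
    metabolite: "Metabolite | str",
    n: int,
    metric: Optional[StepMetric] = None,
) -> list[tuple[Metabolite, int]]:
    """Metabolites reachable through at most *n* reactions from the source.

    Traversal runs over the bipartite pool-reaction graph, undirected, with
    distance counted in reaction hops; a metabolite's distance is the minimum
    over its pools.  The source metabolite is excluded.
    """
    if n < 1:
        raise ValidationError("step count n must be >= 1")
    metric = _metric(metric, network)
    met = network._resolve_metabolite(metabolite)
    g = nx.Graph()
    for rxn in network.reactions.values():
        for pool in rxn.pools():
            if metric.excluded(pool.metabolite) and pool.metabolite is not met:
                continue
            g.add_edge(("R", rxn.id), ("P", pool.id))
    sources = [
        ("P", p.id)
        for p in network.pools.values()
        if p.metabolite is met and ("P", p.id) in g
    ]
    dist = _bfs_distances(g, sources, cutoff=2 * n)
    best: dict[str, int] = {}
    for (kind, eid), d in dist.items():
        if kind != "P":
            continue
        other = network.pools[eid].metabolite
        if other is met:
            continue
        hops = (d + 1) // 2
        if hops <= n:
            best[other.id] = min(best.get(other.id, hops), hops)
    out = [(network.metabolites[mid], d) for mid, d in best.items()]
    return sorted(out, key=lambda t: (t[1], t[0].name, t[0].id))
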