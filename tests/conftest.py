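import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from smda.fixtures import (  # noqa: E402
    make_tca_glycolysis_input,
    make_urea_cycle_network,
)


@pytest.fixture(scope="session")
def urea_network():
    return make_urea_cycle_network()


@pytest.fixture()
def tca_input():
    return make_tca_glycolysis_input()


def bfs_component_oracle(nodes, edges):
    """Plain breadth-first connectivity check, independent of the package."""
    nodes = list(nodes)
    if not nodes:
        return True
    adjacency = {n: set() for n in nodes}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    seen = {nodes[0]}
    queue = [nodes[0]]
    while queue:
        node = queue.pop()
        for nb in adjacency[node]:
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return len(seen) == len(nodes)


def bfs_distance_oracle(adjacency, sources):
    """Plain BFS distances from a set of source nodes."""
    dist = {s: 0 for s in sources}
    frontier = list(sources)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for node in frontier:
            for nb in adjacency.get(node, ()):
                if nb not in dist:
                    dist[nb] = d
                    nxt.append(nb)
        frontier = nxt
    return dist


def shared_pool_adjacency(network, excluded_names=()):
    """Reaction adjacency (shared participant pool), built from first principles."""
    lowered = {n.lower() for n in excluded_names}
    adjacency = {rid: set() for rid in network.reactions}
    reactions = list(network.reactions.values())
    for i, a in enumerate(reactions):
        pools_a = {
            p.id
            for p in a.pools()
            if p.metabolite.name.lower() not in lowered
        }
        for b in reactions[i + 1 :]:
            pools_b = {
                p.id
                for p in b.pools()
                if p.metabolite.name.lower() not in lowered
            }
            if pools_a & pools_b:
                adjacency[a.id].add(b.id)
                adjacency[b.id].add(a.id)
    return adjacency
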