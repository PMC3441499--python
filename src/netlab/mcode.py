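"""Molecular-complex detection by seeded greedy growth (MCODE-style).

Vertices are weighted by the density of the highest k-core of their closed
neighborhood; complexes grow greedily from the heaviest unvisited seed,
admitting neighbors whose weight stays within a percentage of the seed's
weight, then are pruned (haircut) and filtered for a dense core.

Density convention: throughout this module the density of a subgraph with V
vertices and E edges is the loop-inclusive ratio DC = E / V**2, and a cluster's
score is DC * V = E / V.  This is the convention under which published
cluster tables report, e.g., a 13-protein, 78-edge complex scoring 6.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable

import networkx as nx

from ._util import fmt1


@dataclass(frozen=True)
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 3
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if not (0.0 <= self.node_score_cutoff <= 1.0):
            raise ValueError("node_score_cutoff must lie in [0, 1]")


@dataclass(frozen=True)
class MCODECluster:
    seed: Hashable
    members: frozenset
    internal_edges: int

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def density(self) -> float:
        """Loop-inclusive density DC = E / V**2."""
        return self.internal_edges / len(self.members) ** 2

    @property
    def score(self) -> float:
        """DC * |V|, which reduces to internal_edges / |members|."""
        return self.internal_edges / len(self.members)


def loop_inclusive_density(v_count: int, e_count: int) -> float:
    if v_count < 1:
        raise ValueError("v_count must be >= 1")
    return e_count / v_count ** 2


def score_cluster(v_count: int, e_count: int) -> float:
    """Cluster score DC * |V| = e_count / v_count."""
    if v_count < 1:
        raise ValueError("v_count must be >= 1")
    if e_count < 0:
        raise ValueError("e_count must be >= 0")
    return e_count / v_count


def render_score(v_count: int, e_count: int) -> str:
    """Score rendered to one decimal, half-up, as in cluster tables."""
    return fmt1(score_cluster(v_count, e_count))


def weight_vertices(network: nx.Graph,
                    params: MCODEParams = MCODEParams()) -> dict[Hashable, float]:
    """Core-density vertex weights.

    For each node with degree >= degree_cutoff: take the highest k-core of the
    node's closed neighborhood; weight = k * (loop-inclusive density of that
    core).  Nodes below the degree cutoff weigh 0.
    """
    weights: dict[Hashable, float] = {}
    for v in network:
        if network.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = list(network.neighbors(v)) + [v]
        sub = network.subgraph(closed)
        core_numbers = nx.core_number(sub)
        k_max = max(core_numbers.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core_nodes = [n for n, c in core_numbers.items() if c >= k_max]
        core = sub.subgraph(core_nodes)
        weights[v] = k_max * loop_inclusive_density(
            core.number_of_nodes(), core.number_of_edges())
    return weights


def haircut(members: Iterable[Hashable], network: nx.Graph) -> frozenset:
    """Iteratively strip members with < 2 within-cluster edges (2-core fixed point)."""
    current = set(members)
    while True:
        sub = network.subgraph(current)
        weak = {n for n in current if sub.degree(n) < 2}
        if not weak:
            return frozenset(current)
        current -= weak


def _grow(network: nx.Graph, seed: Hashable, weights: dict[Hashable, float],
          visited: set, params: MCODEParams) -> set:
    threshold = (1.0 - params.node_score_cutoff) * weights[seed]
    members = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < params.max_depth:
        nxt = []
        for u in frontier:
            for w in network.neighbors(u):
                if w in members or w in visited:
                    continue
                if weights[w] >= threshold:
                    members.add(w)
                    nxt.append(w)
        frontier = nxt
        depth += 1
    return members


def _fluff(network: nx.Graph, members: set, visited: set,
           params: MCODEParams) -> set:
    """Optionally append boundary neighbors with dense closed neighborhoods."""
    extra = set()
    for u in sorted(members, key=str):
        for w in network.neighbors(u):
            if w in members or w in extra or w in visited:
                continue
            closed = list(network.neighbors(w)) + [w]
            sub = network.subgraph(closed)
            dens = loop_inclusive_density(sub.number_of_nodes(),
                                          sub.number_of_edges())
            if dens > params.fluff_density:
                extra.add(w)
    return members | extra


def find_clusters(network: nx.Graph,
                  params: MCODEParams = MCODEParams()) -> list[MCODECluster]:
    """Predict complexes: weight, grow, haircut, k-core filter, score, rank.

    Seeds are visited in descending weight (ties by symbol), and grown members
    are marked visited, so reported clusters are node-disjoint.  A cluster is
    kept only if its induced subgraph contains a ``k_core``-core.  If the
    haircut disconnects a cluster, the component containing the seed is kept.
    Ranking: score desc, size desc, seed symbol asc.
    """
    weights = weight_vertices(network, params)
    order = sorted(network, key=lambda n: (-weights[n], str(n)))
    visited: set = set()
    clusters: list[MCODECluster] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        members = _grow(network, seed, weights, visited, params)
        visited |= members
        if params.fluff:
            members = _fluff(network, members, visited - members, params)
        if params.haircut:
            members = set(haircut(members, network))
            if not members:
                continue
            sub = network.subgraph(members)
            if not nx.is_connected(sub):
                comps = sorted(nx.connected_components(sub),
                               key=lambda c: (-len(c), min(map(str, c))))
                keep = next((c for c in comps if seed in c), comps[0])
                members = set(keep)
        if not members:
            continue
        sub = network.subgraph(members)
        if max(nx.core_number(sub).values()) < params.k_core:
            continue
        cluster_seed = seed if seed in members else \
            max(members, key=lambda n: (weights[n], str(n)))
        clusters.append(MCODECluster(seed=cluster_seed,
                                     members=frozenset(members),
                                     internal_edges=sub.number_of_edges()))
    clusters.sort(key=lambda c: (-c.score, -c.size, str(c.seed)))
    return clusters
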