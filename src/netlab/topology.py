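"""Degree distribution, power-law fit, clustering, paths, components, hubs.

The degree-exponent fit follows the log-log least-squares convention used by
standard network-metric tools: raw node counts N(k) are regressed on degree k
on log10-log10 axes, with no binning, over degrees k >= 1 with N(k) > 0, and
the exponent gamma is the negated slope.  (Maximum-likelihood power-law
estimation is deliberately out of scope.)

The global clustering coefficient is the arithmetic mean of the per-node local
coefficients over ALL nodes, with nodes of degree < 2 contributing 0 — the
convention of NetworkAnalyzer-style tools, not the transitivity ratio.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
from scipy import stats


@dataclass(frozen=True)
class DegreeDistribution:
    """Node counts N(k) per degree k; probabilities are N(k)/N."""

    counts: Mapping[int, float]
    n_total: int

    def probabilities(self) -> dict[int, float]:
        return {k: c / self.n_total for k, c in self.counts.items()}


@dataclass(frozen=True)
class PowerLawFit:
    gamma: float          # degree exponent (negated slope)
    prefactor: float      # 10**intercept
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class PathStats:
    histogram: Mapping[int, int]   # shortest-path length -> unordered pair count
    mean: float
    max: int


@dataclass(frozen=True)
class ClusteringReport:
    per_node: Mapping[Hashable, float]
    global_coefficient: float


@dataclass(frozen=True)
class ComponentReport:
    components: tuple[frozenset, ...]   # largest first
    isolates: frozenset


@dataclass(frozen=True)
class HubReport:
    ranked_degrees: tuple[tuple[Hashable, int], ...]
    hubs: frozenset
    second_tier: frozenset


def degree_distribution(network: nx.Graph) -> DegreeDistribution:
    """Exact degree counts; zero-degree nodes appear under k = 0."""
    counts = Counter(d for _, d in network.degree())
    return DegreeDistribution(counts=dict(counts), n_total=network.number_of_nodes())


def fit_power_law(dd: DegreeDistribution) -> PowerLawFit:
    """OLS of log10 N(k) on log10 k over k >= 1, N(k) > 0; gamma = -slope."""
    pts = sorted((k, c) for k, c in dd.counts.items() if k >= 1 and c > 0)
    if len(pts) < 3:
        raise ValueError("power-law fit needs >= 3 distinct positive degrees")
    x = np.log10([k for k, _ in pts])
    y = np.log10([c for _, c in pts])
    res = stats.linregress(x, y)
    return PowerLawFit(gamma=-res.slope, prefactor=10.0 ** res.intercept,
                       r_squared=res.rvalue ** 2, n_points=len(pts))


def local_clustering(network: nx.Graph, node: Hashable) -> float:
    """Neighbor-pair connectance t/(d(d-1)/2); 0 for degree < 2."""
    if node not in network:
        raise ValueError(f"unknown node {node!r}")
    return nx.clustering(network, node)


def global_clustering(network: nx.Graph) -> ClusteringReport:
    """Mean of local coefficients over all nodes (degree <2 counted as 0)."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    per_node = nx.clustering(network)
    return ClusteringReport(per_node=per_node,
                            global_coefficient=sum(per_node.values()) / len(per_node))


def path_length_stats(network: nx.Graph) -> PathStats:
    """BFS from every node; histogram over reachable unordered pairs.

    Disconnected pairs are excluded rather than assigned infinite length, so
    the mean stays finite on graphs with several components.
    """
    if network.number_of_edges() == 0:
        raise ValueError("path statistics require at least one edge")
    hist: Counter[int] = Counter()
    for source, lengths in nx.all_pairs_shortest_path_length(network):
        for target, length in lengths.items():
            if length > 0:
                hist[length] += 1
    # every reachable pair was seen from both endpoints
    histogram = {length: c // 2 for length, c in sorted(hist.items())}
    total = sum(histogram.values())
    mean = sum(length * c for length, c in histogram.items()) / total
    return PathStats(histogram=histogram, mean=mean, max=max(histogram))


def connected_components(network: nx.Graph) -> ComponentReport:
    """Components largest first (ties by smallest member); isolates listed apart."""
    comps = [frozenset(c) for c in nx.connected_components(network)]
    comps.sort(key=lambda c: (-len(c), min(map(str, c))))
    isolates = frozenset(n for n in network if network.degree(n) == 0)
    return ComponentReport(components=tuple(comps), isolates=isolates)


def _descending_degrees(network: nx.Graph) -> list[tuple[Hashable, int]]:
    return sorted(network.degree(), key=lambda nd: (-nd[1], str(nd[0])))


def identify_hubs(network: nx.Graph, method: str = "degree_gap",
                  param: float = 0.1) -> HubReport:
    """Identify hub nodes from the degree sequence.

    ``top_fraction``: hubs are nodes whose degree strictly exceeds the
    (1 - param) empirical quantile of the degree sequence.

    ``degree_gap``: scan the descending degree sequence within the top
    ``param`` fraction of nodes for the largest drop between consecutive
    ranks; hubs sit above that drop (ties in drop size resolve to the deeper
    cut).  A second tier sits between the hub cut and the next-largest drop
    below it.  This reproduces tiered hub structure that a verbal
    "top ~20%" rule cannot resolve.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    ranked = _descending_degrees(network)
    degrees = [d for _, d in ranked]
    if method == "top_fraction":
        if not (0.0 < param < 1.0):
            raise ValueError("param must lie in (0, 1) for top_fraction")
        threshold = float(np.quantile(degrees, 1.0 - param))
        hubs = frozenset(n for n, d in ranked if d > threshold)
        return HubReport(ranked_degrees=tuple(ranked), hubs=hubs,
                         second_tier=frozenset())
    if method != "degree_gap":
        raise ValueError(f"unknown hub method {method!r}")
    limit = max(1, math.ceil(param * len(degrees)))
    limit = min(limit, len(degrees) - 1)
    if limit < 1:
        return HubReport(ranked_degrees=tuple(ranked), hubs=frozenset(),
                         second_tier=frozenset())
    gaps = [degrees[i] - degrees[i + 1] for i in range(limit)]
    best = max(gaps)
    if best <= 0:   # degree-regular head: no distinguished hubs
        return HubReport(ranked_degrees=tuple(ranked), hubs=frozenset(),
                         second_tier=frozenset())
    cut = max(i for i, g in enumerate(gaps) if g == best)
    hub_floor = degrees[cut]
    hubs = frozenset(n for n, d in ranked if d >= hub_floor)
    second_tier: frozenset = frozenset()
    tail = gaps[cut + 1:]
    if tail and max(tail) > 0:
        best2 = max(tail)
        cut2 = cut + 1 + max(i for i, g in enumerate(tail) if g == best2)
        second_floor = degrees[cut2]
        second_tier = frozenset(n for n, d in ranked
                                if second_floor <= d < hub_floor)
    return HubReport(ranked_degrees=tuple(ranked), hubs=hubs,
                     second_tier=second_tier)


def degree_share(degrees: list[int] | tuple[int, ...], total_edges: int) -> float:
    """Percent of all network connections accounted for by the given degrees.

    Follows the reporting convention of dividing the summed degrees by the
    total edge count (each edge contributes two degree endpoints network-wide,
    but a node group's connections are its summed degrees).
    """
    if total_edges <= 0:
        raise ValueError("total_edges must be positive")
    return 100.0 * sum(degrees) / total_edges
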