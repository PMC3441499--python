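"""Betweenness-based bottleneck ranking and hub/bottleneck intersection.

Bottlenecks are nodes carrying many non-redundant shortest paths.  The default
scoring is fractional-credit betweenness (each s-t pair distributes one unit
of credit across its shortest paths, sigma_st(v)/sigma_st), unnormalized and
over unordered pairs — the convention of the centrality plugins used for
published PPI analyses.  A strict-count mode (a pair credits v with 1 if ANY
shortest s-t path passes v) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import networkx as nx


@dataclass(frozen=True)
class BottleneckReport:
    ranked: tuple[tuple[Hashable, float], ...]
    top_k: frozenset
    hub_bottlenecks: frozenset
    has_ties: bool


def betweenness(network: nx.Graph, mode: str = "fractional") -> dict[Hashable, float]:
    """Unnormalized betweenness per node (unordered-pair convention)."""
    if mode == "fractional":
        return nx.betweenness_centrality(network, normalized=False)
    if mode != "strict":
        raise ValueError(f"unknown mode {mode!r}")
    scores: dict[Hashable, float] = {n: 0.0 for n in network}
    nodes = sorted(network, key=str)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(network, s, t):
                continue
            interior: set = set()
            for path in nx.all_shortest_paths(network, s, t):
                interior.update(path[1:-1])
            for v in interior:
                scores[v] += 1.0
    return scores


def top_bottlenecks(scores: Mapping[Hashable, float], k: int = 10,
                    hubs: Iterable[Hashable] = ()) -> BottleneckReport:
    """Rank descending by score (ties lexicographic) and take the top k.

    Nodes tied with the k-th score are included (tie expansion) and flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scores):
        raise ValueError(f"k = {k} exceeds node count {len(scores)}")
    ranked = sorted(scores.items(), key=lambda ns: (-ns[1], str(ns[0])))
    kth_score = ranked[k - 1][1]
    top = [n for n, s in ranked if s > kth_score]
    tied = [n for n, s in ranked if s == kth_score]
    top_k = frozenset(top) | frozenset(tied)
    return BottleneckReport(
        ranked=tuple(ranked),
        top_k=top_k,
        hub_bottlenecks=top_k & frozenset(hubs),
        has_ties=len(top) + len(tied) > k,
    )


def pairwise_bottleneck_paths(network: nx.Graph, nodes: Iterable[Hashable],
                              near_limit: int = 3,
                              ) -> dict[tuple, tuple[int | None, bool]]:
    """Shortest-path length for each unordered pair of the given nodes.

    Returns pair -> (length, is_distant); unreachable pairs record
    ``(None, False)``.  ``is_distant`` flags lengths beyond ``near_limit``
    (immediate vs nearest-neighbor connections in the reports).
    """
    node_list = sorted(set(nodes), key=str)
    missing = [n for n in node_list if n not in network]
    if missing:
        raise ValueError(f"nodes not in network: {missing}")
    out: dict[tuple, tuple[int | None, bool]] = {}
    for i, a in enumerate(node_list):
        for b in node_list[i + 1:]:
            try:
                length = nx.shortest_path_length(network, a, b)
                out[(a, b)] = (length, length > near_limit)
            except nx.NetworkXNoPath:
                out[(a, b)] = (None, False)
    return out
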