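"""Seeded generators for networks and STRING-style interaction fixtures.

These generators make every stage of the pipeline testable without database
downloads: growth models (partial duplication, preferential attachment),
Erdős–Rényi baselines, and a curated-export emulator that plants known
cross-subfamily overlap structure and draws confidence scores from a
truncated normal on [0.4, 1.0].

All output is a pure function of the parameter record including its RNG seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.stats import truncnorm

from .network_io import InteractionRecord, ProteinNode, OTHER

#: Subfamily seed-list sizes of the curated GTPase search (searched isoforms).
DEFAULT_SUBFAMILY_SIZES: dict[str, int] = {
    "RHO": 22, "RAS": 29, "RAB": 59, "ARF": 26, "RAN": 1, "RGK": 4,
}

#: Cross-subfamily overlap design: exact counts of shared partner proteins
#: per subfamily-network combination (one 4-way, seven 3-way, 76 pairwise).
DEFAULT_PLANTED_OVERLAPS: dict[frozenset, int] = {
    frozenset({"ARF", "RHO", "RAS", "RAB"}): 1,
    frozenset({"ARF", "RAB", "RHO"}): 1,
    frozenset({"RAB", "RAS", "RHO"}): 2,
    frozenset({"ARF", "RAS", "RHO"}): 4,
    frozenset({"RHO", "RAS"}): 36,
    frozenset({"RHO", "RAB"}): 9,
    frozenset({"RAS", "RAB"}): 9,
    frozenset({"RAB", "ARF"}): 8,
    frozenset({"RHO", "ARF"}): 6,
    frozenset({"RAS", "ARF"}): 5,
    frozenset({"RAN", "RHO"}): 2,
    frozenset({"RAN", "ARF"}): 1,
}


@dataclass(frozen=True)
class DuplicationParams:
    n_target: int
    p_retain: float = 0.45
    seed_graph_size: int = 4
    rng_seed: int = 0
    keep_isolates: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_retain <= 1.0):
            raise ValueError("p_retain must lie in (0, 1]")
        if self.seed_graph_size < 3:
            raise ValueError("seed_graph_size must be >= 3")
        if self.n_target < self.seed_graph_size:
            raise ValueError("n_target must be >= seed_graph_size")


@dataclass(frozen=True)
class FixtureSpec:
    subfamily_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBFAMILY_SIZES))
    n_total: int = 778
    target_edges: int = 1943
    confidence_mean: float = 0.66
    confidence_sd: float = 0.146
    confidence_floor: float = 0.4
    planted_overlaps: Mapping[frozenset, int] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_OVERLAPS))
    triangle_fraction: float = 0.15   # share of edges spent closing seed-centred wedges
    rng_seed: int = 0


def generate_partial_duplication(params: DuplicationParams) -> nx.Graph:
    """Grow a graph by partial node duplication.

    Start from a small complete seed graph; repeatedly pick a uniform random
    existing node and add a copy connected to each of its neighbors
    independently with probability ``p_retain``.  Copies that keep no edge are
    redrawn unless ``keep_isolates`` is set (isolated nodes then emulate
    seeds with no validated partners).
    """
    rng = np.random.default_rng(params.rng_seed)
    g: nx.Graph = nx.complete_graph(params.seed_graph_size)
    n = params.seed_graph_size
    while n < params.n_target:
        anchor = int(rng.integers(0, n))
        neighbors = list(g.neighbors(anchor))
        kept = [v for v in neighbors if rng.random() < params.p_retain]
        if not kept and not params.keep_isolates:
            continue
        g.add_node(n)
        g.add_edges_from((n, v) for v in kept)
        n += 1
    return g


def generate_preferential_attachment(n: int, m: int, rng_seed: int = 0) -> nx.Graph:
    """Rich-get-richer growth: start from K_{m+1}, attach each new node to m
    distinct existing nodes chosen with probability proportional to degree."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if n <= m:
        raise ValueError("n must exceed m")
    rng = np.random.default_rng(rng_seed)
    g: nx.Graph = nx.complete_graph(m + 1)
    for new in range(m + 1, n):
        nodes = np.arange(new)
        degrees = np.array([g.degree(int(v)) for v in nodes], dtype=float)
        probs = degrees / degrees.sum()
        targets = rng.choice(nodes, size=m, replace=False, p=probs)
        g.add_edges_from((new, int(t)) for t in targets)
    return g


def generate_er(n: int, p_edge: float, rng_seed: int = 0) -> nx.Graph:
    """Erdős–Rényi G(n, p) baseline (each unordered pair independent)."""
    if not (0.0 <= p_edge <= 1.0):
        raise ValueError("p_edge must lie in [0, 1]")
    return nx.gnp_random_graph(n, p_edge, seed=int(rng_seed))


def _truncated_normal_scores(rng: np.random.Generator, size: int,
                             mean: float, sd: float, floor: float) -> np.ndarray:
    a = (floor - mean) / sd
    b = (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def seed_symbols(sizes: Mapping[str, int]) -> dict[str, list[str]]:
    """Deterministic seed GTPase symbols per subfamily (e.g. RHO001...)."""
    return {label: [f"{label}{i + 1:03d}" for i in range(count)]
            for label, count in sizes.items()}


def generate_string_fixture(spec: FixtureSpec = FixtureSpec()
                            ) -> tuple[list[InteractionRecord], dict[str, ProteinNode]]:
    """Emit an edge table and annotation table with planted structure.

    The fixture carries: subfamily-labelled GTPase seeds with hub-skewed
    attachment weights, partner proteins planted to occur in exactly the
    subfamily-network combinations given by ``planted_overlaps``, filler
    partners confined to a single subfamily (so the planted overlap counts
    are recovered exactly by the cross-talk analysis), heavy-tailed partner
    degrees topped up toward ``target_edges``, and truncated-normal
    confidence scores on [floor, 1.0].
    """
    rng = np.random.default_rng(spec.rng_seed)
    seeds = seed_symbols(spec.subfamily_sizes)
    labels = sorted(seeds)
    n_seeds = sum(len(v) for v in seeds.values())
    n_shared = sum(spec.planted_overlaps.values())
    n_fill = spec.n_total - n_seeds - n_shared
    if n_fill < 0:
        raise ValueError("n_total too small for seeds plus planted overlap proteins")
    for combo in spec.planted_overlaps:
        unknown = set(combo) - set(seeds)
        if unknown:
            raise ValueError(f"planted overlap names unknown subfamilies {unknown}")

    # hub-skewed attachment weights: Zipf-like within each subfamily
    weights = {label: np.array([1.0 / (i + 1) ** 1.1 for i in range(len(syms))])
               for label, syms in seeds.items()}

    def pick_seeds(label: str, count: int) -> list[str]:
        syms = seeds[label]
        p = weights[label] / weights[label].sum()
        chosen = rng.choice(len(syms), size=count, replace=False, p=p)
        return [syms[int(i)] for i in chosen]

    edges: list[tuple[str, str]] = []
    edge_set: set[frozenset] = set()

    def add_edge(a: str, b: str) -> bool:
        key = frozenset((a, b))
        if a == b or key in edge_set:
            return False
        edge_set.add(key)
        edges.append((a, b))
        return True

    # planted cross-subfamily partners: one edge into each named subfamily
    shared_idx = 0
    for combo in sorted(spec.planted_overlaps, key=lambda c: (len(c), sorted(c))):
        for _ in range(spec.planted_overlaps[combo]):
            shared_idx += 1
            partner = f"XS{shared_idx:04d}"
            for label in sorted(combo):
                add_edge(partner, pick_seeds(label, 1)[0])

    # filler partners: confined to one subfamily, heavy-tailed degree
    label_probs = np.array([len(seeds[l]) for l in labels], dtype=float)
    label_probs /= label_probs.sum()
    fill_partners: list[tuple[str, str]] = []   # (partner, its subfamily)
    for i in range(n_fill):
        partner = f"XP{i + 1:04d}"
        label = labels[int(rng.choice(len(labels), p=label_probs))]
        cap = min(6, len(seeds[label]))
        degree = min(int(rng.zipf(2.0)), cap)
        for s in pick_seeds(label, degree):
            add_edge(partner, s)
        fill_partners.append((partner, label))

    # close seed-centred wedges between partner neighbors: gives the fixture
    # triangle enrichment (non-zero clustering) without altering any protein's
    # subfamily-network membership, which only seed-incident edges determine
    neighbor_map: dict[str, list[str]] = {}
    for a, b in edges:
        partner, seed = (a, b) if a.startswith("X") else (b, a)
        if partner.startswith("X"):
            neighbor_map.setdefault(seed, []).append(partner)
    wedge_seeds = sorted(s for s, ps in neighbor_map.items() if len(ps) >= 2)
    target_closures = int(spec.triangle_fraction * spec.target_edges)
    closures = attempts = 0
    while wedge_seeds and closures < target_closures and attempts < 50 * spec.target_edges:
        attempts += 1
        s = wedge_seeds[int(rng.integers(0, len(wedge_seeds)))]
        partners = neighbor_map[s]
        i, j = rng.choice(len(partners), size=2, replace=False)
        if add_edge(partners[int(i)], partners[int(j)]):
            closures += 1

    # top up toward the target edge count without breaking planted combinations
    attempts = 0
    while len(edges) < spec.target_edges and attempts < 50 * spec.target_edges:
        attempts += 1
        partner, label = fill_partners[int(rng.integers(0, len(fill_partners)))]
        add_edge(partner, pick_seeds(label, 1)[0])

    scores = _truncated_normal_scores(rng, len(edges), spec.confidence_mean,
                                      spec.confidence_sd, spec.confidence_floor)
    records = [InteractionRecord(a, b, float(round(s, 3)), "synthetic")
               for (a, b), s in zip(edges, scores)]

    annotations: dict[str, ProteinNode] = {}
    for label, syms in seeds.items():
        for s in syms:
            annotations[s] = ProteinNode(s, label, is_gtpase=True)
    return records, annotations


def fixture_seed_table(spec: FixtureSpec = FixtureSpec()) -> dict[str, frozenset]:
    """Subfamily -> seed symbol set, matching :func:`generate_string_fixture`."""
    return {label: frozenset(syms)
            for label, syms in seed_symbols(spec.subfamily_sizes).items()}
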