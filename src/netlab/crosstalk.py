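"""Per-subfamily subnetworks and cross-talk overlap reporting.

A subfamily network is built from the curated records by keeping every edge
incident to at least one of the subfamily's seed GTPases; non-seed endpoints
join as first-neighbor members.  Proteins that appear in two or more subfamily
networks are candidate cross-talk mediators; they are grouped by the exact
combination of subfamily networks they occur in.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .network_io import InteractionRecord


@dataclass(frozen=True)
class SubfamilyNetwork:
    subfamily: str
    seeds: frozenset
    network: nx.Graph

    @property
    def members(self) -> frozenset:
        return frozenset(self.network.nodes)


@dataclass(frozen=True)
class OverlapReport:
    membership: Mapping[str, frozenset]            # protein -> subfamily labels (>= 2)
    by_count: Mapping[int, frozenset]              # k -> proteins in exactly k networks
    by_combination: Mapping[frozenset, int]        # label set -> protein count
    combination_members: Mapping[frozenset, frozenset]


@dataclass(frozen=True)
class CoverageStats:
    per_subfamily: Mapping[str, tuple[int, int]]   # label -> (searched, with >=1 record)


def subfamily_network(records: Sequence[InteractionRecord], seeds: Iterable[str],
                      label: str) -> SubfamilyNetwork:
    """Seed-incident subnetwork: seeds, their first neighbors, seed-incident edges."""
    seed_set = frozenset(s.strip().upper() for s in seeds)
    if not seed_set:
        raise ValueError("seed set must be non-empty")
    g = nx.Graph()
    g.add_nodes_from(seed_set)
    for r in records:
        a, b = r.pair
        if a == b:
            continue
        if a in seed_set or b in seed_set:
            g.add_edge(a, b, confidence=r.confidence, evidence=r.evidence_tag)
    return SubfamilyNetwork(subfamily=label.strip().upper(),
                            seeds=seed_set, network=g)


def shared_proteins(subnetworks: Sequence[SubfamilyNetwork],
                    include_seeds: bool = True) -> OverlapReport:
    """Proteins present in >= 2 subfamily networks, grouped by label combination.

    ``include_seeds=False`` drops proteins that are seed GTPases of any
    subfamily from the report (the overlap counts then cover only non-GTPase
    mediators).
    """
    if len(subnetworks) < 2:
        raise ValueError("need at least 2 subfamily networks")
    all_seeds = frozenset().union(*(sn.seeds for sn in subnetworks))
    membership_all: dict[str, set] = defaultdict(set)
    for sn in subnetworks:
        for protein in sn.members:
            membership_all[protein].add(sn.subfamily)
    membership = {p: frozenset(labels) for p, labels in membership_all.items()
                  if len(labels) >= 2 and (include_seeds or p not in all_seeds)}
    by_count: dict[int, set] = defaultdict(set)
    by_combination: dict[frozenset, int] = defaultdict(int)
    combination_members: dict[frozenset, set] = defaultdict(set)
    for protein, labels in membership.items():
        by_count[len(labels)].add(protein)
        by_combination[labels] += 1
        combination_members[labels].add(protein)
    return OverlapReport(
        membership=membership,
        by_count={k: frozenset(v) for k, v in by_count.items()},
        by_combination=dict(by_combination),
        combination_members={k: frozenset(v) for k, v in combination_members.items()},
    )


def first_neighbors(network: nx.Graph, protein: str) -> list[str]:
    """Sorted adjacency list of the protein."""
    if protein not in network:
        raise ValueError(f"unknown protein {protein!r}")
    return sorted(network.neighbors(protein))


def coverage_stats(seed_table: Mapping[str, Iterable[str]],
                   records: Sequence[InteractionRecord]) -> CoverageStats:
    """Per subfamily: seeds searched vs seeds with at least one interaction record."""
    mentioned = set()
    for r in records:
        mentioned.add(r.source_symbol)
        mentioned.add(r.target_symbol)
    per: dict[str, tuple[int, int]] = {}
    for label, seeds in seed_table.items():
        seed_set = {s.strip().upper() for s in seeds}
        per[label.strip().upper()] = (len(seed_set), len(seed_set & mentioned))
    return CoverageStats(per_subfamily=per)
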