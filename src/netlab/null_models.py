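"""Degree-preserving randomization, null ensembles, and the one-sample Z test.

The rewiring move: pick two edges (u, v) and (s, t) with all four endpoints
pairwise distinct and with (u, t) and (s, v) absent from the graph; delete the
two edges and insert (u, t) and (s, v).  Every accepted move preserves every
node's degree exactly, so the shuffled graph is a draw from the fixed-degree
null model.  The null ensemble repeats the shuffle and records a statistic
(here, the global clustering coefficient) per replicate; significance of the
observed value is assessed with a one-sample Z test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Hashable

import networkx as nx
import numpy as np
from scipy import stats

from .mcode import MCODECluster, MCODEParams, find_clusters
from .topology import global_clustering

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RewireParams:
    swaps_per_edge: float = 10.0
    max_attempts_factor: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swaps_per_edge <= 0:
            raise ValueError("swaps_per_edge must be positive")


@dataclass(frozen=True)
class NullEnsemble:
    values: tuple[float, ...]

    @property
    def n_reps(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample (n-1) standard deviation."""
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class ZTestResult:
    z_sd: float      # (observed - null mean) / null SD
    z_se: float      # (observed - null mean) / (null SD / sqrt(n))
    p_two_sided: float


def degree_preserving_rewire(network: nx.Graph,
                             params: RewireParams = RewireParams()) -> nx.Graph:
    """Return a degree-preserving shuffle of the network (seeded, reproducible).

    Performs ``ceil(swaps_per_edge * |E|)`` successful swaps, or stops with a
    logged warning after ``max_attempts_factor`` times that many failed
    proposals (degenerate graphs such as triangles come back unchanged).
    Node attributes are carried over; edge attributes are dropped (a rewired
    edge has no single provenance).
    """
    m = network.number_of_edges()
    out = nx.Graph()
    out.add_nodes_from(network.nodes(data=True))
    out.add_edges_from((a, b) for a, b in network.edges())
    if m < 2:
        logger.warning("rewire: fewer than 2 edges, returning copy unchanged")
        return out
    rng = np.random.default_rng(params.seed)
    edges = [tuple(e) for e in out.edges()]
    target = math.ceil(params.swaps_per_edge * m)
    max_attempts = params.max_attempts_factor * target
    successes = attempts = 0
    while successes < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        u, v = edges[i]
        s, t = edges[j]
        if rng.integers(0, 2):   # random orientation of the second edge
            s, t = t, s
        if len({u, v, s, t}) < 4:
            continue
        if out.has_edge(u, t) or out.has_edge(s, v):
            continue
        out.remove_edge(u, v)
        out.remove_edge(s, t)
        out.add_edge(u, t)
        out.add_edge(s, v)
        edges[i] = (u, t)
        edges[j] = (s, v)
        successes += 1
    if successes < target:
        logger.warning("rewire: only %d of %d target swaps achieved after %d proposals",
                       successes, target, attempts)
    return out


def null_ensemble(network: nx.Graph,
                  statistic: Callable[[nx.Graph], float],
                  n_reps: int = 100,
                  params: RewireParams = RewireParams()) -> NullEnsemble:
    """Independent rewires (seed + replicate index), one statistic per replicate."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    values = []
    for rep in range(n_reps):
        shuffled = degree_preserving_rewire(
            network, replace(params, seed=params.seed + rep))
        values.append(float(statistic(shuffled)))
    return NullEnsemble(values=tuple(values))


def null_clustering_ensemble(network: nx.Graph, n_reps: int = 100,
                             params: RewireParams = RewireParams()) -> NullEnsemble:
    """Null distribution of the global clustering coefficient."""
    return null_ensemble(network,
                         lambda g: global_clustering(g).global_coefficient,
                         n_reps=n_reps, params=params)


def one_sample_z(observed: float, ensemble: NullEnsemble) -> ZTestResult:
    """One-sample Z test of the observed statistic against the null ensemble.

    Reports z under both conventions (per null SD, and per standard error of
    the null mean); the two-sided p value uses the standard-error z.  The sign
    follows observed - null (an observed value above the null mean gives a
    positive z).
    """
    diff = observed - ensemble.mean
    if ensemble.sd == 0.0:
        z = math.copysign(math.inf, diff) if diff != 0.0 else 0.0
        return ZTestResult(z_sd=z, z_se=z, p_two_sided=1.0 if diff == 0.0 else 0.0)
    z_sd = diff / ensemble.sd
    z_se = diff / (ensemble.sd / math.sqrt(ensemble.n_reps))
    p = 2.0 * stats.norm.sf(abs(z_se))
    return ZTestResult(z_sd=z_sd, z_se=z_se, p_two_sided=float(p))


def randomized_mcode_control(network: nx.Graph,
                             rewire: RewireParams = RewireParams(),
                             mcode: MCODEParams = MCODEParams()
                             ) -> list[MCODECluster]:
    """Cluster search on one degree-preserving shuffle (module-detection control)."""
    shuffled = degree_preserving_rewire(network, rewire)
    return find_clusters(shuffled, mcode)
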