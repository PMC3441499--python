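"""End-to-end pipeline orchestration and rendering of summary tables.

Stages run in a fixed order (ingest -> merge -> topology -> centrality ->
module detection -> null model -> cross-talk) and every number in the report
bundle is recomputable from the recorded inputs and seed.  Rendered tables use
half-up one-decimal rounding; JSON output keeps full precision alongside.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import centrality, crosstalk, mcode, network_io, null_models, topology
from ._util import fmt1
from .mcode import MCODECluster, MCODEParams
from .null_models import RewireParams


@dataclass
class PipelineConfig:
    edges: str
    fmt: str = "tsv"
    annotations: str | None = None
    exclude: str | None = None
    seed_table: str | None = None          # optional: subfamily seed lists for cross-talk
    min_confidence: float = 0.4
    hub_method: str = "degree_gap"
    hub_param: float = 0.1
    bottleneck_k: int = 10
    mcode: MCODEParams = field(default_factory=MCODEParams)
    rewire: RewireParams = field(default_factory=RewireParams)
    n_reps: int = 100
    rng_seed: int = 0
    outdir: str = "netlab_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        mcode_params = MCODEParams(**raw.pop("mcode", {}))
        rewire = RewireParams(**raw.pop("rewire", {}))
        return cls(mcode=mcode_params, rewire=rewire, **raw)


def render_cluster_table(clusters: Sequence[MCODECluster]) -> str:
    """Cluster table: rank, score (one decimal), nodes, edges, sorted members."""
    lines = ["rank\tscore\tnodes\tedges\tseed\tmembers"]
    for rank, c in enumerate(clusters, start=1):
        members = ",".join(sorted(map(str, c.members)))
        lines.append(f"{rank}\t{fmt1(c.score)}\t{c.size}\t{c.internal_edges}\t"
                     f"{c.seed}\t{members}")
    return "\n".join(lines) + "\n"


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) >= 2:
            pairs.append((fields[0], fields[1]))
    return pairs


def _read_seed_table(path: str | Path) -> dict[str, frozenset]:
    table: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if fields[0].lower() in ("symbol", "gene", "protein"):
            continue
        if len(fields) >= 2:
            table.setdefault(fields[1].upper(), set()).add(fields[0].upper())
    return {k: frozenset(v) for k, v in table.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        with open(config.edges) as fh:
            records = network_io.parse_edge_table(fh, dialect=config.fmt)
        records = network_io.filter_by_confidence(records, config.min_confidence)
        annotations = None
        if config.annotations:
            with open(config.annotations) as fh:
                annotations = network_io.read_annotations(fh)

        stage = "merge"
        net = network_io.build_network(records, annotations)
        if config.exclude:
            net = network_io.exclude_edges(net, _read_pairs(config.exclude))
        conf = network_io.confidence_summary(records)

        stage = "topology"
        dd = topology.degree_distribution(net)
        fit = topology.fit_power_law(dd)
        comps = topology.connected_components(net)
        clustering = topology.global_clustering(net)
        paths = topology.path_length_stats(net)
        hubs = topology.identify_hubs(net, config.hub_method, config.hub_param)
        hub_degrees = sorted((net.degree(h) for h in hubs.hubs), reverse=True)
        tier_degrees = sorted((net.degree(h) for h in hubs.second_tier), reverse=True)
        m = net.number_of_edges()
        shares = {
            "hubs_pct": topology.degree_share(hub_degrees, m) if hub_degrees else 0.0,
            "second_tier_pct": topology.degree_share(tier_degrees, m) if tier_degrees else 0.0,
            "combined_pct": topology.degree_share(hub_degrees + tier_degrees, m)
            if hub_degrees + tier_degrees else 0.0,
        }

        stage = "centrality"
        scores = centrality.betweenness(net)
        k = min(config.bottleneck_k, net.number_of_nodes())
        bottlenecks = centrality.top_bottlenecks(scores, k=k, hubs=hubs.hubs)

        stage = "mcode"
        clusters = mcode.find_clusters(net, config.mcode)

        stage = "null"
        rewire = RewireParams(swaps_per_edge=config.rewire.swaps_per_edge,
                              max_attempts_factor=config.rewire.max_attempts_factor,
                              seed=config.rng_seed)
        ensemble = null_models.null_clustering_ensemble(net, config.n_reps, rewire)
        ztest = null_models.one_sample_z(clustering.global_coefficient, ensemble)

        stage = "crosstalk"
        overlap_section = None
        if config.seed_table:
            seed_table = _read_seed_table(config.seed_table)
            subnets = [crosstalk.subfamily_network(records, seeds_, label)
                       for label, seeds_ in sorted(seed_table.items()) if seeds_]
            overlap = crosstalk.shared_proteins(subnets)
            coverage = crosstalk.coverage_stats(seed_table, records)
            overlap_section = {
                "n_shared": len(overlap.membership),
                "by_count": {str(kk): sorted(v) for kk, v in
                             sorted(overlap.by_count.items())},
                "by_combination": {"+".join(sorted(c)): n for c, n in
                                   sorted(overlap.by_combination.items(),
                                          key=lambda cn: sorted(cn[0]))},
                "coverage": {lab: list(v) for lab, v in
                             sorted(coverage.per_subfamily.items())},
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle = {
        "config": {
            "edges": str(config.edges), "min_confidence": config.min_confidence,
            "hub_method": config.hub_method, "hub_param": config.hub_param,
            "mcode": asdict(config.mcode),
            "rewire": {"swaps_per_edge": config.rewire.swaps_per_edge,
                       "max_attempts_factor": config.rewire.max_attempts_factor},
            "n_reps": config.n_reps, "rng_seed": config.rng_seed,
        },
        "network_summary": {
            "nodes": net.number_of_nodes(),
            "edges": net.number_of_edges(),
            "components": len(comps.components),
            "isolates": len(comps.isolates),
            "gamma": fit.gamma,
            "r_squared": fit.r_squared,
            "global_clustering": clustering.global_coefficient,
            "mean_path_length": paths.mean,
            "max_path_length": paths.max,
            "confidence_mean": conf.mean,
            "confidence_sd": conf.sd,
        },
        "hubs": {
            "hubs": sorted(hubs.hubs),
            "second_tier": sorted(hubs.second_tier),
            "degree_shares_pct": {kk: fmt1(v) for kk, v in shares.items()},
        },
        "bottlenecks": {
            "top": [[n, s] for n, s in bottlenecks.ranked[:len(bottlenecks.top_k)]],
            "hub_bottlenecks": sorted(bottlenecks.hub_bottlenecks),
        },
        "clusters": [
            {"rank": i + 1, "score": fmt1(c.score), "nodes": c.size,
             "edges": c.internal_edges, "seed": str(c.seed),
             "members": sorted(map(str, c.members))}
            for i, c in enumerate(clusters)
        ],
        "null_model": {
            "n_reps": ensemble.n_reps,
            "mean": ensemble.mean,
            "sd": ensemble.sd,
            "z_sd": ztest.z_sd,
            "z_se": ztest.z_se,
            "p_two_sided": ztest.p_two_sided,
        },
        "path_histogram": {str(kk): v for kk, v in paths.histogram.items()},
        "crosstalk": overlap_section,
    }

    (outdir / "bundle.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    (outdir / "clusters.tsv").write_text(render_cluster_table(clusters))
    (outdir / "edges.tsv").write_text(
        "\n".join("\t".join(e) for e in network_io.canonical_edges(net)) + "\n")
    return bundle
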