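# netlab

Topology, module detection, and null-model analysis for curated
protein–protein interaction (PPI) networks, built around the small-GTPase
interactome (Ras, Rho, Rab, Arf, Ran, and RGK subfamilies and their
partners).

Small GTPases act as molecular switches in signalling, cytoskeleton
dynamics, and vesicle traffic, and their pathways cross-talk through shared
effectors, GEFs, GAPs, and GDIs.  `netlab` turns curated STRING-style edge
tables into a single undirected simple graph and asks the standard
systems-level questions: is the degree distribution scale-free, which
proteins are hubs and bottlenecks, which dense modules (putative complexes)
exist, is the observed clustering more than a degree-sequence artifact, and
which proteins bridge multiple subfamily networks?

## What it computes

- **Ingestion** (`netlab.network_io`): TSV/SIF edge tables with confidence
  scores in [0, 1], inclusive confidence filtering (default ≥ 0.4), graph
  union, deduplication, self-loop removal, blacklist exclusion, confidence
  and curation summaries.
- **Topology** (`netlab.topology`): degree distribution N(k) and the
  power-law fit P(k) ∝ k^(−γ) via ordinary least squares of log₁₀ N(k) on
  log₁₀ k; local/global clustering coefficients (mean over all nodes, degree
  < 2 counted as 0); shortest-path statistics over reachable unordered
  pairs; connected components; hub identification by quantile or by the
  largest gap in the descending degree sequence.
- **Bottlenecks** (`netlab.centrality`): unnormalized fractional-credit
  betweenness σ_st(v)/σ_st, top-k ranking with tie expansion,
  hub–bottleneck intersection, pairwise path lengths among bottlenecks.
- **Module detection** (`netlab.mcode`): MCODE-style seeded growth — vertex
  weights from the highest k-core of each closed neighborhood, growth
  threshold `(1 − node_score_cutoff) × seed weight`, haircut pruning, k-core
  filter; cluster score = DC × |V| with loop-inclusive density DC = E/V².
- **Null models** (`netlab.null_models`): degree-preserving edge swaps
  ((u,v),(s,t) → (u,t),(s,v)), replicate ensembles of the clustering
  coefficient, and the one-sample Z test.
- **Cross-talk** (`netlab.crosstalk`): per-subfamily seed-incident
  subnetworks, proteins shared among ≥ 2 subfamily networks grouped by exact
  combination, first-neighbor lists, coverage statistics.
- **Enrichment** (`netlab.enrichment`): one-sided hypergeometric
  (Fisher's exact) and EASE-penalized over-representation against
  user-supplied annotation tables (TSV or GMT), raw-p filtering at α = 0.05,
  optional Benjamini–Hochberg.
- **Synthetic data** (`netlab.synthetic_data`): seeded generators for
  partial-duplication growth, preferential attachment, Erdős–Rényi
  baselines, and a full STRING-export emulator with planted cross-subfamily
  overlap structure and truncated-normal confidence scores.

## Worked example

Generate a published-scale synthetic interactome and analyze it end to end:

```python
from netlab import synthetic_data as sd, network_io as nio, topology, mcode, null_models as nm

spec = sd.FixtureSpec(rng_seed=7)                      # 778 proteins, 1943 edges
records, annotations = sd.generate_string_fixture(spec)
records = nio.filter_by_confidence(records, 0.4)
net = nio.build_network(records, annotations)
print(f"nodes={net.number_of_nodes()} edges={net.number_of_edges()}")

fit = topology.fit_power_law(topology.degree_distribution(net))
print(f"gamma={fit.gamma:.2f} r2={fit.r_squared:.2f}")

cc = topology.global_clustering(net).global_coefficient
ens = nm.null_clustering_ensemble(net, n_reps=100, params=nm.RewireParams(seed=7))
z = nm.one_sample_z(cc, ens)
print(f"clustering={cc:.3f} null={ens.mean:.3f}+/-{ens.sd:.3f} z={z.z_se:.1f}")

for i, c in enumerate(mcode.find_clusters(net), 1):
    print(f"cluster {i}: score={mcode.render_score(c.size, c.internal_edges)} "
          f"nodes={c.size} edges={c.internal_edges}")
```

Output:

```
nodes=778 edges=1943
gamma=1.41 r2=0.82
clustering=0.199 null=0.064+/-0.006 z=244.4
cluster 1: score=1.7 nodes=12 edges=20
cluster 2: score=1.7 nodes=6 edges=10
cluster 3: score=1.4 nodes=7 edges=10
```

The fitted exponent γ ≈ 1.4 sits in the 1–2 range typical of biological
networks (a signature of duplication-driven rather than purely preferential
growth); the observed clustering (0.199) exceeds the degree-preserving null
(0.064 ± 0.006) by hundreds of standard errors, so the modular structure is
not a degree-sequence artifact; the listed modules are the dense cores that
survive the haircut and 3-core filter, scored by edges-per-member.

The same pipeline runs from the shell:

```sh
netlab simulate fixture --seed 7 --out-prefix demo
netlab topology --network demo.edges.tsv --out-prefix demo
netlab mcode --network demo.edges.tsv --out demo.clusters.tsv
netlab null --network demo.edges.tsv --reps 100 --seed 7 --out demo.null.json
```

To analyze the real deposited GTPase network, place its edge list (TSV:
`protein_a  protein_b  [score  [evidence]]`) at
`data/published/gtpase_network_graph_s1.tsv`; the published-network test in
`tests/test_acceptance.py` then checks the full metric suite (778/1943,
γ ≈ 1.38, clustering 0.33 vs null 0.066, mean path 4.0, ten modules).

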