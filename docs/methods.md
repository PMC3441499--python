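# Methods

This note records the conventions, parameter defaults, and design choices
behind `netlab`, and what the synthetic generators do and do not emulate.

## Network construction

Interaction records are undirected: `(A, B)` and `(B, A)` are the same edge,
stored under the lexicographically ordered pair. Self-loops (often artifacts
of reciprocal detection) are dropped; duplicate edges collapse to one,
keeping the strongest supporting confidence score. Gene symbols are
uppercased and whitespace-stripped; no alias resolution is attempted — that
is an external-database concern. The confidence filter is inclusive
(score ≥ threshold, default 0.4, the STRING "medium confidence" floor chosen
to retain rather than exclude borderline interactions). Annotated GTPases
with no surviving edges are kept as zero-degree nodes: curated seed lists
legitimately contain proteins with no validated partners, and dropping them
would distort the degree distribution's k = 0 class and the isolate report.

## Degree distribution and the power-law fit

The degree exponent γ of P(k) ∝ k^(−γ) is estimated by ordinary least
squares of log₁₀ N(k) on log₁₀ k over degrees k ≥ 1 with N(k) > 0, with no
binning; γ is the negated slope and R² comes from the same regression. This
is the convention of NetworkAnalyzer-style tools and of the regression form
printed alongside published degree-distribution plots; it is *not* a
maximum-likelihood estimator. Two consequences matter for interpretation:

- The fit is dominated by the low-degree head and the noisy singleton tail
  (many degrees with N(k) = 1), which biases γ downward relative to the
  underlying law. On preferential-attachment graphs whose true exponent
  is 3, this fit reports ≈ 1.9 at n = 2000 — an inherent property of the
  convention, reproduced identically with networkx's generator.
- Degrees with N(k) = 0 are skipped (log undefined); k = 0 nodes appear in
  the distribution but never in the fit.

## Clustering, paths, components

The local clustering coefficient of a node with degree d ≥ 2 is
t / (d(d−1)/2), where t counts edges among its neighbors; nodes with fewer
than two neighbors are assigned 0. The global coefficient is the arithmetic
mean over **all** nodes (not the transitivity ratio). Shortest-path
statistics are computed by BFS from every node over reachable unordered
pairs only; disconnected pairs are excluded rather than set to infinity, so
the mean stays finite on fragmented graphs. Components are reported largest
first with zero-degree isolates listed separately.

## Hubs

Two rules are offered. `top_fraction` takes nodes whose degree strictly
exceeds the (1 − f) empirical quantile of the degree sequence (strict,
so that a star graph yields only its center). The default `degree_gap`
scans the descending degree sequence within the top decile for the largest
drop between consecutive ranks and cuts there, breaking ties toward the
deeper cut (more hubs); a second tier spans from the hub cut to the
next-largest drop below it. The gap rule resolves tiered hub structure —
e.g. a sequence headed 134, 110, 96, 77 | 53, 45, 38, 35 | ≤ 15 splits into
a 4-hub top tier and a 4-node second tier — which a verbal "top ~20%"
criterion cannot.

Degree shares are reported as summed group degrees divided by the total
edge count, rendered half-up to one decimal, matching the percentage style
of published hub summaries.

## Bottlenecks

Betweenness uses the standard fractional-credit definition: each unordered
pair (s, t) distributes one unit across its shortest paths, and v accrues
σ_st(v)/σ_st. Scores are left unnormalized — the constant cancels in
ranking. A strict-count mode (v gets 1 whenever any shortest s–t path
passes it) is exposed for sensitivity analysis because "non-redundant
shortest paths" is ambiguous between the two readings; rankings rarely
differ. Top-k selection expands boundary ties and flags them.

## Module detection

The detector follows the MCODE scheme: each node with degree ≥
`degree_cutoff` (default 2) is weighted by k × density of the highest
k-core of its closed neighborhood; clusters grow greedily from the heaviest
unvisited seed, admitting neighbors whose weight is at least
`(1 − node_score_cutoff)` (default 0.8) of the seed weight; the haircut
iteratively strips members with fewer than two within-cluster edges (a
2-core fixed point); clusters whose induced subgraph lacks a
`k_core`-core (default 3) are dropped. Grown members are marked visited, so
clusters are node-disjoint. If the haircut disconnects a cluster, the
component containing the seed is kept. Fluff is implemented but off by
default.

**Density convention.** Throughout, the density of a subgraph with V
vertices and E edges is the loop-inclusive ratio DC = E/V², and the cluster
score is DC × V = E/V. This convention is forced by the published cluster
tables, where every printed (score, nodes, edges) triple satisfies
score = E/V; the loop-free alternative E/(V(V−1)/2) contradicts them.
Scores render half-up to one decimal; full precision is kept in JSON.

A single global weighting pass is used (no per-cluster re-weighting).
One behavioral consequence of the growth rule worth knowing: two equal-weight
dense regions joined by a *direct* edge merge into one cluster (all vertices
clear the 80% threshold); they separate only when the connector is a
lower-weight intermediate node. The test suite pins both behaviors.

## Null model and significance

The degree-preserving shuffle repeatedly draws two edges (u, v), (s, t)
with all four endpoints pairwise distinct — the strict reading (allowing
u = t) could create self-loops — and with (u, t), (s, v) absent, then swaps.
The target is `ceil(swaps_per_edge × |E|)` successful swaps
(`swaps_per_edge` = 10, a standard mixing heuristic; the source analyses do
not state a count), giving up with a logged warning after 100× that many
failed proposals, so degenerate graphs (e.g. a triangle, which admits no
valid swap) return unchanged. Every replicate uses seed + replicate index;
identical seeds give bit-identical edge lists.

The ensemble summarizes replicates with the sample (n−1) SD — at n = 100
the distinction from the population SD is below printed rounding. The
one-sample Z test reports both conventions, z_sd = (obs − mean)/sd and
z_se = z_sd·√n, with the two-sided p from the normal tail of z_se. The sign
follows observed − null; published reports sometimes print the opposite
sign (null − observed). Note that a z printed from rounded summary values
(0.33, 0.066, 0.006, n = 100) gives z_se = 440; exact agreement with a z
computed from unrounded internals is not expected.

## Cross-talk

Protein P belongs to subfamily X's network iff P is a seed of X or a first
neighbor of some seed of X — the only rule consistent with building
subfamily networks from per-GTPase queries; the sources never state one.
Shared-protein reports cover proteins in ≥ 2 subfamily networks, grouped by
exact label combination. GTPase seeds can themselves be shared members of
other subfamilies' networks; `include_seeds=False` excludes them, and both
modes are exposed because published overlap counts do not say which was
used.

## Enrichment

p_fisher is the one-sided upper hypergeometric tail
P(X ≥ k | N, K, n); p_ease recomputes it at k − 1 (EASE's one-removed
penalty), so p_ease ≥ p_fisher always. scipy's `hypergeom.sf` supplies the
tail (log-space internals, stable at genome-scale N). No multiple-testing
correction is applied by default — the published filter is raw P ≤ 0.05 —
but Benjamini–Hochberg is available. The background defaults to the union
of annotated genes and can be set to the full network node set; both
choices are supported because the published runs do not state theirs.

## Synthetic generators

- **Partial duplication**: from a complete seed graph (default K₄), each
  step copies a uniformly chosen node, retaining each of its edges
  independently with `p_retain`; edge-free copies are redrawn by default
  (a flag keeps them, emulating disconnected seeds). The default
  `p_retain = 0.45` was set by a sweep (`scripts/calibrate_duplication.py`):
  at n = 800 it yields a median fitted exponent ≈ 1.43 over 20 seeds, inside
  the 1–2 biological range; retention above ~0.8 leaves the scale-free
  regime. The literature offers several duplication-model variants; this is
  the pure partial-duplication one, without divergence edge additions.
- **Preferential attachment**: exact degree-proportional choice of m
  distinct targets per new node, initialized from K_{m+1}.
- **Erdős–Rényi**: networkx's G(n, p) under an integer seed.
- **Curated-export emulator** (`generate_string_fixture`): defaults are the
  published study's scale — 141 GTPase seeds (22 Rho, 29 Ras, 59 Rab,
  26 Arf, 1 Ran, 4 RGK; the sources also mention 139, so the seed list is
  configurable), 778 proteins, 1943 edges, confidence scores from a normal
  (0.66, 0.146) truncated to [0.4, 1.0] by rejection-free `truncnorm`
  sampling, and planted cross-subfamily overlap counts matching the
  published combination table (84 shared proteins: one 4-way, seven 3-way,
  76 pairwise). Partners outside the planted set attach to seeds of exactly
  one subfamily with Zipf-skewed seed preference and heavy-tailed degrees,
  so the cross-talk module recovers the planted counts *exactly*. A
  wedge-closure step converts ~15% of the edge budget into partner–partner
  edges under shared seeds, giving the fixture triangle enrichment (global
  clustering ≈ 0.2) so the null-model comparison is non-degenerate; closure
  edges are seed-free and cannot alter any protein's subfamily membership.

**What the fixture does not emulate:** real complex structure (modules
arise only incidentally from wedge closures, so module counts and
memberships are not comparable to curated networks), literature/citation
structure, evidence channels, GTPase–GTPase cross-subfamily edges, and the
exact published clustering coefficient (0.33) or path-length distribution.
Passing tests on the fixture therefore validate the machinery and the
planted quantities (scale, confidence distribution, overlap counts, degree
heavy-tail), not biological conclusions.

## Numerical and determinism choices

- Half-up decimal rounding (via `decimal`) for all rendered one-decimal
  table values; Python's bankers' rounding is never used for reports.
- All randomness flows through `numpy.random.default_rng` seeded from the
  parameter records; generator output is a pure function of its parameters.
- Ordering ties break lexicographically everywhere (seed selection,
  rankings, component listing), so pipeline output is bit-reproducible
  under a fixed seed; the report bundle is JSON with sorted keys.
- The pipeline determinism check and the bundled example use 20 null
  replicates; 100 remains the default for published-scale analyses.
- Degenerate inputs: empty record lists, edgeless graphs, and zero-SD
  ensembles raise or flag (±∞ z) explicitly rather than returning NaN.

## Known limitations

- The OLS log-log exponent is a descriptive fit, not an estimator with
  guarantees; comparisons across networks are only meaningful under the
  identical convention.
- MCODE results depend on tie-breaking when many vertices share weights;
  rankings are deterministic here but may differ from other
  implementations' on tied inputs.
- The strict-count betweenness mode enumerates all shortest paths and is
  exponential in the worst case; use it on small or sparse graphs.
- Mean path length excludes disconnected pairs; on very fragmented graphs
  this measures within-component navigability only.
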