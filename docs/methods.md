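# Methods

This note records the statistical models, algorithmic conventions, default
parameters and design choices behind `netbiomark`, and what the synthetic
benchmarks do and do not demonstrate.

## Network construction

Interaction tables carry per-channel confidence scores. Channel scores are
combined by the noisy-OR rule `1 − Π(1 − sᵢ)` restricted to the selected
channels (default `experimental`, `database`); the rule is symmetric, reduces
to the raw score when only one channel carries evidence, and never falls below
the maximum input, mirroring how evidence channels are integrated in curated
interactome resources. The default retention threshold is 0.400 ("medium
confidence"), applied to the channel-restricted combined score — not to a
precomputed all-channel combined score, which would let unrelated evidence
(text mining, co-expression) rescue an interaction the user excluded.

The seed-induced network keeps isolated seed genes as nodes: pathway
membership, not connectivity, defines the node set. Origin labels record seed
membership per pathway (e.g. `ST`, `Ca`, `ST+Ca`) and `CON` for connectors.

### Greedy connector augmentation

Loop until connected or stuck:

1. main component := largest connected component (ties: the component
   containing the lexicographically smallest node);
2. candidates := non-seed proteins of the filtered global universe adjacent to
   ≥ 1 main-component node and ≥ 1 node outside it;
3. select the candidate joining the most disconnected nodes; ties broken by
   degree in the *filtered global universe* (the partial network's degrees
   change during the loop, so the global degree is the only stable reading of
   "highest degree"), then lexicographically for reproducibility;
4. add the winner with all its edges to current graph nodes, label it `CON`.

Joining capacity is the primary criterion and degree the tie-break because
candidates are compared by their ability to join a *set* of disconnected
nodes. Only single-node additions are considered (no two-node bridges); seed
nodes that no single connector can reach are reported as `unresolved` with a
warning rather than an error. The algorithm never removes nodes or edges, and
re-running it on a connected result is a no-op.

## Centrality and the mean + 1 SD rule

Degree is the neighbour count. Betweenness is the undirected, unweighted
Brandes value with endpoints excluded, each unordered pair counted once, and
normalization `(N−1)(N−2)/2`, so a star center scores exactly 1.0; on
disconnected graphs the sum runs over reachable pairs with the normalization
unchanged. Graphs with fewer than 3 nodes score 0 by convention. The
implementation (networkx) is cross-checked in the test suite against an
in-repo brute-force oracle that enumerates every shortest path explicitly.

Thresholds are `mean + 1 SD` with the *sample* (n−1) standard deviation —
matching common spreadsheet/statistics defaults — computed over **all** nodes
of the final network, connectors included (the reference table's mean degree
equals 2E/N for the full network, confirming this convention). Classification
uses strict inequality ("above the threshold"): HB needs both metrics above
threshold, NH-B betweenness only, H-NB degree only, else NC. H-NB nodes are
reported but never counted as central; the candidate pool is {HB, NH-B}.

## Moderated t differential expression

Model: per gene, `s²_g | σ²_g ~ σ²_g · χ²(d_g)/d_g` with
`σ²_g ~ s₀²·d₀/χ²(d₀)` (scaled inverse-chi-square prior). Hyperparameters are
estimated by moments on `z = log s²`: with
`e_g = z_g − ψ(d_g/2) + log(d_g/2)`, the model gives
`Var(e) = ψ′(d/2) + ψ′(d₀/2)` and
`E(e) = log s₀² − ψ(d₀/2) + log(d₀/2)`, so the excess of the empirical
variance of `e` over the mean sampling term identifies `d₀` through the
trigamma inverse (Newton iteration), and the mean of `e` then identifies
`s₀²`. Zero-variance genes are excluded from estimation with a logged count;
fewer than 30 usable genes is an error that advises the ordinary-t fallback.

Degenerate cases: when the empirical variance of `e` does not exceed the
sampling term, `d₀ = ∞` (complete shrinkage) and `s₀²` is estimated by the
raw-scale moment `mean(s²)` — exactly the common value when all `s²` are
equal. `d₀ = 0` disables moderation and reproduces the ordinary pooled
two-sample t identically (verified exhaustively in the tests); `d₀ = ∞` uses
`s̃² = s₀²` with a standard-normal reference. Genes with `s̃² = 0` are flagged
and reported NS rather than dropped. The non-degenerate path is cross-checked
against Bioconductor limma on a shared fixture (agreement to ≤ 1e-6 relative
on t and p and ≤ 1e-4 on the hyperparameters); limma serves only as an
independent oracle.

P-values are two-sided (both directions of deregulation are of interest) and
BH-adjusted via statsmodels; significance is strict (`p_adj < α`, default
0.05), and `logFC` is oriented case − control (metastasis minus primary in
the reference study). Expression is assumed already log2/normalized; a matrix
maximum above 50 triggers a warning, never an automatic transform, since
normalization is platform-specific and out of scope. Probe-to-gene collapse
is provided only as a max-|t| plumbing utility; the reference table does not
state the collapse used upstream, and the package takes no position.

## Concordance semantics

`n_significant` counts datasets with `p_adj < α`. Replication at level 1
requires significance only; at k ≥ 2 it additionally requires all significant
calls to share one direction. This is the only reading that reproduces the
reference table's printed per-class tallies (NH-B: 11 at-least-1, 5
exactly-2, 1 exactly-3; HB: 8 at-least-1, 3 at-least-2), and both at-least-k
and exactly-k tallies are always emitted so either convention is inspectable.
Genes absent from a dataset count as NS there (platform coverage differs
across series), never as errors. Nominations require a central class and
replication at ≥ `min_datasets` (default 2) and are sorted by replication
count, then gene name, making the output invariant to dataset ordering.

## Landscapes

Pixels take the Gaussian-kernel weighted *mean* (not sum) of node values,
`Σ vᵢwᵢ / Σ wᵢ` with `wᵢ = exp(−‖x − pᵢ‖²/2σ²)`: the grid stays in the units
of the node values, a constant field renders exactly constant, and a maximum
principle bounds every pixel by the node-value range. σ is interpreted in
normalized unit-square layout coordinates, default 0.04; pixels with total
weight below 1e-6 are masked as background to avoid 0/0 far from all nodes.
Layouts are seeded force-directed embeddings rescaled to the unit square;
coordinates are deterministic per (graph, seed) but otherwise arbitrary, and
no attempt is made to match any particular layout engine's coordinates.

## Synthetic data

`simulate_interactome` draws a preferential-attachment background (heavy-tailed
degrees — the mean + 1 SD rule is vacuous on degree-regular graphs), marks two
overlapping seed sets whose induced subgraph is connected by construction, and
appends small seed cliques wired to the rest of the world only through one
designated non-seed connector each, making the planted connector provably the
unique bridge. Planted edges draw experimental scores in [0.45, 0.95] (always
pass 0.400); decoy edges draw [0.05, 0.39] (always fail), so filter mistakes
surface as recovery failures. Defaults (300-node background, seed sets of
140/180 with overlap 25, 5 planted clusters) echo the scale of the reference
study's pathway merge.

`simulate_expression` draws `σ²_g` from the prior once per gene (shared
across datasets, keeping recovery identifiable with few datasets), baselines
`μ_g ~ N(8, 1)` per dataset, and adds effects `β_g` of known sign —
identical across datasets for concordant genes, alternating for designated
discordant ones. Defaults d₀ = 4, s₀² = 0.05 (per-gene sd ≈ 0.22), effect
|β| = 1.5, groups of 10 + 10, three datasets.

What passing these benchmarks shows: the algorithms recover exactly the
structure the model plants, under the model's own assumptions (independent
genes, Gaussian noise, variance prior correctly specified, unique bridges).
What they do not show: robustness to correlated genes, batch effects, probe
effects, non-Gaussian noise, mis-specified priors, or interactome false
positives/negatives — none of which the generator emulates.

## Problem sizes and numerical choices

- Null FDR calibration: 200 simulated studies of 400 genes × (10 + 10)
  samples (the generator's default group sizes). Sizes matter here: with very
  few genes or tiny residual df the plug-in prior estimate is noisy and the
  moderated t measurably liberal, so the calibration uses panel and group
  sizes representative of real series.
- Prior recovery: 2000 genes at d₀ = 4, s₀² = 0.05, df = 2.
- Connector recovery: 60-node backgrounds, 1–3 planted clusters, 50–100
  random instances.
- Betweenness oracle: random graphs up to 12 nodes (path enumeration is
  exponential beyond that), ≥ 100 graphs, agreement to 1e-12.
- End-to-end recovery: one simulated study, 500-node background, ~470-gene
  network padded to ≥ 500 genes, 50 planted DE genes of which 20 on central
  nodes, three datasets.
- Trigamma inverse: Newton iteration to 1e-10 relative, with the 1/x
  asymptote for tiny arguments.
- All randomness flows through explicit integer seeds (numpy `default_rng` /
  `random.Random`); derived seeds stay below 2³¹.

## Known limitations

- The greedy connector search is order-deterministic but, like any greedy
  set-cover-style heuristic, not guaranteed minimal: a different connector
  set of equal or smaller size may exist.
- The mean + 1 SD thresholds are distribution-dependent; on small or dense
  graphs the central class can be empty or tiny.
- Identifier namespaces are taken as-is (case-sensitive); cross-namespace
  mapping is delegated to an optional two-column mapping file.
- Meta-analytic effect pooling (Fisher/Stouffer), paired or multi-factor
  designs, and platform normalization are intentionally out of scope.
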