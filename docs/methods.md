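# Methods

## The pipeline and its assumptions

The package models a severity-paired CSF proteomics workflow: differential
spot screening on two-dye difference gels, expansion of the identified
proteins into an interaction network, division of that network into modules,
and per-module gene-set over-representation testing. Each stage is usable on
its own; together they map differential protein abundance onto candidate
perturbed pathways.

### DIGE screen

Each gel carries one complete-injury (AIS A) and one incomplete-injury
(AIS C/D) CSF sample, so a spot's Cy5/Cy3 volume ratio estimates the
complete/incomplete abundance ratio once the gel's dye orientation is
applied (`orient_ratio`; reverse-labelled gels contribute the reciprocal).
Oriented ratios are averaged in log space — the geometric mean treats up-
and down-regulation symmetrically — and converted to the signed-fold
convention of difference-gel software, f(r) = r for r ≥ 1 and −1/r
otherwise, so |f| < 1 cannot occur and a halving prints as −2.0.

The differential call is the conjunction of three criteria, all
configurable in `ScreenConfig`:

| parameter | default | meaning |
|---|---|---|
| `fold_threshold` | 1.5 | minimum average fold magnitude |
| `trend_min` | 3 | gels agreeing on direction (reference design: 7 gels) |
| `p_max` | 0.1 | strict bound on the two-sided one-sample t-test p |
| `min_presence` | 2 | gels a spot must appear on; sparser spots are skipped, not imputed |

The t-test is applied to log2 oriented ratios against zero, which is
well-specified under the multiplicative (lognormal) noise model the
generator uses. With zero sample variance the statistic degenerates; p is
reported as 0 (nonzero common log-ratio) or 1 (all exactly zero) with a
warning, so noise-free fixtures remain screenable.

Spot bookkeeping is many-to-many: isoform spots of one protein collapse to a
single symbol and comigrating proteins in one spot each count, via
`map_spots_to_proteins`. `temporal_compare` classifies each protein across
two sampling periods: `within_threshold` when the late fold magnitude is
below the threshold, `reversed` when both folds exceed it with opposite
signs, `persistent` otherwise. The bundled late-period fold column contains
printed magnitudes below 1, which the signed-fold convention cannot produce;
those cell values are carried as data but only their sign and
threshold-relation are interpreted.

### Seed-expanded network

Seed symbols are first passed through a user-supplied alias map (the bundled
default maps the classical complement symbol CO4 to C4A and C4B), then seeds
with no listed partner in the interactome are dropped with a reason — kept
isolates would distort modularity without adding information. The network is
the induced subgraph on seeds plus first neighbours: one hop only, and edges
among non-seed neighbours are retained. The network is unweighted; the
interactome reader uppercases symbols (mixed-case aliases would otherwise
duplicate nodes) and drops self-interactions, since betweenness and
modularity are defined here on simple graphs. Density is reported as
m / C(n, 2).

### Modularization

`girvan_newman` removes one highest-betweenness edge at a time, recomputing
betweenness after every removal (correctness over speed; the batched variant
can merge distinct splits), evaluates Q for every intermediate component
structure including the initial one, and returns the maximum. Determinism is
enforced twice: equal-betweenness ties break lexicographically on the
canonical (min, max) edge name, and equal-Q ties resolve toward fewer
removals. Isolated nodes become singleton modules (excluded downstream by
the minimum-module-size rule). `greedy_modularity` wraps the agglomerative
CNM heuristic as the scalable alternative; `brute_force_best_partition`
enumerates all set partitions (capped at 10 nodes — Bell numbers explode)
with a lexicographic canonical-labelling tie-break, and serves as the exact
oracle in the test suite: on a named suite of 16 connected graphs of ≤ 8
nodes the divisive best-Q equals the exhaustive optimum to 1e-12.

Edgeless graphs have undefined Q; the modularizers return all-singleton
partitions with Q reported as not applicable rather than raising.

### Enrichment

For each module of at least `min_module_size` (default 2) genes, each term
with k ≥ `min_k` (default 1) module hits is tested with the upper-tail
hypergeometric probability P(X ≥ k | N, K, n), computed by scipy in the log
domain (stable beyond N = 1e5). The universe N defaults to the annotation
file's `#universe=` directive and falls back to the union of annotated
genes — a GMT cannot know the organism's gene count otherwise — and can be
overridden. Query size n counts only module genes present in the annotation
universe; unannotated genes are excluded with a logged count. FDR correction
is Benjamini–Hochberg, applied within each module's term list by default
(matching per-query-set usage of web enrichment tools) with a global scope
available; significance is strict, Hyp* < α with α = 0.001. Only
over-representation is tested. Note that BH reapplication is not a no-op in
general (q-values are running minima of inflated p-values); the suite checks
idempotence only on tie-collapsed corrected lists, where it holds.

## Synthetic data: what it emulates, what it does not

* `gen_planted_partition` is the two-parameter stochastic block model —
  within-module edge probability `p_in`, between-module `p_out` — the
  simplest generator with tunable community recoverability. The standard
  fixture is four modules of 25 nodes at p_in = 0.3, p_out = 0.01, where the
  divisive algorithm recovers the planted labels at ARI 1.0.
* `gen_annotations` assigns terms by independent Bernoulli draws per gene
  (`enrich_frac` = 0.8 inside a planted module, `background_rate` = 0.02
  elsewhere, universe 20000), matching the hypergeometric null up to
  conditioning on set sizes.
* `gen_dige_tables` multiplies each planted true ratio by lognormal noise
  (Gaussian on log2 with `noise_sd`, default 0.15 — a fixture choice at
  which moderate 1.5–2-fold changes remain recoverable from 7 gels, not an
  empirical estimate) and emits reverse-labelled gels as reciprocals.
* `gen_interactome` builds a background network where every partner touches
  at least one seed, so one-hop expansion yields exactly
  `n_seeds + n_partners` nodes; with 45 seeds, 821 partners and 6300 extra
  edges it reproduces the 866-node / 7121-link shape of the reference
  network. This matches construction, not biology: real interactomes are
  scale-free-ish and the module structure of the reference network depends
  on a specific interactome snapshot that is not redistributable, so module
  counts on real data are treated as descriptive, not as a benchmark.

Consequently, passing tests demonstrate correctness of the statistics and
algorithms under their own model assumptions — they do not certify
performance on real gels (spatial artefacts, missing-not-at-random spots,
dye-specific bias beyond orientation) or real interactomes (degree
heterogeneity, annotation bias).

All generators draw from `numpy.random.default_rng(seed)` with one explicit
integer seed per call and no global state; identical parameters and seed
give bit-identical outputs.

## Numerical choices

* Cohort summaries round decimal half-up at printed precision (1 dp for
  ages, 2 dp for days post injury) and use the sample (n−1) standard
  deviation, which reproduces both bundled groups' printed values; the
  population SD does not.
* Thresholds are applied exactly as stated: fold ≥ 1.5 inclusive, p < 0.1
  and Hyp* < 0.001 strict.
* Q comparisons in tests use absolute tolerance 1e-12; the brute-force
  optimizer treats |ΔQ| ≤ 1e-15 as a tie.
* Degenerate inputs: empty cohort tables, edgeless graphs, empty seed sets
  after resolution, inconsistent hypergeometric counts and non-positive
  ratios all raise `InvalidParameterError`/`FormatError` rather than
  propagating NaNs.

## Known limitations

* The divisive algorithm recomputes betweenness per removal: O(m²n) overall,
  practical to a few hundred nodes; use `greedy_modularity` beyond that.
* The exact statistic produced by the original difference-gel analysis
  software is proprietary and unspecified; the one-sample log-ratio t-test
  is the closest well-defined reading of the stated design.
* Per-module FDR scope versus a single global family is a genuine modelling
  choice; both are exposed, and at the default α they rarely disagree on
  strongly planted signals.
* Enrichment treats terms as flat sets: no ontology-graph propagation and no
  term-redundancy pruning.
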