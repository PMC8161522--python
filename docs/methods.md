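# Methods

## The statistical model

The package analyses two-group (control vs trisomic) log2 expression
matrices. All differential expression is ratio-based: values are kept on the
log2 scale and noise is modelled as additive Gaussian there (multiplicative
log-normal on the linear scale), which matches both microarray intensity
behaviour and the fold-change statistics used downstream.

### FCROS

For n_c controls and n_t trisomic samples, all k = n_c·n_t test/control
pairs are used (the all-pairs choice makes the statistic deterministic; no
pairing of animals is assumed). Within each pair, per-gene log2 fold changes
are ranked ascending with average ranks for ties, and divided by the gene
count m so ranks lie in (0, 1]. The per-gene mean normalised rank r̄ is
standardised to z and mapped through the standard normal CDF to the f-value:

- `empirical` (default): z = (r̄ − mean(r̄)) / sd(r̄), using the moments of
  the observed r̄ distribution. This is robust to an asymmetric burden of
  true effects and is what keeps the null calibration exact in practice.
- `theoretical`: z = (r̄ − ½) / √(1/(12k)), the Normal approximation for an
  average of k uniform ranks. Available for comparison; note the k pairs are
  not independent, so this option is approximate by construction.

Genes with f < α_low (default 0.025) or f > α_high (default 0.975) are
DEGs; the window mass (5%) is the expected flagged fraction under the
complete null. The reported per-gene fold change is the **median** of the k
pairwise log2 fold changes (robust; the estimator is otherwise a free
choice). An optional Benjamini–Hochberg adjustment on two-sided f-derived
p-values exists but is off by default: the window on raw f-values is the
primary calling rule.

Degenerate inputs (every gene tied in every pair, or an r̄ spread below
1e-9) yield a warning, f = 0.5 everywhere and zero DEGs rather than a
division by a vanishing standard deviation.

### Bookkeeping definitions

- EG (expressed gene): mean log2 intensity above a detection threshold. No
  platform detection call is available for simulated data, so the default
  threshold is the matrix-wide 10th percentile of per-gene means —
  configurable, and recorded in the pipeline manifest.
- TEG (trisomic expressed gene): an EG whose *start coordinate* lies inside
  a model's duplicated intervals (closed interval, 1-based). The same
  interval-membership rule is used everywhere genes are assigned to regions.
  "Differential TEG" additionally requires a DEG call; the compensation
  percentage is 100 − round(100·differential/TEG), rounding halves away
  from zero to match how such tables are conventionally printed.
- Cross-model correlation: Pearson r of per-gene median log2FC vectors
  (Spearman available), reported as r and conventionally quoted as 100·r.
  The default gene universe is the union of all models' DEGs; a cis-region
  universe is available for comparing three-copy genes only.

### Gene-set stage

Per pair, an unequal-variance two-sample t compares set members' log2 fold
changes against all other measured genes (Welch df taken as the member
count − 1, its limit when the background is much larger than the set).
One-sided p-values (up, down) are combined across pairs by Stouffer's
method. Because the k pairs share samples, the per-pair statistics are
positively correlated under the null — two pairs sharing exactly one sample
have correlation ½ under i.i.d. noise — so the Stouffer sum is divided by
the square root of the *full* covariance total,
Σ_ab ρ_ab with ρ = 1, ½ or 0, parsed from the pair design in the column
names. Without this correction the combined p-values would be severely
anti-conservative (for a 5v5 design the naive variance is understated
5-fold). Two-sided combined p's (2·min(p_up, p_down)) are BH-adjusted
across sets within a model; sets with q < 0.1 are significant in the
direction of the smaller one-sided p.

Meta-pathways: significant sets are aggregated into ten broad functional
groups (synaptic; myelin & SNARE; interferon; ribosome; mitochondria;
transcription & epigenomics; phospho-kinase; cell structure & organelle;
enzyme activity; metabolism) by ordered, case-insensitive keyword rules.
The shipped map is an editable best-effort reconstruction of the groups
such hippocampal screens report; first match wins, and unmapped significant
sets are surfaced rather than dropped. Intermodel connectivity counts, per
meta-pathway and model pair, the genes that are "core members" (measured
members whose mean log2FC has the set's direction and magnitude at or above
the set median) of significant sets in both models.

### Network stage

Edges come from a (node, node, confidence) table; scores on a 0–1000 scale
are auto-detected and rescaled, the confidence threshold (default 0.4,
"medium confidence") is inclusive, and duplicate edges keep their maximum
confidence. The minimum connected seed network is built greedily: start
from the subgraph induced on the seeds and, while more than one component
remains, insert the globally shortest path in the full filtered graph
joining two components, breaking ties by (path length, summed 1−confidence,
lexicographic node sequence); interior path nodes become connectors. Exact
Steiner trees are NP-hard and unnecessary at these sizes; the greedy
heuristic plus a pruning pass — repeatedly deleting any connector whose
removal leaves all seeds in one component — guarantees the delivered
property that every remaining connector is essential. Paths are unweighted
by default (confidences only break ties); 1−confidence weighting is a
config option. Seeds absent from the edge universe or unreachable are
reported, never silently dropped.

Hubs are ranked by exact normalised betweenness centrality (deterministic
tie-break by node id). A hub's 2-step control percentages divide its
≤2-step closure (hub excluded) by the other network nodes and the other
seeds respectively; the closure's subnetwork is the induced subgraph (edges
among level-2 nodes included).

The degree-preserving null restarts every replicate from the observed graph
and applies 10·|E| accepted double edge swaps (numba-compiled; a replicate
that cannot reach its swap target within 200× attempts — e.g. a star or
complete graph — raises an error). The default test metric is the number of
seed-internal edges; global clustering and mean seed distance are
alternatives, and the chosen metric is declared in the output. The
empirical p uses the (1 + #{null ≥ obs})/(N + 1) correction and can never
be zero — a saturated result reports 1/(N+1), not an asymptotic tail value.
Small-world σ = (C/C_rand)/(L/L_rand) uses the same null's mean clustering
and path length (largest component if a replicate disconnects). The degree
tail is fitted by discrete maximum likelihood, α = 1 + n/Σ ln(k/(k_min−½)),
scanning k_min by Kolmogorov–Smirnov distance; this estimator is written
in-package.

### Phenotype formulas

- Comparative Ct: quantity = E^(Ct_min(gene) − Ct), E ∈ (1, 2] (default 2),
  so the best-expressed sample of each gene has quantity 1. Invariant to
  adding a constant to a gene's Ct values.
- geNorm: V_jk = sd over samples of log2(q_j/q_k); M_j = mean over k≠j.
  Candidates are dropped highest-M-first until 2 remain (configurable) or
  all M < 0.5; the normalisation factor is the per-sample geometric mean of
  the kept references.
- Fold induction: normalised quantity divided by the mean of the dark-housed
  samples of the same genotype; dark groups average to exactly 1.
- Western blot: (signal/loading control) / mean over wild-type samples.
- MRI: structure/whole-brain volume ratios, per-structure Student t
  (equal-variance, as is conventional for these designs), BH-adjusted.
- Behaviour: Shapiro–Wilk per group and Brown–Forsythe (median-centred
  Levene) at α = 0.05 gate one-way ANOVA vs Kruskal–Wallis; any group with
  n < 3 forces the non-parametric path (logged). Fisher's LSD post-hoc
  (pairwise t with the pooled ANOVA error term, unadjusted) runs only when
  the omnibus p < 0.05. The novel-object recognition test is a two-sided
  one-sample t of % novel-object sniffing against 50% — two-sided because a
  preference for the familiar object is a real outcome.

## The synthetic-data generator

The generator emulates the structure of a segmental-duplication panel
screen: ~5 trisomic vs ~5 control samples per model, seven overlapping
models (a full-region model containing proximal/middle/distal sub-models, a
compound model equal to the union of two disjoint sub-intervals, a
single-gene transgenic, and a composite model that adds a non-syntenic
interval on another chromosome), cis genes at a 1.5× linear dosage ratio
with partial compensation, and genome-wide trans effects partially shared
between models with overlapping intervals.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_control, n_trisomic | 5, 5 | the per-group sample size of such screens |
| dosage_ratio | 1.5 | three copies vs two at proportional expression |
| compensation_prob | 0.45 | mid-range of the 38–57% compensation these panels report |
| noise_sd | 0.15 log2 units | array-like replicate noise giving realistic power at n = 5; not a published value |
| baseline_mean, baseline_sd | 7.0, 2.0 log2 units | typical intensity scale and spread |
| n_trans_effects | 300 (10,000-gene genome) | yields genome-wide DEG counts in the observed few-percent range |
| trans_effect_sd | 0.3 log2 units | trans effects mostly smaller than the cis shift, partially detectable |
| shared_program_fraction | 0.5 | half of a model's trans program shared with its closest panel mate |

Cross-model structure: compensation flags are drawn once per gene and shared
across the panel (compensated genes behave alike in every trisomic context),
and each model reuses round(shared_fraction · o · n_trans) entries of a
global (gene, effect) pool, where o is the largest Jaccard overlap between
its cis set and any other panel member's. This makes cross-model fold-change
correlation a monotone function of the sharing parameter.

What the generator does **not** emulate: probe-level microarray artefacts
(no probe sets, background correction or normalisation — the simulated
matrix is already normalised), intensity-dependent variance, correlated
noise between samples, batch effects, or biologically structured trans
networks. Passing tests therefore demonstrate the statistical machinery is
correct under the stated model, not that it is robust to every failure mode
of real array data.

All generators draw from a single `numpy` Generator per call, seeded
explicitly; identical seeds give byte-identical outputs.

## Problem sizes

The test-suite and analysis drivers run at deliberately desk-sized scales:
10,000–20,000 genes, 5v5 designs, 300-node interactomes, 10,000 null
replicates (the swap kernel handles this in seconds; larger replicate
counts are a parameter, not a code change), 500 random gene sets × 10 seeds
for FDR checks. The analysis cohort in `analysis/` uses one fixed seed
(2026) end to end.

## Known limitations

- The greedy connector insertion is a heuristic; it guarantees connectivity
  and connector essentiality, not global Steiner optimality.
- The meta-pathway keyword map is a reconstruction; real GO/KEGG term
  counts depend on database snapshots and are out of scope.
- The theoretical FCROS standardisation ignores inter-pair dependence; the
  empirical mode is the default for that reason.
- Repeated-measures behaviour designs are reduced to per-session one-way
  comparisons; no mixed models.
- The machine-learning connector-relevance scoring used in some published
  network analyses is replaced by a transparent composite (betweenness ×
  degree percentiles) and is clearly labelled as such where exposed.
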