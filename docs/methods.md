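# Methods

This note documents the statistical procedures implemented in `tipdnb`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.  The package analyses a
gene × sample expression matrix whose samples fall into ordered condition
groups; the first group of the design is the reference for every contrast.

## Differential-expression screen (`tipdnb.deg`)

Counts are normalised to `log2((c + p) / (L + 2p) · 10⁶)` with library size
`L` and pseudocount `p = 0.5` (the standard prior-count convention; the
pseudocount only matters for genes near zero).  For each treatment group a
per-gene two-sided Welch t-test against the reference gives the p-value and
`log2FC = mean(group) − mean(reference)` on the log2 scale; Benjamini–
Hochberg step-up adjustment is applied across genes within each contrast,
and a gene is a DEG when `FDR < fdr_threshold` **and**
`|log2FC| > lfc_threshold` (defaults 0.01 and 1.2, both strict, so boundary
values are not called).

The Welch test is deliberately simple and pools no information across
genes.  Two consequences are worth knowing:

* **Small designs are very conservative.**  At n = 3 per group the
  Satterthwaite degrees of freedom are ≈ 2–4, which caps how small a
  p-value can get; after BH adjustment at 0.01 across thousands of genes,
  essentially nothing is callable regardless of effect size.  Screens at
  n = 3 should be read as highly specific, not sensitive; with n = 10 the
  screen recovers planted two-fold (log2) effects with recall ≈ 1 and
  observed FDR ≈ 0 (tested).  Count-model tests with pooled dispersion
  estimation behave very differently here; this package states its test in
  its outputs and does not emulate them.
* **Composition effects.**  Plain CPM normalisation assumes expression
  changes roughly cancel across the transcriptome.  If a large fraction of
  the library shifts strongly in one direction, all null genes acquire an
  apparent opposite fold change and the observed FDR rises.  Trimmed-mean
  scale normalisation is out of scope; very asymmetric strong responses
  are a documented limitation.

Under a global-null simulation the mean fraction of gene × contrast pairs
passing the rule stays at or below the nominal 0.01 (tested over 20 seeds).

Top-N overlap between contrasts takes each group's top `n = 50` DEGs by
`|log2FC|` (ties broken by smaller FDR, then gene id) and reports the
intersection both as a fraction of the list length (`over_n`; the smallest
actual list if a group has fewer than n DEGs) and of the union
(`over_union`) — the two readings of an "overlap percentage" — because
multi-list overlap proportions are otherwise ambiguous.

qPCR relative quantification uses `2^−ΔΔCt`: per group,
`ΔCt = mean Ct(target) − mean Ct(reference gene)`, then
`ΔΔCt = ΔCt(group) − ΔCt(reference group)`; the reference group's fold
change is exactly 1.

## Temporal profile clustering (`tipdnb.clustering`)

Each gene is reduced to its vector of group means over the ordered
conditions and z-scored across groups (population SD), so clustering sees
trend shape only; genes constant across group means are dropped and listed.
Clustering is fuzzy c-means on Euclidean distance — the algorithm behind
Mfuzz-style time-course clustering — implemented directly:

* objective `J = Σᵢⱼ uᵢⱼ^m ‖xᵢ − vⱼ‖²` with memberships summing to 1 per gene;
* alternating closed-form updates (membership `uᵢⱼ ∝ (Σₖ (dᵢⱼ/dᵢₖ)^{2/(m−1)})⁻¹`,
  centroids as `u^m`-weighted means), which makes the objective
  non-increasing (asserted per iteration in tests);
* k-means++ seeding from the given seed, so runs are reproducible from the
  config alone;
* a profile exactly on a centroid gets a unit membership (the update is
  singular there);
* convergence when the maximum centroid displacement falls below
  `tol = 1e−6`, with `max_iter = 500` and an explicit `converged` flag.

Defaults: `c = 8` clusters and fuzzifier `m = 1.25`.  The fuzzifier is the
one genuinely free knob: values near 1 give near-hard partitions (tested:
`m = 1.01` yields maximal memberships ≥ 0.99 on separated data), large
values blur everything.  1.25 is a common choice for standardized
expression profiles and is configurable; the Schwämmle–Jensen data-size
heuristic is available (`estimate_fuzzifier`, CLI `--estimate-m`) but not
the default, to keep results a pure function of the config.
Clustering operates on group means (one point per ordered condition), not
per-replicate profiles — the object of interest is the trend.

Centroid shapes are labelled with a tolerance ε = 5% of the centroid
range: monotone up (all successive differences ≥ −ε), monotone down
(all ≤ ε), up-then-down (a single +→− sign change), otherwise "other".
A flat centroid satisfies the monotone-up rule first; the order is part of
the contract.

## Gene-set enrichment (`tipdnb.gsea`)

Genes are ranked by signal-to-noise `(meanA − meanB)/(sdA + sdB)` with each
sd floored at `max(0.2·|mean|, 0.2)` (the classic convention; a plain
log2FC metric is available), ties broken by gene id.  The enrichment score
walks the ranked list: a set member adds `|r|^p / Σ_hits |r|^p` (weight
`p = 1`; uniform shares if all hit metrics are zero), a non-member
subtracts `1/(N − N_hit)`; ES is the running-sum value of largest
magnitude (first position on ties).  With `p = 0` the running sum ends at
zero — the unweighted Kolmogorov–Smirnov case, kept as an internal
consistency check.

Significance comes from permutation: sample-label permutation (all distinct
relabelings when there are at most B of them) when each group has at least
7 replicates, otherwise random same-size gene sets — the standard fallback
for small-n designs, and the only option at n = 3.  The nominal p is
`(1 + #{same-sign nulls with |ES_null| ≥ |ES|}) / (1 + B_same-sign)`; NES is
ES over the mean same-sign null; BH adjustment runs across all tested sets
with significance at adjusted p < 0.05.

The leading edge is the set members at or before the running-sum peak (at
or after, for negative ES).  The key-gene screen then requires, over two
contrasts ("mild" and "severe" vs the reference), `|LFC| > 0.7` in one and
`|LFC| > 1` in the other, in either arrangement.  LFC is read as absolute
log2 fold change: a threshold on signed fold change would exclude
down-regulated markers, which are expected among e.g. suppressed metabolic
genes in injury time courses.

## Dynamic network biomarker analysis (`tipdnb.dnb`)

The DNB premise: approaching a critical transition, a group of genes shows
(i) sharply increased within-condition variance, (ii) strong mutual
correlation, and (iii) weakened correlation with the rest of the
transcriptome; past the transition the signature disappears.  Per
non-reference group:

1. **Selection.**  A gene is selected when its within-group SD is at least
   `sd_fold = 2.0` times its reference-group SD.  "High deviation" is
   operationalised as this transparent fold rule by default; two
   alternatives are provided: a per-gene one-sided variance-ratio F-test
   (BH-adjusted, `method='ftest'`) for users who want formal error
   control, and an absolute mode (`use_reference=False`) that selects
   genes whose group SD exceeds `sd_fold` times the median group SD,
   for designs where the reference group is unreliable.  Genes with zero
   reference SD are selected when their group SD is positive and flagged.
   On counts matrices, genes zero in at least half the samples are
   excluded first.
2. **Grouping.**  Average-linkage hierarchical clustering on the distance
   `1 − |PCC|`, tree cut at `1 − threshold` with `threshold = 0.9`:
   clusters merge only while their average absolute correlation stays
   above 0.9.  On well-separated correlation blocks this coincides with
   the connected components of the `|PCC| ≥ 0.9` graph (tested); between
   the two readings of "group genes at a 0.9 threshold", the
   average-linkage tree is taken as the default because a distance matrix
   implies agglomerative grouping, and the component reading is available
   as `cluster_method='components'`.  Clusters smaller than
   `min_cluster_size = 5` are set aside: pairs and triplets give unstable
   mean correlations.
3. **Scoring.**  For each candidate cluster, `mean_SD` (mean within-group
   SD of cluster genes), `PCC₁` (mean |PCC| over distinct intra-cluster
   pairs), `PCC₀` (mean |PCC| between cluster genes and the *other
   selected* genes — the per-group analysis universe is the selected set
   by default; `pcc0_universe='all'` computes it genome-wide instead,
   which lowers PCC₀ for a decoupled module but lets unexpressed and
   noise-floor genes dominate the average), and

       CI = mean_SD · PCC₁ / PCC₀.

   Absolute correlations are used in both PCC terms.  A cluster with
   `PCC₀` below 1e−6 has an undefined CI (an isolated cluster is not
   infinitely scored); a group with no scored cluster has an undefined CI
   and is excluded from the arg-max rather than raising.
4. **Tipping point.**  The group with the maximal CI over its best cluster
   (ties: larger cluster, then lexicographically first gene).  On null
   data the CI-vs-group profile is flat — in practice no candidate cluster
   forms at all at the 0.9 threshold — so a sharp peak is signal (tested:
   50/50 null seeds flat, 100/100 planted seeds recovered at the
   default parameters).

CI is scale-dependent: its `mean_SD` factor carries the units of the input
matrix, so CIs computed on log2-CPM data (the pipeline default, mean SDs
of order 1) are numerically much smaller than CIs computed on other
scales, while the correlation factors are scale-free.  Comparisons are
therefore only meaningful within one run; the input scale is an explicit
flag and is recorded in the run manifest.  A further caveat: with n = 3
replicates, pairwise Pearson correlations are extremely noisy and the
0.9 threshold acts more as a coarse filter than a precise cut; the
recovery experiments in the tests use n = 10 for exactly this reason.

## Synthetic data (`tipdnb.synthetic`)

The generator emulates the target study design: six ordered groups
(reference "sham", then graded treatment durations) with 3 replicates by
default.  Per gene, a baseline mean is drawn log-normally (natural-log
location 5.5, scale 1.2 → median ≈ 245 counts), and replicate counts are
gamma–Poisson (negative binomial) with dispersion φ = 0.05 — the
mean–variance structure bulk RNA-seq screens assume.  Planted structure
enters as group-indexed log2 offsets:

* **DE genes** — per treatment group, a fraction (default 5%) of genes
  receives a signed offset with `|effect| ~ N(2.0, 0.5)`.  Effects are
  kept modest by default: planting very large effects in a large fraction
  of genes triggers the CPM composition artifact described above, which is
  a property of the normalisation, not of the screen.
* **Profile genes** — trend shapes over the ordered groups: linear up or
  down to ±amplitude, a tent peaking mid-course, or a late-only response.
* **Enriched gene sets** — membership is fixed before sampling; a planted
  set fills its signal fraction from genes already consistently directional
  across all treatment groups, recruiting background genes (and giving
  them a uniform ±2 log2 offset, recorded in the truth) when too few
  exist.  Planted enrichment is therefore real by construction, and is
  defined relative to reference contrasts.
* **DNB module** — in the tipping group only, module genes share a latent
  per-replicate factor and receive extra independent jitter on the log2
  scale.  The per-gene count-noise floor is `σ₀² = (φ + 1/μ)/ln2²` (delta
  method, verified within ~3% empirically).  Module variance is set to
  `max(F, 1/(1 − ρ₁)) · σ₀²` for variance-inflation target F and
  intra-correlation target ρ₁: when `ρ₁ ≤ (F − 1)/F` both targets are met
  exactly; otherwise they are jointly unreachable — the irreducible
  independent count noise cannot fit inside the independent-variance
  budget `(1 − ρ₁)F σ₀²` — and the correlation target takes precedence
  (realized inflation `1/(1 − ρ₁)`), because the downstream 0.9
  correlation threshold makes the realized correlation the load-bearing
  quantity.  The latent factor is standardized to zero mean and unit
  sample variance per dataset so the planted correlation is realized in
  each simulation rather than only in expectation.  Background genes get a
  small loading on the same factor sized to hit the module-to-background
  correlation target.

One global seed drives a separate child seed per gene (plus dedicated
streams for structure assignment and the latent factor), so results are
bit-reproducible and independent of gene order.

What the generator does **not** emulate: library-size and batch
confounders, gene–gene correlation outside the planted module, length or
GC biases, and outlier samples.  Passing recovery tests therefore show the
algorithms do what they claim under their own assumptions — not that real
data satisfies those assumptions.

## Problem sizes in the test suite

The recovery and calibration experiments run at sizes chosen to make their
statistical claims meaningful while keeping the suite quick: tipping-point
recovery uses 100 seeds of 500 genes × 6 groups × 10 replicates (n = 10
rather than 3 for correlation stability), the null-calibration screens use
5,000 genes × 20 seeds, enrichment and composite-index oracle checks use
50–100 random instances at 20–50 genes, and the brute-force oracles are
exact, so their tolerances are numerical (1e−12), not statistical.

## Pipeline (`tipdnb.pipeline`, `tipdnb.cli`)

`run_all` executes deg → cluster → gsea → dnb from one validated YAML
config; unknown keys are hard errors (no silent typo tolerance), every
parameter has the defaults above, and all intermediates are TSV/JSON so
any stage can be re-run from files.  The manifest records package version,
schema version, seed, parameters, input SHA-256 checksums and stage
wall-times; identical config + seed reproduces byte-identical outputs
(tested).
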