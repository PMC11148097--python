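# Methods

## Design overview

`ithlayers` quantifies intratumor heterogeneity (ITH) from multi-region
sampling: each patient contributes ≥ 2 spatially separated tumor regions
and one matched normal. Four molecular layers are treated with two
representations:

* **discrete alterations** (somatic mutations, CNV events) — binary
  presence per region, compared by Jaccard distance;
* **continuous profiles** (methylation beta values per window, expression
  abundance per gene) — purity-corrected, sum-normalized into probability
  distributions, compared by Jensen–Shannon distance (JSD).

Per patient and layer, all C(n_regions, 2) pairwise distances are computed
and their arithmetic mean is the patient's layer ITH. Cohort analyses
(subtype contrasts, cross-layer correlations, survival stratification)
consume these pairwise values and per-patient means.

## Somatic-call processing

Calls arrive as a MAF-like table downstream of an external caller; the
package applies, in order:

1. **Sample QC** — exclude regions with QScore < 35, contamination > 0.02
   or mean depth < 30×. Thresholds are strict exclusions (boundary values
   pass); a missing metric excludes the sample with reason
   `missing_metric`.
2. **Read-support filter** — SNVs need ≥ 6 alt reads, small indels ≥ 8
   (indel = ref/alt length difference). Applied per region.
3. **Population-frequency filter** — calls with > 1% population frequency
   are removed as putative germline. This runs **before** rescue so that
   germline contamination can never be propagated across regions.
4. **Cross-region rescue** — for each variant passing in ≥ 1 region of a
   patient, a call is added in every other region with ≥ 1 raw supporting
   read. Rescue is monotone and idempotent and repairs the false-negative
   sharing that multi-region designs otherwise over-count as branch
   events.
5. **Trunk/branch** — on post-rescue presence: trunk iff present in all
   tumor regions. Rescue-first ordering is deliberate: the rescue rule
   exists precisely to stabilize this classification.

TMB is the missense count (per region), optionally per Mb over a 39-Mb
exome target. Driver status is a role annotation (oncogene/TSG vs
passenger), as a cancer-gene-census list would provide; enrichment is the
per-patient driver fraction among trunk vs branch mutations, compared
across the cohort by Wilcoxon rank-sum with pairwise deletion of patients
lacking one side. Signature matching is cosine similarity against a
caller-provided catalog with a strict > 0.6 acceptance threshold; spectrum
extraction itself (NMF) is out of scope.

## CNV layer

Arm-level calls use the strict *more-than-60%* rule: gain iff amplified
segments exceed 60% of the arm's segments (loss analogously). The fraction
is over segment **counts** by default, with a `fraction_by="length"`
switch, because callers emit segmentations whose counts, not lengths, the
rule references. Arm and focal events flatten to `arm:direction` keys in a
binary region × event matrix sharing the code path of the mutation
presence matrix.

## Purity correction

Observed bulk signal is modelled as a two-component mixture,
`observed = p·tumor + (1−p)·normal` with `p` the region's tumor purity.
The correction inverts this against the matched normal profile and clamps
to [0, 1] for beta values, [0, ∞) for expression. This closed-form linear
deconvolution replaces heavier reference-based purity tools: it is the
standard identity, uses only data the bundle already carries, and is
exactly invertible on the generator's noise-free mixtures (tested to
1e-12). The matched patient normal is the default reference; a pooled
normal mean can be substituted when no matched normal exists.

## DMR calling

Windows (default 100-bp conceptually; any fixed tiling works) are pooled
across the samples of each group; each window gets a two-sided Fisher
exact test on the pooled methylated/unmethylated 2×2 table,
Benjamini–Hochberg FDR (substituting for the SLIM q-values internal to
methylKit), and a DMR requires |Δbeta| ≥ 0.2 **and** q < 0.05. Windows
with pooled coverage below 5 reads in either group are dropped. The
effect-size floor dominates error control: under the null the positive
fraction is far below the nominal 0.05 (verified over 50 simulated null
cohorts).

## ITH metrics

* Jaccard distance `1 − |∩|/|∪|`; undefined (missing) when both sets are
  empty, excluded from patient means.
* JSD with base-2 logarithms (bounded [0, 1]); probability conversion is
  plain sum-normalization with **no pseudocount** — the KL terms are taken
  against the mixture `R ≥ P/2`, so no division by zero can occur, and an
  all-zero profile is an error rather than invented mass.
* Methylation JSD uses all covered windows (not DMR-restricted), on
  purity-corrected betas aligned by inner join across the patient's
  regions; restricting to DMRs is a caller-side choice the API permits by
  pre-filtering the table.
* Median split: patients strictly above the cohort median are "high",
  at-or-below are "low" (tie rule fixed for determinism, configurable);
  missing values stay unassigned.

## Trees

Distance matrices are Euclidean: on binary alteration rows (normal = the
all-zero row) this is sqrt(Hamming), on methylation it uses
purity-corrected betas binned to 500-kb windows with the measured normal
profile as the root row. Tree search is **exhaustive OLS minimum
evolution**: every unrooted binary topology (3 at 4 leaves, 10,395 at the
8-leaf cap) gets OLS branch lengths against the distance matrix; negative
fitted lengths are clamped to zero before the total-length comparison
(switchable to raw OLS lengths); ties break on a lexicographic split
encoding. For additive inputs this is an exact inverse of path-distance
computation (round-trip tested to 1e-9), which a heuristic search cannot
guarantee. Trees are rooted at the normal leaf; the edge incident to the
root is reported as the displayed trunk length, while trunk/branch
*statistics* always come from sharing counts, not tree edges.
Concordance between layer trees is the Robinson–Foulds distance on
unrooted topologies, with "aligned" operationalized as RF = 0 — a strict
criterion; visual tree comparison in the literature is more permissive, so
aligned counts here are conservative.

## Survival and cohort statistics

Wilcoxon rank-sum: exact enumeration when the pooled sample is ≤ 12
without ties, otherwise the tie-corrected continuity-corrected normal
approximation (scipy backend). Spearman correlations use the t
approximation with n−2 df and report missing on zero rank variance.
Kaplan–Meier estimation and the log-rank test are backed by lifelines and
validated against hand product-limit and observed-minus-expected oracles.
Group comparison of median-split ITH uses the log-rank test — the standard
Kaplan–Meier companion — with medians reported as time or "NR" (not
reached). All tests are two-sided at α = 0.05. Multivariate Cox modelling
is intentionally excluded; the per-patient covariate table the pipeline
exports feeds any survival package directly.

## Synthetic cohort generator

The generator's defaults encode the emulated study conditions: 12 H-like
and 8 L-like patients, 3 tumor regions + 1 normal each, trunk fractions
0.663 (H) and 0.172 (L), tumor/normal exome depth 250×/75×, methylation
depth 34×, ~100 somatic mutations per patient, 2% of generated mutations
carrying > 1% population frequency to exercise the germline filter.
Purities are drawn uniformly from (0.3, 0.8) — per-region purity is not
published, so this range is a single fixed choice of a plausible FFPE
operating regime. Per-mutation clone structure is the trunk/branch
dichotomy itself: trunk with the subtype's probability, otherwise a
uniformly chosen non-empty proper region subset (the only clone structure
the downstream statistics use; no multilevel clone tree is modelled).
Driver probability is boosted on the trunk by an odds multiplier
(default 3).

Read counts are Binomial(depth, purity/2) in carrier regions and
Binomial(depth, error_rate) elsewhere. The default
`error_rate = 1e-4` is the per-read probability that a read supports the
*specific* alternate allele after base-quality filtering; at 250× this
yields a sporadic supporting read in ~2.5% of non-carrier regions —
enough traffic to exercise the rescue rule while keeping rescue-induced
trunk inflation around 0.01, small against the trunk-fraction recovery
tolerance of 0.05. (At 1e-3 a sporadic read appears in ~22% of non-carrier
regions and the ≥ 1-read rescue rule would systematically convert branch
to trunk.)

Methylation: per-window normal betas from Beta(2, 8); DMR windows (10%)
shift by ±0.3 with trunk/branch region assignment like mutations; observed
betas are the purity mixture, counts Binomial(Poisson(34), observed).
Expression: log-normal baselines, 10% of genes at ±1 log2 fold-change in
tumor, purity-mixed **without** additional noise — expression values are
expected abundances, which keeps the purity-correction identity exact and
leaves count-level noise modelling out of scope. Survival: exponential
event times whose hazard is multiplied by `hazard_ratio_highITH`
(default 0.25, i.e. high genetic ITH → lower hazard, the direction
observed in the emulated study) for patients above the cohort median of
*true* mean Jaccard ITH; censoring replaces the event with a
Uniform(0, T) time for a configurable fraction of patients.

Each patient consumes an independent substream spawned from the master
seed, so cohorts are bit-reproducible and stable under patient reordering;
the cohort-level survival draw uses its own substream.

### What the generator does not emulate

Real genome coordinates and trinucleotide contexts, mutation multiplicity
and CNV–VAF coupling, FFPE damage artifacts beyond the QC thresholds,
spatially correlated methylation, count-level expression noise, and
informative censoring. Passing tests therefore demonstrate correctness of
the computational chain under the stated generative model, not robustness
to every artifact of real FFPE multi-region data.

## Problem sizes and numerical choices

Test and acceptance runs use scaled cohorts (typically 5–20 patients,
40–100 mutations, 60–300 methylation windows, 30–200 genes) — sizes chosen
so each property is statistically identifiable while the full suite stays
fast. Floating-point policy: JSD squares are floored at 0 before the
square root; OLS ties in tree search resolve lexicographically;
report JSON is written with sorted keys and full float precision so
fixed-seed pipeline runs are byte-identical. Degenerate inputs follow a
"missing, not invented" rule: Jaccard on two empty sets, trunk proportions
with zero variants, Spearman under zero rank variance and medians of
empty splits are all reported as missing rather than coerced to numbers.

## Known limitations

* The exact tree search caps at 8 leaves; larger designs need a heuristic
  minimum-evolution implementation (out of scope).
* Expression differential analysis, GISTIC-style focal peak discovery,
  NMF signature extraction and Cox regression are consumed as inputs or
  exported for external tools, not reimplemented.
* RF = 0 is a conservative definition of tree alignment; small methylation
  feature counts after 500-kb binning make phyloepigenetic topologies
  noisy, so concordance rates on synthetic data undercount "visually
  similar" trees.
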