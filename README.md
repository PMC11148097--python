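# ithlayers

Multi-region, multi-omic **intratumor heterogeneity (ITH)** analysis for
tumor cohorts sampled at several spatially separated regions per tumor plus
a matched normal — the design used to study rare lung adenocarcinoma
subtypes such as fetal adenocarcinoma (high-grade vs low-grade). The
package starts downstream of external variant/CNV/methylation callers: its
inputs are call tables (MAF-like mutations, SEG-like segments, BED-like
methylation counts, expression matrices), and its outputs are per-patient
ITH scores, trees, and cohort statistics.

## What it computes

* **Somatic-call processing** — sample QC (QScore ≥ 35, contamination
  ≤ 0.02, depth ≥ 30×), supporting-read filters (SNV ≥ 6, indel ≥ 8 alt
  reads), the > 1% population-frequency germline filter, and the
  cross-region **rescue rule**: a variant that passes in one region and has
  ≥ 1 supporting read in a paired region is called in both.
* **Trunk/branch classification** — after rescue, a variant present in all
  tumor regions is *trunk*, otherwise *branch*; per-patient trunk
  proportions and driver (oncogene/TSG) enrichment on trunk vs branch.
* **Arm-level CNV calls** — an arm is gained/lost when > 60% of its
  segments are amplified/deleted; arm events feed a binary region × event
  matrix.
* **Genetic ITH** — the Jaccard distance between region alteration sets
  (Eq. below), per region pair and averaged per patient:

  `d_J(V_i, V_j) = 1 − |V_i ∩ V_j| / |V_i ∪ V_j|`

* **Epigenetic / transcriptional ITH** — the Jensen–Shannon distance
  between sum-normalized, **tumor-purity-corrected** methylation or
  expression profiles (base-2 logs, so JSD ∈ [0, 1]):

  `JSD(P1, P2) = sqrt( ½ [ D_KL(P1‖R) + D_KL(P2‖R) ] )`, `R = (P1+P2)/2`

  Purity correction inverts the two-component mixture
  `observed = p·tumor + (1−p)·normal` against the matched normal.
* **Trees** — per patient, minimum-evolution trees on Euclidean distances
  (binary matrices for mutations/CNV, purity-corrected 500-kb window betas
  for methylation), rooted at the normal sample; topologies found by exact
  exhaustive OLS search (≤ 8 leaves) and compared by Robinson–Foulds
  distance.
* **Cohort statistics** — Wilcoxon rank-sum subtype comparisons, Spearman
  correlations between layers on pairwise ITH values, Kaplan–Meier curves
  and log-rank tests after splitting patients at the cohort **median** of
  per-patient mean ITH.
* **Synthetic cohorts** — a generator with known ground truth (clone
  structure, purities, DMRs, survival groups) emulating 3 tumor regions +
  1 normal per patient at 250×/75× exome depth, so the whole chain is
  testable without controlled-access patient data.

## Worked example

Simulate a 20-patient cohort (12 high-grade-like patients with trunk
fraction 0.663, 8 low-grade-like with 0.172) and run the full pipeline:

```sh
ithlayers simulate --seed 5 --out simdemo/
ithlayers run --manifest simdemo/manifest.yaml --out rundemo/ --seed 5
```

which prints

```
wrote cohort of 20 patients to simdemo/manifest.yaml
analyzed 20 patients; report at rundemo/report.json
median-split log-rank p-values: {"cnv": {"os": 0.04966983977734399, ...},
 "mutational": {"os": 0.004679116725307229, "rfs": 0.01330228962633311}, ...}
```

In `rundemo/report.json` for this run: the median trunk proportion is
0.689 in the H-like group vs 0.168 in the L-like group (tracking the
configured 0.663/0.172); pairwise mutational ITH is higher in the L-like
group (median 0.653 vs 0.221, Wilcoxon p ≈ 7.5e-11); drivers are enriched
on the trunk (mean trunk driver fraction 0.245 vs branch 0.111,
p ≈ 2.7e-7); and the high-genetic-ITH group — simulated with a 0.25 hazard
multiplier — shows better overall survival (log-rank p ≈ 0.0047). These
directions are the generator's configured truth propagating through the
pipeline, not biological claims.

The same analyses run on real call tables via a YAML manifest pointing at
the TSV layers (see `ithlayers.io_formats` for column dialects).

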