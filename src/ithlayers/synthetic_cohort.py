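"""Synthetic multi-region, multi-omic cohorts with known ground truth.

Emulates the sampling design of a multi-region FFPE tumor study: per
patient, ``n_regions`` spatially separated tumor regions (default 3) plus
one matched normal; whole-exome-like somatic calls with binomial read
counts at ~250×/75× tumor/normal depth; arm-structured copy-number
segments; bisulfite-style window methylation counts at ~34×; purity-mixed
expression abundances; and exponential survival outcomes whose hazard
depends on the patient's genetic-ITH group.

Clone structure is the trunk/branch dichotomy the downstream statistics
use: each somatic alteration is a trunk event (present in all regions)
with the subtype-specific trunk fraction (defaults 0.663 for the
high-grade-like group and 0.172 for the low-grade-like group), otherwise
it is assigned a uniformly chosen non-empty proper subset of regions.
Observed methylation and expression values are two-component purity
mixtures of the true tumor signal and the matched normal profile, which
makes the purity correction in :mod:`ithlayers.methylation_layer` exactly
invertible on noise-free values.

Everything is driven by one master seed through per-patient substreams, so
cohorts are bit-reproducible and stable under patient reordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import cnv_layer
from .io_formats import CohortBundle
from .ith_metrics import jaccard_distance

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_patient",
    "simulate_cohort",
    "simulate_survival_groups",
]

_VARIANT_CLASSES_SNV = ("missense", "synonymous", "nonsense", "splice")
_VARIANT_PROBS_SNV = (0.6, 0.2, 0.1, 0.1)
_CHROMS = tuple(f"chr{c}" for c in range(1, 6))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Defaults encode the emulated study conditions: 12 high-grade-like (H)
    and 8 low-grade-like (L) patients, 3 tumor regions each, subtype trunk
    fractions at the reported cohort medians, 250×/75× tumor/normal
    sequencing depth and 34× methylation depth, with purities drawn
    uniformly from (0.3, 0.8) since per-patient purity values are not
    reported.
    """

    n_patients_H: int = 12
    n_patients_L: int = 8
    n_regions: int = 3
    trunk_fraction_H: float = 0.663
    trunk_fraction_L: float = 0.172
    n_mutations_mean: float = 100.0
    driver_fraction: float = 0.1
    trunk_driver_enrichment: float = 3.0
    purity_range: tuple[float, float] = (0.3, 0.8)
    tumor_depth: int = 250
    normal_depth: int = 75
    error_rate: float = 1e-4
    contaminant_fraction: float = 0.02
    n_windows: int = 300
    dmr_fraction: float = 0.1
    dmr_shift: float = 0.3
    meth_depth: int = 34
    n_genes: int = 200
    de_fraction: float = 0.1
    de_log2fc: float = 1.0
    n_expression_patients: int | None = None
    arm_event_rate: float = 0.3
    segments_per_arm: int = 10
    segment_noise_rate: float = 0.02
    hazard_ratio_highITH: float = 0.25
    os_scale_months: float = 60.0
    rfs_scale_months: float = 40.0
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "trunk_fraction_H": self.trunk_fraction_H,
            "trunk_fraction_L": self.trunk_fraction_L,
            "driver_fraction": self.driver_fraction,
            "dmr_fraction": self.dmr_fraction,
            "de_fraction": self.de_fraction,
            "censor_rate": self.censor_rate,
            "contaminant_fraction": self.contaminant_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if min(self.tumor_depth, self.normal_depth, self.meth_depth) < 1:
            raise ValueError("sequencing depths must be >= 1")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"purity_range must lie in (0, 1], got {self.purity_range}")

    @property
    def n_patients(self) -> int:
        return self.n_patients_H + self.n_patients_L

    def trunk_fraction(self, subtype: str) -> float:
        return self.trunk_fraction_H if subtype == "H" else self.trunk_fraction_L

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Per-patient generative truth: clone labels, true tumor profiles and
    true pairwise ITH, plus the cohort-level survival grouping."""

    patients: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)


def _choose_subset(rng: np.random.Generator, n_regions: int) -> np.ndarray:
    """Uniformly chosen non-empty proper subset of region indices."""
    size = int(rng.integers(1, n_regions))
    members = rng.choice(n_regions, size=size, replace=False)
    mask = np.zeros(n_regions, dtype=bool)
    mask[members] = True
    return mask


def _trunk_driver_prob(cfg: SimulationConfig) -> float:
    p = cfg.driver_fraction
    if p in (0.0, 1.0):
        return p
    odds = p / (1.0 - p) * cfg.trunk_driver_enrichment
    return odds / (1.0 + odds)


def simulate_patient(
    config: SimulationConfig,
    patient_index: int,
    rng: np.random.Generator,
) -> tuple[dict, dict]:
    """Simulate one patient: sample sheet rows, somatic calls, CNV
    segments, methylation counts and expression columns, plus the ground
    truth behind them.

    The first ``n_patients_H`` indices are high-grade-like (subtype H),
    the rest low-grade-like (L).  Returns (tables, truth) where ``tables``
    holds DataFrames keyed like the cohort layers.
    """
    if patient_index < 0 or patient_index >= config.n_patients:
        raise ValueError("patient_index out of range")
    subtype = "H" if patient_index < config.n_patients_H else "L"
    tf = config.trunk_fraction(subtype)
    pid = f"P{patient_index + 1:02d}"
    regions = [f"{pid}_R{k + 1}" for k in range(config.n_regions)]
    normal_id = f"{pid}_N"
    lo, hi = config.purity_range
    purities = rng.uniform(lo, hi, config.n_regions)

    sample_rows = [
        {
            "patient_id": pid,
            "region_id": rid,
            "tissue": "tumor",
            "purity": purities[k],
            "mean_depth": float(config.tumor_depth),
            "qscore": float(np.round(rng.uniform(40, 60), 2)),
            "contamination": float(np.round(rng.uniform(0.0, 0.01), 4)),
        }
        for k, rid in enumerate(regions)
    ]
    sample_rows.append(
        {
            "patient_id": pid,
            "region_id": normal_id,
            "tissue": "normal",
            "purity": 1.0,
            "mean_depth": float(config.normal_depth),
            "qscore": float(np.round(rng.uniform(40, 60), 2)),
            "contamination": float(np.round(rng.uniform(0.0, 0.01), 4)),
        }
    )

    # --- somatic mutations -------------------------------------------------
    n_mut = int(rng.poisson(config.n_mutations_mean))
    mut_rows: list[dict] = []
    labels: dict[str, str] = {}
    true_sets: dict[str, set] = {rid: set() for rid in regions}
    p_driver_trunk = _trunk_driver_prob(config)
    for i in range(n_mut):
        chrom = _CHROMS[i % len(_CHROMS)]
        pos = 1_000_000 + (i // len(_CHROMS)) * 150 + 1
        is_indel = rng.random() < 0.1
        if is_indel:
            ref, alt = "AC", "A"
            vclass = "frameshift_indel" if rng.random() < 0.7 else "inframe_indel"
        else:
            ref, alt = "C", "T"
            vclass = rng.choice(_VARIANT_CLASSES_SNV, p=_VARIANT_PROBS_SNV)
        key = f"{chrom}:{pos}:{ref}:{alt}"
        contaminant = rng.random() < config.contaminant_fraction
        trunk = rng.random() < tf
        carriers = (
            np.ones(config.n_regions, dtype=bool)
            if trunk
            else _choose_subset(rng, config.n_regions)
        )
        p_driver = p_driver_trunk if trunk else config.driver_fraction
        is_driver = rng.random() < p_driver
        if is_driver:
            gene = f"DRV{int(rng.integers(0, 30)):02d}"
            role = "oncogene" if rng.random() < 0.5 else "TSG"
        else:
            gene = f"GENE{i:04d}"
            role = "passenger"
        if contaminant:
            pop_freq = float(rng.uniform(0.02, 0.2))
            carriers = np.ones(config.n_regions, dtype=bool)
            labels[key] = "germline_contaminant"
        else:
            pop_freq = 0.0
            labels[key] = "trunk" if trunk else "branch"
            for k, rid in enumerate(regions):
                if carriers[k]:
                    true_sets[rid].add(key)
        for k, rid in enumerate(regions):
            if contaminant:
                p_alt = 0.5
            elif carriers[k]:
                p_alt = purities[k] / 2.0
            else:
                p_alt = config.error_rate
            alt_reads = int(rng.binomial(config.tumor_depth, p_alt))
            mut_rows.append(
                {
                    "patient_id": pid,
                    "region_id": rid,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": gene,
                    "variant_class": vclass,
                    "alt_reads": alt_reads,
                    "ref_reads": config.tumor_depth - alt_reads,
                    "pop_freq": pop_freq,
                    "driver_role": role,
                }
            )

    somatic = {k: v for k, v in labels.items() if v in ("trunk", "branch")}
    n_somatic = len(somatic)
    realized_trunk = (
        sum(1 for v in somatic.values() if v == "trunk") / n_somatic
        if n_somatic
        else float("nan")
    )
    true_pairs = [
        jaccard_distance(true_sets[a], true_sets[b])
        for a, b in itertools.combinations(regions, 2)
    ]
    finite_pairs = [v for v in true_pairs if not np.isnan(v)]
    true_mean_jaccard = float(np.mean(finite_pairs)) if finite_pairs else float("nan")

    # --- copy-number segments ---------------------------------------------
    arm_table = cnv_layer.default_arm_table()
    seg_rows: list[dict] = []
    cnv_truth: dict[str, set] = {rid: set() for rid in regions}
    for _, arm_row in arm_table.iterrows():
        arm, chrom = arm_row["arm"], arm_row["chrom"]
        has_event = rng.random() < config.arm_event_rate
        state = direction = None
        carriers = np.zeros(config.n_regions, dtype=bool)
        if has_event:
            state = "amp" if rng.random() < 0.5 else "del"
            direction = "gain" if state == "amp" else "loss"
            carriers = (
                np.ones(config.n_regions, dtype=bool)
                if rng.random() < tf
                else _choose_subset(rng, config.n_regions)
            )
        bounds = np.linspace(
            arm_row["start"], arm_row["end"], config.segments_per_arm + 1, dtype=int
        )
        for k, rid in enumerate(regions):
            if has_event and carriers[k]:
                n_altered = int(rng.integers(7, config.segments_per_arm + 1))
                altered = set(
                    rng.choice(config.segments_per_arm, n_altered, replace=False)
                )
                cnv_truth[rid].add(f"{arm}:{direction}")
            else:
                altered, n_altered = set(), 0
            for s in range(config.segments_per_arm):
                if s in altered:
                    seg_state = state
                elif rng.random() < config.segment_noise_rate:
                    seg_state = "amp" if rng.random() < 0.5 else "del"
                else:
                    seg_state = "neutral"
                seg_rows.append(
                    {
                        "region_id": rid,
                        "chrom": chrom,
                        "start": int(bounds[s]),
                        "end": int(bounds[s + 1]),
                        "state": seg_state,
                        "arm": arm,
                    }
                )

    # --- methylation -------------------------------------------------------
    nw = config.n_windows
    win_chrom = np.array([_CHROMS[w % len(_CHROMS)] for w in range(nw)])
    win_start = np.array([(w // len(_CHROMS)) * 25_000 for w in range(nw)])
    normal_beta = rng.beta(2, 8, nw)
    dmr_flag = rng.random(nw) < config.dmr_fraction
    shift_sign = np.where(rng.random(nw) < 0.5, 1.0, -1.0)
    shifted = np.clip(normal_beta + shift_sign * config.dmr_shift, 0.0, 1.0)
    tumor_beta = np.tile(normal_beta, (config.n_regions, 1))
    dmr_trunk = rng.random(nw) < tf
    for w in np.flatnonzero(dmr_flag):
        carriers = (
            np.ones(config.n_regions, dtype=bool)
            if dmr_trunk[w]
            else _choose_subset(rng, config.n_regions)
        )
        tumor_beta[carriers, w] = shifted[w]
    meth_rows: list[dict] = []
    observed_beta = {}
    for k, rid in enumerate(regions):
        observed = purities[k] * tumor_beta[k] + (1 - purities[k]) * normal_beta
        observed_beta[rid] = observed
        totals = np.maximum(rng.poisson(config.meth_depth, nw), 1)
        meths = rng.binomial(totals, observed)
        for w in range(nw):
            meth_rows.append(
                {
                    "region_id": rid,
                    "chrom": win_chrom[w],
                    "start": int(win_start[w]),
                    "end": int(win_start[w]) + 1000,
                    "methylated_count": int(meths[w]),
                    "total_count": int(totals[w]),
                }
            )
    totals_n = np.maximum(rng.poisson(config.meth_depth, nw), 1)
    meths_n = rng.binomial(totals_n, normal_beta)
    for w in range(nw):
        meth_rows.append(
            {
                "region_id": normal_id,
                "chrom": win_chrom[w],
                "start": int(win_start[w]),
                "end": int(win_start[w]) + 1000,
                "methylated_count": int(meths_n[w]),
                "total_count": int(totals_n[w]),
            }
        )

    # --- expression (noise-free purity-mixed abundances) --------------------
    genes = [f"G{g:04d}" for g in range(config.n_genes)]
    baseline = rng.lognormal(mean=2.3, sigma=1.0, size=config.n_genes)
    de_flag = rng.random(config.n_genes) < config.de_fraction
    de_sign = np.where(rng.random(config.n_genes) < 0.5, 1.0, -1.0)
    fold = np.where(de_flag, 2.0 ** (de_sign * config.de_log2fc), 1.0)
    tumor_expr = np.tile(baseline, (config.n_regions, 1))
    de_trunk = rng.random(config.n_genes) < tf
    for g in np.flatnonzero(de_flag):
        carriers = (
            np.ones(config.n_regions, dtype=bool)
            if de_trunk[g]
            else _choose_subset(rng, config.n_regions)
        )
        tumor_expr[carriers, g] = baseline[g] * fold[g]
    expr_cols = {}
    for k, rid in enumerate(regions):
        expr_cols[rid] = purities[k] * tumor_expr[k] + (1 - purities[k]) * baseline
    expr_cols[normal_id] = baseline
    expression = pd.DataFrame(expr_cols, index=pd.Index(genes, name="gene"))

    tables = {
        "samples": pd.DataFrame(sample_rows),
        "mutations": pd.DataFrame(mut_rows),
        "segments": pd.DataFrame(seg_rows),
        "methylation": pd.DataFrame(meth_rows),
        "expression": expression,
    }
    truth = {
        "patient_id": pid,
        "subtype": subtype,
        "trunk_fraction_configured": tf,
        "trunk_fraction_realized": realized_trunk,
        "mutation_labels": labels,
        "true_region_sets": {r: sorted(s) for r, s in true_sets.items()},
        "true_mean_jaccard": true_mean_jaccard,
        "purities": dict(zip(regions, map(float, purities))),
        "cnv_truth": {r: sorted(s) for r, s in cnv_truth.items()},
        "methylation": {
            "dmr_flag": dmr_flag.tolist(),
            "normal_beta": normal_beta.tolist(),
            "tumor_beta": {rid: tumor_beta[k].tolist() for k, rid in enumerate(regions)},
            "observed_beta": {r: v.tolist() for r, v in observed_beta.items()},
        },
        "expression": {
            "de_flag": de_flag.tolist(),
            "baseline": baseline.tolist(),
        },
    }
    return tables, truth


def simulate_survival_groups(
    n_per_group: int,
    hazard_ratio: float,
    censor_rate: float,
    rng: np.random.Generator,
    scale_months: float = 60.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Two exponential survival groups where the second group's hazard is
    multiplied by ``hazard_ratio``; uniform censoring on a ``censor_rate``
    fraction of subjects.  Returns [(times, events), (times, events)]."""
    out = []
    for hr in (1.0, hazard_ratio):
        t = rng.exponential(scale_months / hr, n_per_group)
        censored = rng.random(n_per_group) < censor_rate
        times = np.where(censored, rng.uniform(0, t), t)
        events = (~censored).astype(int)
        out.append((times, events))
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[CohortBundle, GroundTruth]:
    """Simulate the full cohort: concatenated per-patient tables plus the
    clinical sheet, with survival hazards tied to the cohort-median split
    of each patient's TRUE mean pairwise Jaccard ITH.

    Identical configs (same seed) produce bit-identical bundles; patients
    use independent substreams of the master seed.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients + 1)
    truth = GroundTruth()
    per_layer: dict[str, list[pd.DataFrame]] = {
        k: [] for k in ("samples", "mutations", "segments", "methylation")
    }
    expr_frames: list[pd.DataFrame] = []
    n_expr = (
        config.n_patients
        if config.n_expression_patients is None
        else config.n_expression_patients
    )
    for idx in range(config.n_patients):
        tables, pt_truth = simulate_patient(
            config, idx, np.random.default_rng(streams[idx])
        )
        pid = pt_truth["patient_id"]
        for k in per_layer:
            per_layer[k].append(tables[k])
        if idx < n_expr:
            expr_frames.append(tables["expression"])
        truth.patients[pid] = pt_truth

    surv_rng = np.random.default_rng(streams[-1])
    ith = pd.Series(
        {p: t["true_mean_jaccard"] for p, t in truth.patients.items()}
    ).sort_index()
    median = float(ith.median()) if ith.notna().any() else float("nan")
    # patients at or below the median (or with undefined ITH) are "low"
    groups = {p: ("high" if v > median else "low") for p, v in ith.items()}
    clinical_rows = []
    for pid in sorted(truth.patients):
        pt = truth.patients[pid]
        group = groups[pid]
        hazard_mult = config.hazard_ratio_highITH if group == "high" else 1.0
        row = {"patient_id": pid, "subtype": pt["subtype"]}
        if pt["subtype"] == "L":
            row["purity_class"] = "pure"
        else:
            row["purity_class"] = "mixed" if surv_rng.random() < 2 / 3 else "pure"
        row["stage"] = str(surv_rng.choice(["I", "II", "III"], p=[0.7, 0.15, 0.15]))
        for prefix, scale in (
            ("os", config.os_scale_months),
            ("rfs", config.rfs_scale_months),
        ):
            t = float(surv_rng.exponential(scale / hazard_mult))
            if surv_rng.random() < config.censor_rate:
                row[f"{prefix}_months"] = float(surv_rng.uniform(0, t))
                row[f"{prefix}_event"] = 0
            else:
                row[f"{prefix}_months"] = t
                row[f"{prefix}_event"] = 1
        clinical_rows.append(row)
        truth.patients[pid]["ith_group"] = group
    truth.cohort = {
        "median_true_jaccard": median,
        "ith_groups": groups,
        "config": config.to_dict(),
    }

    expression = pd.concat(expr_frames, axis=1) if expr_frames else pd.DataFrame()
    bundle = CohortBundle(
        samples=pd.concat(per_layer["samples"], ignore_index=True),
        mutations=pd.concat(per_layer["mutations"], ignore_index=True),
        segments=pd.concat(per_layer["segments"], ignore_index=True),
        methylation=pd.concat(per_layer["methylation"], ignore_index=True),
        expression=expression,
        clinical=pd.DataFrame(clinical_rows),
    )
    bundle.validate()
    return bundle, truth
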