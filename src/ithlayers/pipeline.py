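"""End-to-end orchestration: QC → filtering → rescue → trunk/branch → TMB
→ arm-level CNV → purity correction → four-layer ITH → trees and
concordance → cross-layer correlations → driver enrichment → subtype
comparisons → median-split survival, from one manifest to one JSON report
plus per-stage TSVs and Newick trees.

The pipeline itself is deterministic (no random draws); the seed in the
config is recorded in the report so runs are traceable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv_layer, io_formats, methylation_layer, phylo_trees, variant_layer
from .ith_metrics import LAYERS, pairwise_ith
from .stats_survival import spearman, stratified_survival_analysis, wilcoxon_rank_sum

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline inputs and thresholds (defaults follow the documented
    call-level rules)."""

    manifest: str
    out_dir: str
    seed: int = 0
    layers: tuple[str, ...] = LAYERS
    min_qscore: float = 35.0
    max_contamination: float = 0.02
    min_depth: float = 30.0
    snv_min_reads: int = 6
    indel_min_reads: int = 8
    max_pop_freq: float = 0.01
    coverage_mb: float = 39.0
    arm_fraction_by: str = "count"
    tree_window_size: int = 500_000
    median_split_tie: str = "low"

    def __post_init__(self) -> None:
        unknown = set(self.layers) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown layers: {sorted(unknown)}")
        if self.arm_fraction_by not in ("count", "length"):
            raise ValueError("arm_fraction_by must be 'count' or 'length'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "layers" in d:
            d = dict(d, layers=tuple(d["layers"]))
        return cls(**d)


class StageError(RuntimeError):
    """Failure in one pipeline stage, annotated with the stage name."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _aligned_methylation(meth: pd.DataFrame, region_ids: list[str]) -> pd.DataFrame:
    """Window × region beta matrix over the windows covered in every
    requested region (inner alignment)."""
    sub = meth[meth["region_id"].isin(region_ids)].copy()
    sub["beta"] = sub["methylated_count"] / sub["total_count"]
    mat = sub.pivot_table(
        index=["chrom", "start", "end"], columns="region_id", values="beta"
    )
    return mat.dropna()


@_stage("methylation_profiles")
def _methylation_profiles(
    bundle: io_formats.CohortBundle,
    pid: str,
    regions: list[str],
    normal_id: str,
    purities: dict[str, float],
    window_size: int | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray] | None:
    meth = bundle.methylation
    if meth.empty:
        return None
    source = meth[meth["region_id"].isin(regions + [normal_id])]
    if source.empty:
        return None
    if window_size is not None:
        source = methylation_layer.bin_windows(
            source[["region_id", "chrom", "start", "methylated_count", "total_count"]],
            window_size=window_size,
        )
    mat = _aligned_methylation(source, regions + [normal_id])
    if mat.empty or normal_id not in mat.columns:
        return None
    have = [r for r in regions if r in mat.columns]
    if len(have) < 2:
        return None
    normal = mat[normal_id].to_numpy(float)
    corrected = {
        r: methylation_layer.purity_correct(
            mat[r].to_numpy(float), purities[r], normal, layer="methylation"
        )
        for r in have
    }
    return corrected, normal


def _expression_profiles(
    bundle: io_formats.CohortBundle,
    regions: list[str],
    normal_id: str,
    purities: dict[str, float],
) -> tuple[dict[str, np.ndarray], np.ndarray] | None:
    expr = bundle.expression
    if expr.empty or normal_id not in expr.columns:
        return None
    have = [r for r in regions if r in expr.columns]
    if len(have) < 2:
        return None
    normal = expr[normal_id].to_numpy(float)
    corrected = {
        r: methylation_layer.purity_correct(
            expr[r].to_numpy(float), purities[r], normal, layer="expression"
        )
        for r in have
    }
    return corrected, normal


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict and writes report
    JSON, per-stage TSVs and Newick trees under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = io_formats.load_cohort(config.manifest)

    log: list[dict] = []

    def record(stage: str, **counts) -> None:
        log.append({"stage": stage, **counts})

    # --- sample QC ---------------------------------------------------------
    kept, exclusions = variant_layer.qc_filter_samples(
        bundle.samples,
        min_qscore=config.min_qscore,
        max_contamination=config.max_contamination,
        min_depth=config.min_depth,
    )
    record("qc_filter_samples", n_in=len(bundle.samples), n_kept=len(kept))
    kept_regions = set(kept["region_id"])

    # --- variant filtering + rescue (cohort-wide, grouped by patient) ------
    raw = bundle.mutations[bundle.mutations["region_id"].isin(kept_regions)]
    passing = variant_layer.filter_calls(
        raw,
        snv_min_reads=config.snv_min_reads,
        indel_min_reads=config.indel_min_reads,
        max_pop_freq=config.max_pop_freq,
    )
    rescued = variant_layer.rescue_across_regions(passing, raw)
    record(
        "filter_and_rescue",
        n_raw=len(raw),
        n_passing=len(passing),
        n_after_rescue=len(rescued),
    )

    # --- arm-level CNV (cohort-wide) ---------------------------------------
    segments = bundle.segments[bundle.segments["region_id"].isin(kept_regions)]
    arm_calls = cnv_layer.call_arm_level(segments, fraction_by=config.arm_fraction_by)
    events = cnv_layer.arm_events(arm_calls)
    record("call_arm_level", n_segments=len(segments), n_events=len(events))

    # --- per-patient layers ------------------------------------------------
    patients_report: dict[str, dict] = {}
    ith_pair_rows: list[dict] = []
    driver_trunk, driver_branch = {}, {}
    skipped: list[dict] = []
    for pid in bundle.patient_ids:
        regions = [r for r in bundle.tumor_regions(pid) if r in kept_regions]
        normal_id = bundle.normal_region(pid)
        if len(regions) < 2 or normal_id is None or normal_id not in kept_regions:
            skipped.append({"patient_id": pid, "reason": "insufficient regions after QC"})
            continue
        purities = dict(
            zip(kept["region_id"], kept["purity"].astype(float))
        )
        entry: dict = {"n_tumor_regions": len(regions)}

        # mutational layer
        pcalls = rescued[rescued["patient_id"] == pid]
        presence = variant_layer.build_presence(pcalls, regions)
        labels, p_trunk, p_branch = variant_layer.classify_trunk_branch(presence)
        entry["n_variants"] = int(presence.shape[1])
        entry["trunk_proportion"] = p_trunk
        entry["branch_proportion"] = p_branch
        roles = (
            pcalls.assign(key=variant_layer.variant_keys(pcalls))
            .drop_duplicates("key")
            .set_index("key")["driver_role"]
            .to_dict()
            if not pcalls.empty
            else {}
        )
        ft, fb = variant_layer.driver_enrichment(labels, roles)
        entry["driver_fraction_trunk"] = ft
        entry["driver_fraction_branch"] = fb
        driver_trunk[pid], driver_branch[pid] = ft, fb
        tmb = variant_layer.compute_tmb(pcalls, coverage_mb=config.coverage_mb)
        entry["tmb"] = {
            row["region_id"]: {
                "missense_count": int(row["missense_count"]),
                "missense_per_mb": row["missense_per_mb"],
                "exonic_per_mb": row["exonic_per_mb"],
            }
            for _, row in tmb.iterrows()
        }

        mut_sets = {r: set(presence.columns[presence.loc[r] > 0]) for r in regions}
        cnv_mat = cnv_layer.build_cnv_matrix(
            events[events["region_id"].isin(regions)], regions
        )
        cnv_sets = {r: set(cnv_mat.columns[cnv_mat.loc[r] > 0]) for r in regions}

        meth_prof = _methylation_profiles(bundle, pid, regions, normal_id, purities)
        expr_prof = _expression_profiles(bundle, regions, normal_id, purities)

        entry["ith"] = {}
        layer_data = {
            "mutational": mut_sets,
            "cnv": cnv_sets,
            "methylation": meth_prof[0] if meth_prof else None,
            "transcriptional": expr_prof[0] if expr_prof else None,
        }
        for layer in config.layers:
            data = layer_data.get(layer)
            if data is None or len(data) < 2:
                continue
            try:
                result = pairwise_ith(pid, layer, data)
            except ValueError:
                continue
            entry["ith"][layer] = {
                "mean": result.mean_ith,
                "n_pairs": result.n_pairs,
                "pairs": [[a, b, d] for a, b, d in result.pairs],
            }
            ith_pair_rows.extend(result.to_records())

        # trees -------------------------------------------------------------
        entry["trees"] = {}
        tree_by_layer: dict[str, phylo_trees.PhyloTree] = {}
        tree_inputs: dict[str, pd.DataFrame] = {}
        if "mutational" in config.layers and presence.shape[1] > 0:
            rows = presence.copy()
            rows.loc[normal_id] = 0
            tree_inputs["mutational"] = rows
        if "cnv" in config.layers and cnv_mat.shape[1] > 0:
            rows = cnv_mat.copy()
            rows.loc[normal_id] = 0
            tree_inputs["cnv"] = rows
        if "methylation" in config.layers:
            binned = _methylation_profiles(
                bundle, pid, regions, normal_id, purities,
                window_size=config.tree_window_size,
            )
            if binned is not None:
                corrected, normal_vec = binned
                rows = pd.DataFrame(corrected).T
                rows.loc[normal_id] = normal_vec
                tree_inputs["methylation"] = rows
        for layer, rows in tree_inputs.items():
            if rows.shape[0] < 3 or rows.shape[1] == 0:
                continue
            dm = phylo_trees.euclidean_distances(rows)
            tree = phylo_trees.minimum_evolution_tree(dm, root_label=normal_id)
            tree_by_layer[layer] = tree
            newick = io_formats.write_newick(tree)
            entry["trees"][layer] = {
                "newick": newick,
                "total_length": tree.total_length,
                "trunk_length": tree.root_edge_length,
            }
            tree_dir = out_dir / "trees"
            tree_dir.mkdir(exist_ok=True)
            (tree_dir / f"{pid}_{layer}.nwk").write_text(newick + "\n")
        if "mutational" in tree_by_layer and "methylation" in tree_by_layer:
            rf, aligned = phylo_trees.tree_concordance(
                tree_by_layer["mutational"], tree_by_layer["methylation"]
            )
            entry["tree_concordance"] = {"rf_distance": rf, "aligned": aligned}
        patients_report[pid] = entry
    record("per_patient_layers", n_patients=len(patients_report), n_skipped=len(skipped))

    # --- cohort statistics -------------------------------------------------
    pair_df = pd.DataFrame(
        ith_pair_rows,
        columns=["patient_id", "layer", "region_a", "region_b", "distance"],
    )
    subtype_of = (
        bundle.clinical.set_index("patient_id")["subtype"].to_dict()
        if not bundle.clinical.empty
        else {}
    )
    cohort: dict = {"n_patients": len(patients_report)}

    ith_means = pd.DataFrame(
        {
            layer: {
                pid: entry["ith"][layer]["mean"]
                for pid, entry in patients_report.items()
                if layer in entry["ith"]
            }
            for layer in config.layers
        }
    )
    cohort["ith_means"] = {
        layer: {p: v for p, v in ith_means[layer].dropna().items()}
        for layer in ith_means.columns
    }

    # subtype comparison on pairwise values (each dot = one region pair)
    if subtype_of and not pair_df.empty:
        comp = {}
        pair_df = pair_df.assign(subtype=pair_df["patient_id"].map(subtype_of))
        for layer in config.layers:
            sub = pair_df[(pair_df["layer"] == layer) & pair_df["distance"].notna()]
            x = sub.loc[sub["subtype"] == "H", "distance"].to_numpy()
            y = sub.loc[sub["subtype"] == "L", "distance"].to_numpy()
            if x.size and y.size:
                u, p = wilcoxon_rank_sum(x, y)
                comp[layer] = {
                    "U": u,
                    "p": p,
                    "median_H": float(np.median(x)),
                    "median_L": float(np.median(y)),
                }
        cohort["subtype_ith_comparison"] = comp

    # cross-layer correlations on pairwise values, per subtype
    if subtype_of and not pair_df.empty:
        wide = pair_df.pivot_table(
            index=["patient_id", "region_a", "region_b"],
            columns="layer",
            values="distance",
        ).reset_index()
        wide["subtype"] = wide["patient_id"].map(subtype_of)
        corrs: dict = {}
        for subtype, grp in wide.groupby("subtype"):
            sub_corr = {}
            for la, lb in itertools.combinations(
                [l for l in config.layers if l in grp.columns], 2
            ):
                paired = grp[[la, lb]].dropna()
                if len(paired) >= 3:
                    rho, p = spearman(paired[la], paired[lb])
                    sub_corr[f"{la}_vs_{lb}"] = {"rho": rho, "p": p, "n": len(paired)}
            corrs[str(subtype)] = sub_corr
        cohort["ith_correlations"] = corrs

    # driver enrichment: trunk vs branch driver fractions across patients
    dt = pd.Series(driver_trunk, dtype=float)
    db = pd.Series(driver_branch, dtype=float)
    both = pd.concat([dt, db], axis=1, keys=["trunk", "branch"]).dropna()
    if len(both) >= 2:
        u, p = wilcoxon_rank_sum(both["trunk"], both["branch"])
        cohort["driver_enrichment"] = {
            "U": u,
            "p": p,
            "n_patients": len(both),
            "mean_trunk_driver_fraction": float(both["trunk"].mean()),
            "mean_branch_driver_fraction": float(both["branch"].mean()),
        }

    # median-split survival per layer
    if not bundle.clinical.empty and not ith_means.dropna(how="all").empty:
        usable = ith_means.loc[:, ith_means.notna().sum() >= 2]
        if not usable.empty:
            cohort["survival"] = stratified_survival_analysis(usable, bundle.clinical)
    record("cohort_statistics")

    config_record = {
        k: v
        for k, v in asdict(config).items()
        if k not in ("manifest", "out_dir")  # paths are run-local, keep reports diffable
    }
    report = {
        "config": config_record,
        "stage_log": log,
        "qc_exclusions": exclusions.to_dict(orient="records"),
        "skipped_patients": skipped,
        "patients": patients_report,
        "cohort": cohort,
    }
    io_formats.write_report(report, out_dir / "report.json")
    exclusions.to_csv(out_dir / "qc_exclusions.tsv", sep="\t", index=False)
    arm_calls.to_csv(out_dir / "arm_calls.tsv", sep="\t", index=False)
    pair_df.drop(columns=["subtype"], errors="ignore").to_csv(
        out_dir / "ith_pairs.tsv", sep="\t", index=False
    )
    ith_means.rename_axis("patient_id").to_csv(out_dir / "ith_summary.tsv", sep="\t")
    trunk_rows = [
        {
            "patient_id": pid,
            "n_variants": e["n_variants"],
            "trunk_proportion": e["trunk_proportion"],
            "branch_proportion": e["branch_proportion"],
        }
        for pid, e in patients_report.items()
    ]
    pd.DataFrame(trunk_rows).to_csv(out_dir / "trunk_branch.tsv", sep="\t", index=False)
    return report
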