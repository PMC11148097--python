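"""Somatic-variant QC, filtering, cross-region rescue and trunk/branch
classification.

The call-level rules, applied downstream of external variant callers:

* sample QC — drop a region when its library QScore < 35, estimated
  contamination > 0.02, or mean depth < 30× (boundary values pass: the
  exclusion thresholds are strict);
* call filtering — an SNV needs >= 6 supporting (alt-allele) reads, a small
  indel >= 8; any call at > 1% population frequency is treated as likely
  germline and removed;
* cross-region rescue — multi-region sampling of one tumor makes false
  negatives detectable: if a variant passes filtering in one region of a
  patient and has at least one raw supporting read in another region, it is
  called in that region too;
* trunk/branch — after rescue, a variant present in ALL tumor regions of a
  patient is a trunk mutation, otherwise a branch mutation.

Tumor mutation burden is the missense-mutation count, optionally per Mb of
covered exome (39 Mb of whole-exome target by default).  Driver annotation
follows a cancer-gene-census style role table (oncogene / TSG = driver);
signature matching is plain cosine similarity against a reference catalog
with a strict > 0.6 threshold.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "variant_keys",
    "qc_filter_samples",
    "filter_calls",
    "rescue_across_regions",
    "build_presence",
    "classify_trunk_branch",
    "compute_tmb",
    "driver_enrichment",
    "match_signature",
    "mutated_gene_frequencies",
]

DRIVER_ROLES = ("oncogene", "TSG")
MISSENSE = "missense"


def variant_keys(calls: pd.DataFrame) -> pd.Series:
    """Identity key per call: ``chrom:pos:ref:alt`` (gene is annotation
    only)."""
    return (
        calls["chrom"].astype(str)
        + ":"
        + calls["pos"].astype(int).astype(str)
        + ":"
        + calls["ref"].astype(str)
        + ":"
        + calls["alt"].astype(str)
    )


def _is_indel(calls: pd.DataFrame) -> pd.Series:
    return calls["ref"].str.len() != calls["alt"].str.len()


def qc_filter_samples(
    samples: pd.DataFrame,
    min_qscore: float = 35.0,
    max_contamination: float = 0.02,
    min_depth: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-level QC.  Returns (kept samples, exclusion log).

    A sample is kept iff qscore >= min_qscore AND contamination <=
    max_contamination AND mean_depth >= min_depth; each exclusion is logged
    with its reason, and a missing metric excludes with ``missing_metric``.
    """
    exclusions: list[dict] = []
    keep = np.ones(len(samples), dtype=bool)
    for i, (_, row) in enumerate(samples.iterrows()):
        metrics = (row["qscore"], row["contamination"], row["mean_depth"])
        if any(pd.isna(m) for m in metrics):
            reason = "missing_metric"
        elif row["qscore"] < min_qscore:
            reason = f"qscore<{min_qscore}"
        elif row["contamination"] > max_contamination:
            reason = f"contamination>{max_contamination}"
        elif row["mean_depth"] < min_depth:
            reason = f"mean_depth<{min_depth}"
        else:
            continue
        keep[i] = False
        exclusions.append(
            {
                "patient_id": row["patient_id"],
                "region_id": row["region_id"],
                "reason": reason,
            }
        )
    log = pd.DataFrame(exclusions, columns=["patient_id", "region_id", "reason"])
    return samples.loc[keep].reset_index(drop=True), log


def filter_calls(
    calls: pd.DataFrame,
    snv_min_reads: int = 6,
    indel_min_reads: int = 8,
    max_pop_freq: float = 0.01,
) -> pd.DataFrame:
    """Supporting-read and population-frequency filters, order-preserving.

    SNVs need alt_reads >= 6, indels >= 8 ("supporting reads < 6/8" fail),
    and calls exceeding 1% population frequency are removed as putative
    germline.
    """
    if calls.empty:
        return calls.copy()
    if (calls["alt_reads"] < 0).any():
        raise ValueError("negative alt_reads count")
    indel = _is_indel(calls)
    min_reads = np.where(indel, indel_min_reads, snv_min_reads)
    keep = (calls["alt_reads"] >= min_reads) & (calls["pop_freq"] <= max_pop_freq)
    return calls.loc[keep].reset_index(drop=True)


def rescue_across_regions(
    passing: pd.DataFrame, raw: pd.DataFrame
) -> pd.DataFrame:
    """Cross-region rescue of low-frequency calls.

    For every variant that passed filtering in at least one region of a
    patient, add the raw call from every other region of that patient where
    it has >= 1 supporting read.  Output is a superset of ``passing``
    (monotone) and re-running adds nothing (idempotent); a variant passing
    nowhere is never introduced.
    """
    if passing.empty:
        out = passing.copy()
        out["rescued"] = pd.Series(dtype=bool)
        return out
    passing = passing.copy()
    if "rescued" not in passing.columns:
        passing["rescued"] = False
    if raw.empty:
        return passing.reset_index(drop=True)
    pkey = passing["patient_id"].astype(str) + "|" + variant_keys(passing)
    rkey = raw["patient_id"].astype(str) + "|" + variant_keys(raw)
    already = set(pkey + "|" + passing["region_id"].astype(str))
    candidates = raw.loc[
        rkey.isin(set(pkey))
        & (raw["alt_reads"] >= 1)
        & ~(rkey + "|" + raw["region_id"].astype(str)).isin(already)
    ].copy()
    candidates = candidates.drop_duplicates(
        subset=["patient_id", "region_id", "chrom", "pos", "ref", "alt"]
    )
    candidates["rescued"] = True
    out = pd.concat([passing, candidates], ignore_index=True)
    return out


def build_presence(
    calls: pd.DataFrame, tumor_regions: Iterable[str]
) -> pd.DataFrame:
    """Binary region × variant presence matrix for one patient's calls."""
    regions = sorted(set(tumor_regions))
    if calls.empty:
        return pd.DataFrame(index=regions, dtype=int)
    keys = variant_keys(calls)
    mat = (
        pd.crosstab(calls["region_id"], keys)
        .clip(upper=1)
        .reindex(index=regions, fill_value=0)
    )
    mat.index.name = None
    mat.columns.name = None
    return mat.astype(int)


def classify_trunk_branch(
    presence: pd.DataFrame,
) -> tuple[pd.Series, float | None, float | None]:
    """Label each variant trunk (present in every tumor region) or branch.

    Returns (labels, trunk_proportion, branch_proportion); with zero
    variants the proportions are undefined and reported as None.
    """
    if presence.shape[0] < 2:
        raise ValueError("trunk/branch classification needs >= 2 tumor regions")
    if presence.shape[1] == 0:
        return pd.Series(dtype=object), None, None
    trunk = presence.sum(axis=0) == presence.shape[0]
    labels = pd.Series(
        np.where(trunk, "trunk", "branch"), index=presence.columns
    )
    p_trunk = float(trunk.mean())
    return labels, p_trunk, 1.0 - p_trunk


def compute_tmb(
    calls: pd.DataFrame, coverage_mb: float = 39.0
) -> pd.DataFrame:
    """Per-region tumor mutation burden.

    TMB is the number of missense mutations; both the missense and the
    total exonic call count are also reported per megabase of covered
    exome.
    """
    if coverage_mb <= 0:
        raise ValueError("coverage_mb must be positive")
    if calls.empty:
        return pd.DataFrame(
            columns=["region_id", "missense_count", "missense_per_mb", "exonic_per_mb"]
        )
    grouped = calls.groupby("region_id", sort=True)
    rows = []
    for region, grp in grouped:
        n_missense = int((grp["variant_class"] == MISSENSE).sum())
        rows.append(
            {
                "region_id": region,
                "missense_count": n_missense,
                "missense_per_mb": n_missense / coverage_mb,
                "exonic_per_mb": len(grp) / coverage_mb,
            }
        )
    return pd.DataFrame(rows)


def driver_enrichment(
    labels: pd.Series, roles: Mapping[str, str]
) -> tuple[float, float]:
    """Driver (oncogene / tumor-suppressor) fraction among trunk and among
    branch mutations of one patient.

    ``labels`` maps variant key -> trunk|branch, ``roles`` maps variant key
    -> driver_role.  A patient with no trunk (or no branch) mutations gets
    NaN for that fraction, to be excluded pairwise from cohort tests.
    """
    is_driver = pd.Series(
        {k: roles.get(k, "unknown") in DRIVER_ROLES for k in labels.index}
    )
    out = []
    for side in ("trunk", "branch"):
        mask = labels == side
        out.append(float(is_driver[mask].mean()) if mask.any() else float("nan"))
    return out[0], out[1]


def match_signature(
    candidate: np.ndarray, catalog: pd.DataFrame, threshold: float = 0.6
) -> list[tuple[str, float]]:
    """Cosine-similarity matching of a mutational-spectrum vector against a
    reference signature catalog (features × signatures).

    Returns (signature, similarity) pairs with similarity strictly above
    ``threshold``, sorted by descending similarity.
    """
    v = np.asarray(candidate, dtype=float)
    if v.ndim != 1 or v.shape[0] != catalog.shape[0]:
        raise ValueError("candidate length does not match catalog rows")
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("zero-norm candidate vector")
    sims = []
    for name in catalog.columns:
        ref = catalog[name].to_numpy(dtype=float)
        nr = np.linalg.norm(ref)
        if nr == 0:
            raise ValueError(f"zero-norm reference signature {name!r}")
        sims.append((str(name), float(np.dot(v, ref) / (nv * nr))))
    matched = [(n, s) for n, s in sims if s > threshold]
    return sorted(matched, key=lambda t: (-t[1], t[0]))


def mutated_gene_frequencies(
    calls: pd.DataFrame, patient_ids: Iterable[str]
) -> pd.Series:
    """Per-gene fraction of patients carrying >= 1 mutation in the gene
    (alteration frequencies are computed per patient, not per region)."""
    patients = sorted(set(patient_ids))
    if not patients:
        raise ValueError("empty patient list")
    if calls.empty:
        return pd.Series(dtype=float)
    per_gene = calls.groupby("gene")["patient_id"].nunique()
    return (per_gene / len(patients)).sort_index()
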