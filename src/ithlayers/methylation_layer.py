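"""Window-level methylation, tumor-purity deconvolution, and a simplified
differential-methylation caller.

A bulk tumor region is a mixture of tumor cells (fraction = purity ``p``)
and normal cells, so an observed methylation beta value or expression
abundance is modelled as

    observed = p * tumor + (1 - p) * normal.

Inverting this two-component linear model against the matched normal
profile gives the purity-corrected tumor signal
``(observed - (1-p) * normal) / p``, clamped to [0, 1] for beta values and
to [0, inf) for expression.  Both the Jensen–Shannon ITH metrics and the
phyloepigenetic trees consume these corrected profiles.

Differentially methylated regions (DMRs) between tumor and normal are
called per window on pooled methylated/unmethylated counts with a 2×2
exact test, Benjamini–Hochberg FDR control at q < 0.05, and a minimum
absolute beta difference of 0.2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bin_windows",
    "purity_correct",
    "call_dmr_simple",
]


def bin_windows(
    cpg_records: pd.DataFrame,
    window_size: int,
    step: int | None = None,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Aggregate per-CpG (or finer-window) counts into fixed windows.

    Windows are 0-based half-open ``[k*step, k*step + window_size)`` per
    (region, chrom); a record at position ``start`` contributes its counts
    to every window covering that position (with ``step == window_size``
    the tiling is disjoint and counts are conserved).  Windows whose total
    count is below ``min_coverage`` are dropped, as are empty windows.
    Output columns: region_id, chrom, start, end, methylated_count,
    total_count, beta.
    """
    if window_size <= 0 or (step is not None and step <= 0):
        raise ValueError("window_size and step must be positive")
    step = window_size if step is None else step
    if cpg_records.empty:
        return pd.DataFrame(
            columns=[
                "region_id",
                "chrom",
                "start",
                "end",
                "methylated_count",
                "total_count",
                "beta",
            ]
        )
    rows = []
    for (region, chrom), grp in cpg_records.groupby(["region_id", "chrom"], sort=True):
        pos = grp["start"].to_numpy(int)
        meth = grp["methylated_count"].to_numpy(int)
        tot = grp["total_count"].to_numpy(int)
        first = np.maximum(0, (pos - window_size) // step + 1)
        last = pos // step
        acc: dict[int, list[int]] = {}
        for p0, f, l, m, t in zip(pos, first, last, meth, tot):
            for k in range(f, l + 1):
                if k * step <= p0 < k * step + window_size:
                    cell = acc.setdefault(k, [0, 0])
                    cell[0] += m
                    cell[1] += t
        for k in sorted(acc):
            m, t = acc[k]
            if t < max(min_coverage, 1):
                continue
            rows.append(
                {
                    "region_id": region,
                    "chrom": chrom,
                    "start": k * step,
                    "end": k * step + window_size,
                    "methylated_count": m,
                    "total_count": t,
                    "beta": m / t,
                }
            )
    return pd.DataFrame(rows)


def purity_correct(
    observed: np.ndarray | pd.Series,
    purity: float,
    normal_reference: np.ndarray | pd.Series,
    layer: str = "methylation",
) -> np.ndarray:
    """Invert the two-component purity mixture against the matched normal.

    ``corrected = (observed - (1 - purity) * normal) / purity`` with a
    floor of 0 for both layers and a cap of 1 for methylation beta values
    (expression abundances are uncapped).  purity = 1 is the identity.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if layer not in ("methylation", "expression"):
        raise ValueError(f"unknown layer {layer!r}")
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(normal_reference, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("observed and normal profiles are misaligned")
    corrected = (obs - (1.0 - purity) * ref) / purity
    corrected = np.maximum(corrected, 0.0)
    if layer == "methylation":
        corrected = np.minimum(corrected, 1.0)
    return corrected


def call_dmr_simple(
    tumor_windows: pd.DataFrame,
    normal_windows: pd.DataFrame,
    min_diff: float = 0.2,
    fdr: float = 0.05,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Window-level differential methylation between tumor and normal.

    Counts are pooled per window (chrom, start, end) across the samples of
    each group; each window gets a two-sided Fisher exact test on the
    pooled 2×2 methylated/unmethylated table and a Benjamini–Hochberg
    q-value.  A window is a DMR iff |delta_beta| >= ``min_diff`` AND
    q < ``fdr``; direction is hyper (tumor above normal) or hypo.  Windows
    with pooled coverage below ``min_coverage`` in either group are
    excluded before testing.
    """
    key = ["chrom", "start", "end"]

    def pooled(df: pd.DataFrame) -> pd.DataFrame:
        return df.groupby(key, sort=True)[["methylated_count", "total_count"]].sum()

    t = pooled(tumor_windows)
    n = pooled(normal_windows)
    merged = t.join(n, how="inner", lsuffix="_t", rsuffix="_n")
    merged = merged[
        (merged["total_count_t"] >= min_coverage)
        & (merged["total_count_n"] >= min_coverage)
    ]
    if merged.empty:
        return pd.DataFrame(
            columns=key + ["delta_beta", "p", "q", "direction", "is_dmr"]
        )
    beta_t = merged["methylated_count_t"] / merged["total_count_t"]
    beta_n = merged["methylated_count_n"] / merged["total_count_n"]
    delta = beta_t - beta_n
    pvals = np.empty(len(merged))
    for i, (_, row) in enumerate(merged.iterrows()):
        table = [
            [row["methylated_count_t"], row["total_count_t"] - row["methylated_count_t"]],
            [row["methylated_count_n"], row["total_count_n"] - row["methylated_count_n"]],
        ]
        pvals[i] = fisher_exact(table, alternative="two-sided")[1]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = merged.reset_index()[key].copy()
    out["delta_beta"] = delta.to_numpy()
    out["p"] = pvals
    out["q"] = qvals
    out["direction"] = np.where(delta.to_numpy() > 0, "hyper", "hypo")
    out["is_dmr"] = (np.abs(out["delta_beta"]) >= min_diff) & (out["q"] < fdr)
    return out
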