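"""Cohort-level statistics applied to ITH outputs: rank tests, Spearman
correlation, Kaplan–Meier estimation and log-rank comparison of
median-split groups.

All tests are two-sided at alpha = 0.05.  The Wilcoxon rank-sum test is
evaluated by exact enumeration when the combined sample size is at most 12
and there are no ties (cheap and exact at this cohort's scale), otherwise
by the tie-corrected, continuity-corrected normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .ith_metrics import median_split

__all__ = [
    "SurvivalCurve",
    "wilcoxon_rank_sum",
    "spearman",
    "fisher_exact_2x2",
    "km_estimate",
    "logrank_test",
    "stratified_survival_analysis",
]

EXACT_WILCOXON_MAX_N = 12


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Returns (U statistic of the first sample, two-sided p).
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xa, ya])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= EXACT_WILCOXON_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Returns (rho, p); with zero rank variance in either variable rho is
    undefined and both values are NaN.
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("spearman needs >= 3 paired observations")
    if len(np.unique(xa)) == 1 or len(np.unique(ya)) == 1:
        return float("nan"), float("nan")
    res = sps.spearmanr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2×2 contingency table; returns
    (odds ratio, p).  Utility for cohort-vs-comparator frequency contrasts."""
    odds, p = sps.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")
    return float(odds), float(p)


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier product-limit estimate."""

    times: np.ndarray  # distinct observed event times
    at_risk: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    median: float  # months, inf = not reached

    @property
    def median_label(self) -> str:
        return "NR" if math.isinf(self.median) else f"{self.median:g}"


def km_estimate(
    times: Sequence[float], events: Sequence[int]
) -> SurvivalCurve:
    """Kaplan–Meier estimate of the survival function.

    ``events`` uses 1 for an observed event (death / recurrence) and 0 for
    censoring.  The median is the first time at which S(t) <= 0.5, or
    infinity ("not reached") for e.g. fully censored data.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0 or t.size != e.size:
        raise ValueError("times and events must be non-empty and aligned")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    event_times = np.asarray(kmf.event_table.index[kmf.event_table["observed"] > 0], float)
    surv = np.asarray(
        [float(kmf.survival_function_at_times(tt).iloc[0]) for tt in event_times]
    )
    at_risk = np.asarray(
        kmf.event_table.loc[event_times, "at_risk"], dtype=float
    ) if event_times.size else np.array([])
    median = float(kmf.median_survival_time_)
    return SurvivalCurve(times=event_times, at_risk=at_risk, survival=surv, median=median)


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[int]]]
) -> tuple[float, int, float]:
    """Log-rank comparison of two or more survival groups.

    Returns (chi-square, degrees of freedom, p).  Requires every group to
    be non-empty and at least one event overall.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    times, events, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, float)
        e = np.asarray(e, int)
        if t.size == 0:
            raise ValueError(f"group {gi} has zero subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, gi))
    all_t = np.concatenate(times)
    all_e = np.concatenate(events)
    all_g = np.concatenate(labels)
    if all_e.sum() == 0:
        raise ValueError("log-rank test needs >= 1 event overall")
    res = multivariate_logrank_test(all_t, all_g, all_e)
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)


def stratified_survival_analysis(
    ith_means: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoints: Mapping[str, tuple[str, str]] | None = None,
) -> dict:
    """Median-split survival stratification per ITH layer.

    ``ith_means`` is patient × layer mean ITH; ``clinical`` carries
    os_months/os_event and rfs_months/rfs_event per patient.  Each layer's
    patients are split at the cohort median, and Kaplan–Meier curves plus a
    log-rank test are computed per endpoint.  Layers whose values are all
    missing, or whose split is degenerate, are reported as not evaluable.
    """
    if endpoints is None:
        endpoints = {"os": ("os_months", "os_event"), "rfs": ("rfs_months", "rfs_event")}
    clin = clinical.set_index("patient_id")
    out: dict = {}
    for layer in ith_means.columns:
        values = ith_means[layer].dropna()
        if len(values) < 2:
            out[layer] = {"evaluable": False, "reason": "insufficient non-missing ITH"}
            continue
        groups = median_split(values)
        entry: dict = {
            "evaluable": True,
            "groups": {p: g for p, g in groups.sort_index().items()},
            "endpoints": {},
        }
        if groups.nunique() < 2:
            entry["evaluable"] = False
            entry["reason"] = "degenerate median split (one group empty)"
            out[layer] = entry
            continue
        for name, (time_col, event_col) in endpoints.items():
            by_group = []
            medians = {}
            for g in ("high", "low"):
                pats = groups.index[groups == g]
                t = clin.loc[pats, time_col].to_numpy(float)
                e = clin.loc[pats, event_col].to_numpy(int)
                by_group.append((t, e))
                medians[g] = km_estimate(t, e).median_label
            try:
                chi2, df, p = logrank_test(by_group)
            except ValueError as exc:
                entry["endpoints"][name] = {"evaluable": False, "reason": str(exc)}
                continue
            entry["endpoints"][name] = {
                "evaluable": True,
                "chi_square": chi2,
                "df": df,
                "p": p,
                "median_high": medians["high"],
                "median_low": medians["low"],
                "n_high": int((groups == "high").sum()),
                "n_low": int((groups == "low").sum()),
            }
        out[layer] = entry
    if not out:
        raise ValueError("no ITH layers provided")
    return out
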