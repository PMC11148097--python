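"""Intratumor-heterogeneity (ITH) metrics.

Two distances quantify how dissimilar spatially separated regions of one
tumor are, one per data modality:

* **Jaccard distance** on binary alteration sets (somatic mutations or CNV
  events): ``d_J(V_i, V_j) = 1 - |V_i ∩ V_j| / |V_i ∪ V_j|``.  0 means the
  two regions share every alteration (lowest ITH), 1 means they share none
  (highest ITH).
* **Jensen–Shannon distance** on probability distributions derived from
  purity-corrected methylation or expression profiles:
  ``JSD(P1, P2) = sqrt( [D_KL(P1‖R) + D_KL(P2‖R)] / 2 )`` with
  ``R = (P1 + P2)/2`` and base-2 logarithms, so the distance lies in
  [0, 1]; 0 iff the distributions are identical, 1 iff their supports are
  disjoint.

Per patient, every unordered pair of tumor regions gets a distance and the
arithmetic mean over pairs is the patient's layer-level ITH score.  Cohorts
are then stratified by the median of these per-patient means.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("mutational", "cnv", "methylation", "transcriptional")
_SET_LAYERS = ("mutational", "cnv")
_PROFILE_LAYERS = ("methylation", "transcriptional")

__all__ = [
    "LAYERS",
    "ITHResult",
    "jaccard_distance",
    "to_probability",
    "jensen_shannon_distance",
    "pairwise_ith",
    "median_split",
]


@dataclass(frozen=True)
class ITHResult:
    """Pairwise and mean ITH of one patient for one molecular layer."""

    patient_id: str
    layer: str
    pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def mean_ith(self) -> float:
        """Arithmetic mean of pair distances; NaN pairs (undefined Jaccard on
        two empty sets) are excluded, and all-NaN yields NaN."""
        vals = [d for _, _, d in self.pairs if not math.isnan(d)]
        return float(np.mean(vals)) if vals else float("nan")

    def to_records(self) -> list[dict]:
        return [
            {
                "patient_id": self.patient_id,
                "layer": self.layer,
                "region_a": a,
                "region_b": b,
                "distance": d,
            }
            for a, b, d in self.pairs
        ]


def jaccard_distance(v_i: Iterable, v_j: Iterable) -> float:
    """Jaccard distance ``1 - |V_i ∩ V_j| / |V_i ∪ V_j|`` between two
    alteration sets.

    Returns NaN (undefined, reported missing) when both sets are empty.
    """
    a, b = set(v_i), set(v_j)
    union = a | b
    if not union:
        return float("nan")
    return 1.0 - len(a & b) / len(union)


def to_probability(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Sum-normalize a non-negative profile vector into a probability
    distribution.  No pseudocount is added: the JSD below never divides by a
    zero mixture component where the numerator is positive."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("profile must be one-dimensional")
    if not np.all(np.isfinite(v)):
        raise ValueError("profile contains non-finite values")
    if np.any(v < 0):
        raise ValueError("profile contains negative values")
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return v / total


def _kl_base2(p: np.ndarray, q: np.ndarray) -> float:
    # sum_i p_i * log2(p_i / q_i), with the 0*log(0/x) = 0 convention
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def jensen_shannon_distance(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Jensen–Shannon distance between two aligned probability distributions.

    Base-2 logarithms bound the result to [0, 1].  The mixture
    ``R = (P1+P2)/2`` dominates each argument wherever it is positive, so the
    divergence is always finite.
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"misaligned features: {a.shape} vs {b.shape}")
    for name, v in (("P1", a), ("P2", b)):
        if np.any(v < 0) or not math.isclose(v.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"{name} is not a probability distribution")
    r = (a + b) / 2.0
    jsd_sq = 0.5 * (_kl_base2(a, r) + _kl_base2(b, r))
    # numerical noise can push the square a hair below zero for P1 == P2
    return math.sqrt(max(jsd_sq, 0.0))


def pairwise_ith(
    patient_id: str,
    layer: str,
    data: Mapping[str, Iterable] | Mapping[str, np.ndarray],
) -> ITHResult:
    """All pairwise region distances for one patient and one layer.

    ``data`` maps tumor region id to either an alteration set (mutational /
    cnv layers, Jaccard distance) or an aligned non-negative profile vector
    (methylation / transcriptional layers, Jensen–Shannon distance on
    sum-normalized profiles).
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    regions = sorted(data)
    if len(regions) < 2:
        raise ValueError(f"insufficient regions for {patient_id}/{layer}: need >= 2")
    if layer in _PROFILE_LAYERS:
        probs = {r: to_probability(data[r]) for r in regions}
        lengths = {p.shape[0] for p in probs.values()}
        if len(lengths) > 1:
            raise ValueError("profiles have inconsistent feature counts")
    pairs: list[tuple[str, str, float]] = []
    for a, b in itertools.combinations(regions, 2):
        if layer in _SET_LAYERS:
            d = jaccard_distance(data[a], data[b])
        else:
            d = jensen_shannon_distance(probs[a], probs[b])
        pairs.append((a, b, d))
    return ITHResult(patient_id=patient_id, layer=layer, pairs=pairs)


def median_split(
    values: Mapping[str, float] | pd.Series, tie: str = "low"
) -> pd.Series:
    """Assign each patient to the "high" or "low" ITH group by the cohort
    median of per-patient mean ITH.

    Values strictly above the median are "high"; values at or below it are
    "low" (the tie rule is configurable but must be fixed for determinism).
    Missing values stay unassigned (dropped from the output).
    """
    if tie not in ("low", "high"):
        raise ValueError("tie must be 'low' or 'high'")
    s = pd.Series(values, dtype=float).dropna()
    if len(s) < 2:
        raise ValueError("median split needs >= 2 non-missing values")
    med = float(s.median())
    if tie == "low":
        groups = np.where(s > med, "high", "low")
    else:
        groups = np.where(s >= med, "high", "low")
    return pd.Series(groups, index=s.index, name="ith_group")
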