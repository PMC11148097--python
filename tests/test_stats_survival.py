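"""Rank tests, Spearman correlation, Kaplan–Meier and log-rank."""

import numpy as np
import pytest

from ithlayers.stats_survival import (
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    spearman,
    stratified_survival_analysis,
    wilcoxon_rank_sum,
)
import pandas as pd


class TestWilcoxon:
    def test_identical_samples(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_separated_samples(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)  # 2/20 orderings as extreme

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_agrees_with_normal_approximation(self, rng):
        """For n around the exact/approximate switchover the two modes give
        p-values within 0.02 on continuous data."""
        from scipy.stats import mannwhitneyu

        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(0.5, 1, size=6)
            p_exact = mannwhitneyu(x, y, method="exact").pvalue
            p_asym = mannwhitneyu(x, y, method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.02
            assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(p_exact)


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman(x, [2.0, 4.0, 8.0, 16.0])[0] == pytest.approx(1.0)
        assert spearman(x, [5.0, 4.0, 2.0, 1.0])[0] == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2)=4
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_degenerate_input(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [1.0, 2.0])


def _km_oracle(times, events):
    """Brute-force product-limit: S(t) = prod over event times <= t of
    (1 - d_i / n_i)."""
    order = np.argsort(times, kind="stable")
    t, e = np.asarray(times)[order], np.asarray(events)[order]
    surv = {}
    s = 1.0
    for tt in sorted(set(t[e == 1])):
        n_at_risk = np.sum(t >= tt)
        d = np.sum((t == tt) & (e == 1))
        s *= 1.0 - d / n_at_risk
        surv[tt] = s
    return surv


class TestKaplanMeier:
    def test_no_censoring_steps(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert curve.median == pytest.approx(2.0)

    def test_all_censored(self):
        curve = km_estimate([5, 6, 7], [0, 0, 0])
        assert curve.survival.size == 0
        assert np.isinf(curve.median) and curve.median_label == "NR"

    def test_with_censoring_matches_hand_product_limit(self):
        curve = km_estimate([6, 10, 15], [1, 0, 1])
        oracle = _km_oracle([6, 10, 15], [1, 0, 1])
        assert oracle[6] == pytest.approx(2 / 3)
        assert oracle[15] == pytest.approx(0.0)
        np.testing.assert_allclose(curve.survival, [oracle[6], oracle[15]], atol=1e-12)

    def test_matches_oracle_on_random_data(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 15))
            times = np.round(rng.exponential(10, n), 1)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                continue
            curve = km_estimate(times, events)
            oracle = _km_oracle(times, events)
            for tt, s in zip(curve.times, curve.survival):
                assert s == pytest.approx(oracle[tt], abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0], [1])


class TestLogrank:
    def test_identical_groups(self):
        g = ([1.0, 2.0, 3.0], [1, 1, 1])
        chi2, df, p = logrank_test([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 1 and p == pytest.approx(1.0, abs=1e-6)

    def test_clear_separation(self):
        chi2, _, p = logrank_test(
            [([1.0, 2.0, 3.0], [1, 1, 1]), ([10.0, 10.0, 10.0], [0, 0, 0])]
        )
        assert chi2 > 0 and p < 0.05

    def test_label_swap_invariance(self):
        a = ([1.0, 4.0, 6.0], [1, 0, 1])
        b = ([2.0, 8.0, 9.0], [1, 1, 0])
        assert logrank_test([a, b])[0] == pytest.approx(logrank_test([b, a])[0])

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            logrank_test([([1.0], [1]), ([], [])])
        with pytest.raises(ValueError):
            logrank_test([([1.0], [0]), ([2.0], [0])])  # zero events


def test_fisher_exact_utility():
    odds, p = fisher_exact_2x2([[2, 18], [160, 142]])
    assert p < 0.001 and odds < 1


def test_stratified_survival_analysis_skips_missing_layers():
    ith = pd.DataFrame(
        {
            "mutational": {"P1": 0.1, "P2": 0.2, "P3": 0.6, "P4": 0.7},
            "methylation": {"P1": np.nan, "P2": np.nan, "P3": np.nan, "P4": np.nan},
        }
    )
    clinical = pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3", "P4"],
            "subtype": ["H", "H", "L", "L"],
            "purity_class": ["pure"] * 4,
            "stage": ["I"] * 4,
            "os_months": [10.0, 20.0, 40.0, 50.0],
            "os_event": [1, 1, 1, 0],
            "rfs_months": [8.0, 15.0, 30.0, 45.0],
            "rfs_event": [1, 1, 0, 0],
        }
    )
    out = stratified_survival_analysis(ith, clinical)
    assert out["mutational"]["evaluable"]
    assert set(out["mutational"]["endpoints"]) == {"os", "rfs"}
    assert not out["methylation"]["evaluable"]
    assert out["mutational"]["groups"]["P4"] == "high"
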