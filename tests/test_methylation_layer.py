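"""Window binning, purity deconvolution and the simplified DMR caller."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from ithlayers import SimulationConfig, methylation_layer as ml, simulate_cohort


def _cpgs(rows):
    return pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "methylated_count", "total_count"]
    )


class TestBinWindows:
    def test_single_cpg_beta(self):
        out = ml.bin_windows(_cpgs([["R1", "chr1", 50, 3, 10]]), window_size=100)
        assert len(out) == 1
        assert out.iloc[0]["beta"] == pytest.approx(0.3)
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (0, 100)

    def test_pooled_counts(self):
        out = ml.bin_windows(
            _cpgs([["R1", "chr1", 10, 2, 10], ["R1", "chr1", 90, 4, 10]]),
            window_size=100,
        )
        assert len(out) == 1
        assert out.iloc[0]["beta"] == pytest.approx(6 / 20)

    def test_empty_windows_absent(self):
        out = ml.bin_windows(_cpgs([["R1", "chr1", 250, 1, 4]]), window_size=100)
        assert out["start"].tolist() == [200]  # only the covered window

    def test_count_conservation(self, rng):
        pos = rng.integers(0, 5000, 200)
        records = _cpgs(
            [["R1", "chr1", int(p), int(m), int(m) + 5]
             for p, m in zip(pos, rng.integers(0, 6, 200))]
        )
        out = ml.bin_windows(records, window_size=100)
        assert out["total_count"].sum() == records["total_count"].sum()
        assert out["methylated_count"].sum() == records["methylated_count"].sum()


class TestPurityCorrect:
    def test_identity_at_full_purity(self):
        obs = np.array([0.1, 0.5, 0.9])
        np.testing.assert_allclose(ml.purity_correct(obs, 1.0, np.zeros(3)), obs)

    def test_worked_example(self):
        out = ml.purity_correct(np.array([0.6]), 0.8, np.array([0.2]))
        assert out[0] == pytest.approx((0.6 - 0.2 * 0.2) / 0.8)  # = 0.7

    def test_clamping(self):
        out = ml.purity_correct(np.array([0.1]), 0.5, np.array([0.5]))
        assert out[0] == 0.0  # raw -0.3 clamped
        capped = ml.purity_correct(np.array([1.0]), 0.5, np.array([0.0]))
        assert capped[0] == 1.0  # beta cap
        expr = ml.purity_correct(
            np.array([100.0]), 0.5, np.array([0.0]), layer="expression"
        )
        assert expr[0] == pytest.approx(200.0)  # expression is uncapped

    def test_invalid_purity(self):
        with pytest.raises(ValueError):
            ml.purity_correct(np.array([0.5]), 0.0, np.array([0.5]))

    def test_exact_inverse_of_simulator_mixing(self):
        """On noise-free mixtures the correction recovers the true tumor
        beta to machine precision (no clamping engaged)."""
        cfg = SimulationConfig(
            n_patients_H=1, n_patients_L=0, n_mutations_mean=5,
            n_windows=50, n_genes=5, seed=5,
        )
        _, truth = simulate_cohort(cfg)
        pt = truth.patients["P01"]
        normal = np.array(pt["methylation"]["normal_beta"])
        for rid, observed in pt["methylation"]["observed_beta"].items():
            corrected = ml.purity_correct(
                np.array(observed), pt["purities"][rid], normal
            )
            np.testing.assert_allclose(
                corrected, np.array(pt["methylation"]["tumor_beta"][rid]), atol=1e-12
            )

    def test_correction_beats_no_correction(self):
        """Corrected betas are closer to the true tumor betas than the raw
        purity-mixed observations (mean absolute error)."""
        cfg = SimulationConfig(
            n_patients_H=2, n_patients_L=0, n_mutations_mean=5,
            n_windows=200, dmr_fraction=0.3, n_genes=5, seed=6,
        )
        _, truth = simulate_cohort(cfg)
        for pt in truth.patients.values():
            normal = np.array(pt["methylation"]["normal_beta"])
            for rid, observed in pt["methylation"]["observed_beta"].items():
                obs = np.array(observed)
                true = np.array(pt["methylation"]["tumor_beta"][rid])
                corrected = ml.purity_correct(obs, pt["purities"][rid], normal)
                assert np.abs(corrected - true).mean() <= np.abs(obs - true).mean()


def _windows(region, betas, depth=100):
    return pd.DataFrame(
        {
            "region_id": region,
            "chrom": "chr1",
            "start": np.arange(len(betas)) * 100,
            "end": (np.arange(len(betas)) + 1) * 100,
            "methylated_count": (np.asarray(betas) * depth).astype(int),
            "total_count": depth,
        }
    )


class TestDMRCaller:
    def test_identical_counts_no_dmrs(self):
        t = _windows("T1", [0.2, 0.5, 0.8])
        n = _windows("N1", [0.2, 0.5, 0.8])
        out = ml.call_dmr_simple(t, n)
        assert not out["is_dmr"].any()

    def test_small_delta_fails_min_diff_despite_significance(self):
        t = _windows("T1", [0.39], depth=10_000)
        n = _windows("N1", [0.20], depth=10_000)
        out = ml.call_dmr_simple(t, n)
        assert out.iloc[0]["q"] < 0.001 and not out.iloc[0]["is_dmr"]

    def test_strong_hypermethylation_called(self):
        t = _windows("T1", [0.9])
        n = _windows("N1", [0.1])
        out = ml.call_dmr_simple(t, n)
        row = out.iloc[0]
        assert row["is_dmr"] and row["direction"] == "hyper"
        # oracle: the exact test on the pooled 2x2 table
        p_oracle = fisher_exact([[90, 10], [10, 90]])[1]
        assert row["p"] == pytest.approx(p_oracle)
        assert p_oracle < 1e-6

    def test_hypomethylation_direction(self):
        out = ml.call_dmr_simple(_windows("T1", [0.1]), _windows("N1", [0.9]))
        assert out.iloc[0]["direction"] == "hypo"

    def test_low_coverage_windows_dropped(self):
        t = _windows("T1", [0.9], depth=3)
        n = _windows("N1", [0.1], depth=3)
        assert ml.call_dmr_simple(t, n).empty
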