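"""Sample QC, call filtering, cross-region rescue, trunk/branch labels,
TMB, driver enrichment and signature matching."""

import numpy as np
import pandas as pd
import pytest

from ithlayers import SimulationConfig, simulate_cohort, variant_layer as vl


def _samples(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "region_id",
            "tissue",
            "purity",
            "mean_depth",
            "qscore",
            "contamination",
        ],
    )


def _calls(rows):
    cols = [
        "patient_id",
        "region_id",
        "chrom",
        "pos",
        "ref",
        "alt",
        "gene",
        "variant_class",
        "alt_reads",
        "ref_reads",
        "pop_freq",
        "driver_role",
    ]
    return pd.DataFrame(rows, columns=cols)


def _call(region, alt_reads, ref="C", alt="T", pos=100, pop_freq=0.0, **kw):
    base = {
        "patient_id": "P1",
        "region_id": region,
        "chrom": "chr1",
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gene": kw.get("gene", "G1"),
        "variant_class": kw.get("variant_class", "missense"),
        "alt_reads": alt_reads,
        "ref_reads": 100 - alt_reads,
        "pop_freq": pop_freq,
        "driver_role": kw.get("driver_role", "passenger"),
    }
    return base


class TestSampleQC:
    def test_boundary_values_pass(self):
        # thresholds are strict exclusions: 35/0.02/30 exactly are kept
        samples = _samples(
            [["P1", "R1", "tumor", 0.5, 30.0, 35.0, 0.02]]
        )
        kept, log = vl.qc_filter_samples(samples)
        assert len(kept) == 1 and log.empty

    @pytest.mark.parametrize(
        "qscore, contamination, depth, reason_part",
        [
            (34.9, 0.01, 100, "qscore"),
            (50.0, 0.021, 100, "contamination"),
            (50.0, 0.01, 29.9, "mean_depth"),
            (np.nan, 0.01, 100, "missing_metric"),
        ],
    )
    def test_exclusions_logged(self, qscore, contamination, depth, reason_part):
        samples = _samples([["P1", "R1", "tumor", 0.5, depth, qscore, contamination]])
        kept, log = vl.qc_filter_samples(samples)
        assert kept.empty
        assert len(log) == 1 and reason_part in log.iloc[0]["reason"]

    def test_empty_input(self):
        kept, log = vl.qc_filter_samples(_samples([]))
        assert kept.empty and log.empty


class TestFilterCalls:
    def test_snv_and_indel_read_thresholds(self):
        calls = _calls(
            [
                _call("R1", 6, pos=1),
                _call("R1", 5, pos=2),
                _call("R1", 8, ref="AC", alt="A", pos=3),
                _call("R1", 7, ref="AC", alt="A", pos=4),
            ]
        )
        out = vl.filter_calls(calls)
        assert out["pos"].tolist() == [1, 3]

    def test_population_frequency_filter(self):
        calls = _calls([_call("R1", 50, pop_freq=0.02), _call("R1", 50, pos=2, pop_freq=0.01)])
        out = vl.filter_calls(calls)
        assert out["pos"].tolist() == [2]  # >1% removed, =1% kept

    def test_negative_reads_rejected(self):
        with pytest.raises(ValueError):
            vl.filter_calls(_calls([_call("R1", -1)]))


class TestRescue:
    def _patient(self):
        raw = _calls(
            [
                _call("R1", 10),
                _call("R2", 1),
                _call("R3", 0),
            ]
        )
        passing = vl.filter_calls(raw)
        return passing, raw

    def test_rescues_only_regions_with_support(self):
        passing, raw = self._patient()
        out = vl.rescue_across_regions(passing, raw)
        assert sorted(out["region_id"]) == ["R1", "R2"]
        assert out.loc[out["region_id"] == "R2", "rescued"].all()

    def test_never_invents_variants(self):
        raw = _calls([_call("R1", 2), _call("R2", 1)])  # passes nowhere
        out = vl.rescue_across_regions(vl.filter_calls(raw), raw)
        assert out.empty

    def test_monotone_and_idempotent(self):
        passing, raw = self._patient()
        once = vl.rescue_across_regions(passing, raw)
        assert len(once) >= len(passing)
        twice = vl.rescue_across_regions(once, raw)
        pd.testing.assert_frame_equal(
            once.sort_values(["region_id", "pos"]).reset_index(drop=True),
            twice.sort_values(["region_id", "pos"]).reset_index(drop=True),
        )


class TestTrunkBranch:
    def test_labels_and_proportions(self):
        presence = pd.DataFrame(
            {"v_all": [1, 1, 1], "v_r1": [1, 0, 0]}, index=["R1", "R2", "R3"]
        )
        labels, p_trunk, p_branch = vl.classify_trunk_branch(presence)
        assert labels["v_all"] == "trunk" and labels["v_r1"] == "branch"
        assert p_trunk == pytest.approx(0.5) and p_branch == pytest.approx(0.5)

    def test_six_trunk_two_branch(self):
        cols = {f"t{i}": [1, 1] for i in range(6)} | {f"b{i}": [1, 0] for i in range(2)}
        presence = pd.DataFrame(cols, index=["R1", "R2"])
        _, p_trunk, _ = vl.classify_trunk_branch(presence)
        assert p_trunk == pytest.approx(0.75)

    def test_all_shared_and_zero_variants(self):
        presence = pd.DataFrame({"v": [1, 1]}, index=["R1", "R2"])
        _, p_trunk, _ = vl.classify_trunk_branch(presence)
        assert p_trunk == 1.0
        _, p_trunk, p_branch = vl.classify_trunk_branch(
            pd.DataFrame(index=["R1", "R2"])
        )
        assert p_trunk is None and p_branch is None


def test_filter_rescue_classify_recovers_truth_without_errors():
    """With a zero sequencing-error rate the pipeline chain reproduces the
    generator's trunk/branch labels exactly."""
    cfg = SimulationConfig(
        n_patients_H=2,
        n_patients_L=2,
        n_mutations_mean=80,
        error_rate=0.0,
        contaminant_fraction=0.05,
        n_windows=10,
        n_genes=5,
        seed=3,
    )
    bundle, truth = simulate_cohort(cfg)
    passing = vl.filter_calls(bundle.mutations)
    rescued = vl.rescue_across_regions(passing, bundle.mutations)
    for pid, pt in truth.patients.items():
        regions = bundle.tumor_regions(pid)
        presence = vl.build_presence(rescued[rescued["patient_id"] == pid], regions)
        labels, _, _ = vl.classify_trunk_branch(presence)
        expected = {k: v for k, v in pt["mutation_labels"].items() if v != "germline_contaminant"}
        assert dict(labels) == expected


class TestTMB:
    def test_counts_and_per_mb(self):
        calls = _calls(
            [_call("R1", 10, pos=p) for p in range(1, 4)]
            + [_call("R1", 10, pos=p, variant_class="synonymous") for p in (5, 6)]
        )
        tmb = vl.compute_tmb(calls, coverage_mb=39.0)
        row = tmb.iloc[0]
        assert row["missense_count"] == 3
        assert row["exonic_per_mb"] == pytest.approx(5 / 39)

    def test_two_per_mb_example(self):
        calls = _calls([_call("R1", 10, pos=p) for p in range(1, 79)])
        assert vl.compute_tmb(calls).iloc[0]["missense_per_mb"] == pytest.approx(2.0)

    def test_empty(self):
        assert vl.compute_tmb(_calls([])).empty


class TestDriverEnrichment:
    def test_fractions(self):
        labels = pd.Series(
            {"v1": "trunk", "v2": "trunk", "v3": "trunk", "v4": "trunk", "v5": "branch"}
        )
        roles = {"v1": "oncogene", "v2": "TSG", "v3": "passenger", "v4": "passenger", "v5": "passenger"}
        ft, fb = vl.driver_enrichment(labels, roles)
        assert ft == pytest.approx(0.5) and fb == 0.0

    def test_missing_side_is_nan(self):
        labels = pd.Series({"v1": "trunk"})
        ft, fb = vl.driver_enrichment(labels, {"v1": "passenger"})
        assert ft == 0.0 and np.isnan(fb)

    def test_simulated_enrichment_direction(self):
        """trunk_driver_enrichment=3 puts more drivers on the trunk than on
        the branches in the clear majority of seeds (cohort means over the
        observed, post-rescue tables)."""
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_patients_H=4,
                n_patients_L=0,
                n_mutations_mean=80,
                trunk_driver_enrichment=3.0,
                n_windows=5,
                n_genes=5,
                seed=100 + seed,
            )
            bundle, _ = simulate_cohort(cfg)
            rescued = vl.rescue_across_regions(
                vl.filter_calls(bundle.mutations), bundle.mutations
            )
            trunk_fracs, branch_fracs = [], []
            for pid in bundle.patient_ids:
                pcalls = rescued[rescued["patient_id"] == pid]
                presence = vl.build_presence(pcalls, bundle.tumor_regions(pid))
                labels, _, _ = vl.classify_trunk_branch(presence)
                roles = (
                    pcalls.assign(key=vl.variant_keys(pcalls))
                    .drop_duplicates("key")
                    .set_index("key")["driver_role"]
                    .to_dict()
                )
                ft, fb = vl.driver_enrichment(labels, roles)
                if not (np.isnan(ft) or np.isnan(fb)):
                    trunk_fracs.append(ft)
                    branch_fracs.append(fb)
            if np.mean(trunk_fracs) > np.mean(branch_fracs):
                hits += 1
        assert hits >= 16  # >= 80% of seeds


class TestSignatureMatching:
    def _catalog(self):
        cat = pd.DataFrame(0.0, index=range(96), columns=["SBS_A", "SBS_B"])
        cat.loc[:47, "SBS_A"] = 1.0
        cat.loc[48:, "SBS_B"] = 1.0
        return cat

    def test_identity_match(self):
        cat = self._catalog()
        matches = vl.match_signature(cat["SBS_A"].to_numpy(), cat)
        assert matches[0] == ("SBS_A", pytest.approx(1.0))

    def test_orthogonal_no_match(self):
        cat = self._catalog()
        v = np.zeros(96)
        v[0:48] = [1, -0] * 24  # only overlaps SBS_A
        v = np.zeros(96)
        v[:48] = 1.0
        assert all(name != "SBS_B" for name, _ in vl.match_signature(v, cat))

    def test_equal_mixture_equal_similarity(self):
        cat = self._catalog()
        v = 0.5 * cat["SBS_A"].to_numpy() + 0.5 * cat["SBS_B"].to_numpy()
        matches = vl.match_signature(v, cat)
        # cosine with each = 1/sqrt(2) ≈ 0.707 > 0.6, equal for both
        assert len(matches) == 2
        assert matches[0][1] == pytest.approx(matches[1][1])
        assert matches[0][1] == pytest.approx(1 / np.sqrt(2))

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            vl.match_signature(np.zeros(96), self._catalog())


def test_mutated_gene_frequencies():
    calls = _calls(
        [
            dict(_call("R1", 10, gene="TP53"), patient_id="P1"),
            dict(_call("R2", 10, gene="TP53"), patient_id="P1"),
            dict(_call("R1", 10, gene="TP53"), patient_id="P2"),
            dict(_call("R1", 10, gene="EGFR"), patient_id="P3"),
        ]
    )
    freqs = vl.mutated_gene_frequencies(calls, ["P1", "P2", "P3", "P4"])
    assert freqs["TP53"] == pytest.approx(0.5)  # two of four patients
    assert freqs["EGFR"] == pytest.approx(0.25)
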