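"""Digital karyotype: shares, Z-scores, outlier calls, permutation null."""

import numpy as np
import pandas as pd
import pytest

from rnakaryo import (
    KaryotypeConfig,
    bootstrap_pvalues,
    call_outliers,
    chromosome_normcounts,
    compute_zscores,
    digital_karyotype,
    qc_pipeline,
    stringent_karyotype,
)
from rnakaryo.simulate import SimulationConfig, simulate_cohort

from conftest import SCALED_QC, make_dataset


def two_chrom_dataset(columns):
    """One gene per chromosome 1 and 2; ``columns`` maps sample -> counts."""
    return make_dataset(columns, {"A": "1", "B": "2"})


class TestNormcounts:
    def test_equal_split(self):
        ds = two_chrom_dataset({"S1": [50, 50], "S2": [50, 50]})
        shares = chromosome_normcounts(ds, "S1")
        assert shares["1"] == pytest.approx(0.5)
        assert shares["2"] == pytest.approx(0.5)

    def test_degenerate_share(self):
        ds = two_chrom_dataset({"S1": [100, 0], "S2": [1, 1]})
        assert chromosome_normcounts(ds, "S1")["1"] == pytest.approx(1.0)

    def test_scale_invariance_and_unit_sum(self):
        ds = two_chrom_dataset({"S1": [30, 70], "S2": [60, 140]})
        shares = chromosome_normcounts(ds)
        pd.testing.assert_series_equal(
            shares.loc["S1"], shares.loc["S2"], check_names=False
        )
        assert shares.sum(axis=1).values == pytest.approx([1.0, 1.0])

    def test_zero_depth_errors(self):
        ds = two_chrom_dataset({"S1": [0, 0], "S2": [1, 1]})
        with pytest.raises(ValueError, match="zero-depth"):
            chromosome_normcounts(ds)

    def test_par_and_mt_and_y_excluded(self, small_cohort):
        dataset, _ = small_cohort
        shares = chromosome_normcounts(dataset)
        assert "Y" not in shares.columns and "MT" not in shares.columns
        assert shares.sum(axis=1).values == pytest.approx(
            np.ones(dataset.n_samples), abs=1e-12
        )


class TestZscores:
    def _z(self, values, ddof_mode="sample"):
        shares = pd.DataFrame({"1": values})
        shares.index = [f"S{i}" for i in range(len(values))]
        types = pd.Series("WE", index=shares.index)
        return compute_zscores(shares, types, KaryotypeConfig(sd_mode=ddof_mode))

    def test_hand_computed_column(self):
        z, _ = self._z([0.1, 0.1, 0.1, 0.2])
        np.testing.assert_allclose(z["1"].values, [-0.5, -0.5, -0.5, 1.5])

    def test_two_samples_closed_form(self):
        z, _ = self._z([0.4, 0.6])
        np.testing.assert_allclose(
            np.abs(z["1"].values), [1 / np.sqrt(2)] * 2, rtol=1e-12
        )

    def test_degenerate_sd_flagged_as_zero(self):
        z, degenerate = self._z([0.5, 0.5, 0.5])
        assert (z["1"] == 0).all()
        assert degenerate["1"].all()

    def test_column_mean_zero_within_type(self, small_cohort):
        dataset, _ = small_cohort
        shares = chromosome_normcounts(dataset)
        z, _ = compute_zscores(shares, dataset.samples["sample_type"])
        for stype in ("WE", "TE"):
            block = z.loc[dataset.samples["sample_type"] == stype]
            np.testing.assert_allclose(
                block.mean(axis=0).values, 0.0, atol=1e-10
            )
            sd = block.std(axis=0, ddof=1)
            np.testing.assert_allclose(sd[sd > 0].values, 1.0, rtol=1e-10)

    def test_brute_force_oracle_equivalence(self):
        # 4 samples x 3 chromosomes with hand-specified counts
        counts = {
            "S1": [10, 5, 20, 30, 7],
            "S2": [12, 6, 18, 28, 9],
            "S3": [8, 4, 25, 31, 6],
            "S4": [15, 9, 15, 27, 11],
        }
        chromosomes = {"g1": "1", "g2": "1", "g3": "2", "g4": "3", "g5": "3"}
        ds = make_dataset(counts, chromosomes)
        shares = chromosome_normcounts(ds)
        z, _ = compute_zscores(shares, ds.samples["sample_type"])

        # independent explicit-loop recomputation
        sample_ids = list(counts)
        chrom_labels = ["1", "2", "3"]
        oracle_shares = {}
        for s in sample_ids:
            total = sum(counts[s])
            per_chrom = {c: 0.0 for c in chrom_labels}
            for gene, chrom in chromosomes.items():
                idx = list(chromosomes).index(gene)
                per_chrom[chrom] += counts[s][idx]
            oracle_shares[s] = {c: per_chrom[c] / total for c in chrom_labels}
        for c in chrom_labels:
            vals = [oracle_shares[s][c] for s in sample_ids]
            mean = sum(vals) / len(vals)
            var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
            sd = var ** 0.5
            for s in sample_ids:
                expected = (oracle_shares[s][c] - mean) / sd
                assert z.at[s, c] == pytest.approx(expected, abs=1e-12)
            assert sum(oracle_shares[s][c] for c in chrom_labels) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_single_sample_type_skipped_not_fatal(self):
        shares = pd.DataFrame({"1": [0.4, 0.6, 0.5]}, index=["a", "b", "c"])
        types = pd.Series(["WE", "WE", "TE"], index=shares.index)
        z, _ = compute_zscores(shares, types)
        assert np.isnan(z.at["c", "1"])
        assert not np.isnan(z.at["a", "1"])


class TestOutlierCalls:
    @pytest.mark.parametrize(
        "z,expected", [(2.5, "gain"), (-2.5, "loss"), (2.0, "euploid"),
                       (-2.0, "euploid"), (0.0, "euploid")]
    )
    def test_strict_cutoffs(self, z, expected):
        frame = pd.DataFrame({"1": [z]}, index=["S1"])
        calls, ploidy = call_outliers(frame)
        assert calls.at["S1", "1"] == expected
        assert ploidy["S1"] == ("euploid" if expected == "euploid" else "aneuploid")


class TestBootstrap:
    def test_seed_reproducibility_and_range(self, small_cohort):
        dataset, _ = small_cohort
        filtered = qc_pipeline(dataset, SCALED_QC)
        config = KaryotypeConfig(n_shuffles=50, seed=7)
        shares = chromosome_normcounts(filtered)
        z, _ = compute_zscores(shares, filtered.samples["sample_type"], config)
        p1 = bootstrap_pvalues(filtered, z, config)
        p2 = bootstrap_pvalues(filtered, z, config)
        pd.testing.assert_frame_equal(p1, p2)
        vals = p1.values[~np.isnan(p1.values)]
        assert vals.min() >= 1 / 51 and vals.max() <= 1.0

    def test_zero_z_has_p_one(self):
        # identical samples -> all z = 0 -> every replicate is as extreme
        ds = make_dataset(
            {"S1": [10, 20, 30], "S2": [10, 20, 30], "S3": [10, 20, 30]},
            {"a": "1", "b": "2", "c": "3"},
        )
        config = KaryotypeConfig(n_shuffles=25, seed=1)
        shares = chromosome_normcounts(ds)
        z, _ = compute_zscores(shares, ds.samples["sample_type"], config)
        p = bootstrap_pvalues(ds, z, config)
        assert (p.values == 1.0).all()

    def test_pool_needs_two_chromosomes(self):
        ds = make_dataset({"S1": [1, 2], "S2": [3, 4]}, {"a": "1", "b": "1"})
        shares = chromosome_normcounts(ds)
        z, _ = compute_zscores(shares, ds.samples["sample_type"])
        with pytest.raises(ValueError, match="at least 2 chromosomes"):
            bootstrap_pvalues(ds, z, KaryotypeConfig(n_shuffles=5))


class TestStringent:
    def test_requires_both_outlier_and_small_p(self):
        calls = pd.DataFrame({"1": ["gain", "gain", "euploid"]},
                             index=["a", "b", "c"])
        p = pd.DataFrame({"1": [0.01, 0.20, 0.01]}, index=["a", "b", "c"])
        sig = stringent_karyotype(calls, p)
        assert sig["1"].tolist() == [True, False, False]


def test_single_trisomy_recovered_with_high_z(small_cohort):
    """One trisomy-16 embryo among 8 stands far outside the cohort spread."""
    dataset, truth = small_cohort
    filtered = qc_pipeline(dataset, SCALED_QC)
    result = digital_karyotype(
        filtered, KaryotypeConfig(n_shuffles=300, seed=3)
    )
    assert result["calls"].at["E1_WE", "16"] == "gain"
    assert result["z"].at["E1_WE", "16"] > 2
    assert result["significant"].at["E1_WE", "16"]
    # euploid embryos stay mostly clean on chromosome 16
    others = result["calls"]["16"].drop(["E1_WE", "E1_TE"])
    assert (others == "euploid").all()
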