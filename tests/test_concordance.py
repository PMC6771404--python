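"""Paired biopsy-embryo concordance and mosaicism classification."""

import numpy as np
import pandas as pd
import pytest

from rnakaryo import (
    classify_mosaicism,
    reciprocal_aneuploidy,
    zprofile_correlations,
    zscore_distances,
)
from rnakaryo.concordance import build_pair_records, mosaicism_frame
from rnakaryo.sexing import SexCall

CHROMS = [str(i) for i in range(1, 23)]


def z_frame(rows):
    return pd.DataFrame(rows, columns=CHROMS[: len(next(iter(rows.values())))])


class TestCorrelations:
    def test_identical_profiles_r_one(self):
        profile = np.linspace(-2, 2, 10)
        z_we = pd.DataFrame([profile], index=["W1"])
        z_te = pd.DataFrame([profile], index=["T1"])
        out = zprofile_correlations(z_we, z_te, {"T1": "W1"})
        assert out["matrix"].at["T1", "W1"] == pytest.approx(1.0)
        assert out["paired_r"] == [pytest.approx(1.0)]

    def test_negated_profiles_r_minus_one(self):
        profile = np.linspace(-2, 2, 10)
        z_we = pd.DataFrame([profile], index=["W1"])
        z_te = pd.DataFrame([-profile], index=["T1"])
        out = zprofile_correlations(z_we, z_te, {"T1": "W1"})
        assert out["matrix"].at["T1", "W1"] == pytest.approx(-1.0)

    def test_exchangeable_values_give_p_half(self):
        # two identical WE profiles: each TE correlates equally with its
        # pair and its non-pair, so paired and unpaired r coincide
        rng = np.random.default_rng(0)
        v = rng.normal(size=10)
        t1, t2 = rng.normal(size=10), rng.normal(size=10)
        z_we = pd.DataFrame([v, v], index=["W1", "W2"])
        z_te = pd.DataFrame([t1, t2], index=["T1", "T2"])
        out = zprofile_correlations(z_we, z_te, {"T1": "W1", "T2": "W2"})
        assert out["test_p"] == pytest.approx(0.5)

    def test_zero_variance_profile_excluded_with_warning(self):
        z_we = pd.DataFrame(
            [np.linspace(-1, 1, 10), np.zeros(10)], index=["W1", "W2"]
        )
        z_te = pd.DataFrame([np.linspace(-1, 1, 10)], index=["T1"])
        with pytest.warns(UserWarning, match="W2"):
            out = zprofile_correlations(z_we, z_te, {"T1": "W1"})
        assert list(out["matrix"].columns) == ["W1"]

    def test_needs_two_chromosomes(self):
        z_we = pd.DataFrame([[1.0]], index=["W1"])
        z_te = pd.DataFrame([[1.0]], index=["T1"])
        with pytest.raises(ValueError, match=">= 2 chromosomes"):
            zprofile_correlations(z_we, z_te, {})


class TestZDistances:
    def test_identity(self):
        z = pd.Series([1.0, -2.0], index=["1", "2"])
        assert (zscore_distances(z, z) == 0).all()

    def test_reciprocal_distance(self):
        we = pd.Series({"17": 2.5, "1": 0.0})
        te = pd.Series({"17": -2.5, "1": 0.0})
        dist = zscore_distances(we, te)
        assert dist["17"] == pytest.approx(5.0)
        pd.testing.assert_series_equal(dist, zscore_distances(te, we))

    def test_chromosome_mismatch_errors(self):
        with pytest.raises(ValueError, match="chromosome sets"):
            zscore_distances(
                pd.Series({"1": 0.0}), pd.Series({"2": 0.0})
            )


class TestReciprocal:
    def test_opposite_directions_flagged(self):
        we = {"17": "gain", "16": "euploid"}
        te = {"17": "loss", "16": "euploid"}
        assert reciprocal_aneuploidy(we, te) == ["17"]
        assert reciprocal_aneuploidy(te, we) == ["17"]  # symmetric

    def test_same_direction_not_flagged(self):
        we = {"16": "gain"}
        te = {"16": "gain"}
        assert reciprocal_aneuploidy(we, te) == []

    def test_euploid_pair_empty(self):
        we = {"1": "euploid", "2": "euploid"}
        assert reciprocal_aneuploidy(we, we) == []


def _meta(rows):
    frame = pd.DataFrame(rows).set_index("sample_id")
    for col in ("pgta_sex", "pgta_gains", "pgta_losses"):
        if col not in frame.columns:
            frame[col] = None
    return frame


def _calls_frame(rows):
    return pd.DataFrame(rows).T.reindex(columns=CHROMS).fillna("euploid")


class TestMosaicismClassification:
    def test_discordant_outlier_is_conservative_evidence(self):
        # WE gained chromosome 16, its paired TE is euploid
        samples = _meta(
            [
                {"sample_id": "E1_WE", "embryo_id": "E1", "sample_type": "WE"},
                {"sample_id": "E1_TE", "embryo_id": "E1", "sample_type": "TE"},
            ]
        )
        calls = _calls_frame({"E1_WE": {"16": "gain"}, "E1_TE": {}})
        sex = [SexCall("E1_WE", 0, 1, "XX", False), SexCall("E1_TE", 0, None, "XX", False)]
        out, rates = classify_mosaicism(samples, sex, calls)
        assert out[0].discordant_outlier_evidence
        assert out[0].mosaic_conservative and out[0].mosaic_permissive
        assert rates["conservative"]["n"] == 1

    def test_y_loss_from_pgta_vs_te(self):
        # PGT-A says XY but the TE biopsy shows no Y expression
        samples = _meta(
            [
                {"sample_id": "E2_TE", "embryo_id": "E2", "sample_type": "TE",
                 "pgta_sex": "XY", "pgta_gains": (), "pgta_losses": ()},
            ]
        )
        calls = _calls_frame({"E2_TE": {}})
        sex = [SexCall("E2_TE", 0.0, None, "XX", False)]
        out, _ = classify_mosaicism(samples, sex, calls)
        assert out[0].y_loss_evidence and out[0].mosaic_conservative

    def test_pgta_we_mismatch_is_permissive_only(self):
        # PGT-A monosomy 15, WE RNA karyotype euploid, no other evidence
        samples = _meta(
            [
                {"sample_id": "E3_WE", "embryo_id": "E3", "sample_type": "WE",
                 "pgta_sex": "XX", "pgta_gains": (), "pgta_losses": ("15",)},
            ]
        )
        calls = _calls_frame({"E3_WE": {}})
        sex = [SexCall("E3_WE", 0, 1, "XX", False)]
        out, rates = classify_mosaicism(samples, sex, calls)
        assert out[0].pgta_we_mismatch
        assert not out[0].mosaic_conservative
        assert out[0].mosaic_permissive
        assert rates["permissive"]["percent"] == 100.0

    def test_single_result_embryos_excluded(self):
        samples = _meta(
            [{"sample_id": "E4_WE", "embryo_id": "E4", "sample_type": "WE"}]
        )
        calls = _calls_frame({"E4_WE": {}})
        out, rates = classify_mosaicism(samples, [SexCall("E4_WE", 0, 1, "XX", False)], calls)
        assert out == []
        assert rates["n_eligible"] == 0
        assert rates["conservative"]["percent"] is None

    def test_conservative_subset_of_permissive(self):
        rows, calls, sex = [], {}, []
        for i, (gain, pgta_loss) in enumerate(
            [(True, None), (False, "5"), (False, None), (True, "7")]
        ):
            we, te = f"E{i}_WE", f"E{i}_TE"
            row = {"sample_id": we, "embryo_id": f"E{i}", "sample_type": "WE"}
            if pgta_loss:
                row |= {"pgta_sex": "XX", "pgta_gains": (),
                        "pgta_losses": (pgta_loss,)}
            rows.append(row)
            rows.append({"sample_id": te, "embryo_id": f"E{i}", "sample_type": "TE"})
            calls[we] = {"16": "gain"} if gain else {}
            calls[te] = {}
            sex += [SexCall(we, 0, 1, "XX", False), SexCall(te, 0, None, "XX", False)]
        out, _ = classify_mosaicism(_meta(rows), sex, _calls_frame(calls))
        for call in out:
            assert not call.mosaic_conservative or call.mosaic_permissive


def test_pair_records_from_z_and_calls():
    z = pd.DataFrame(
        {
            "E1_WE": [2.5, 0.1, 0.0],
            "E1_TE": [-2.5, 0.2, 0.1],
        },
        index=["17", "1", "2"],
    ).T
    calls = pd.DataFrame(
        {"E1_WE": ["gain", "euploid", "euploid"],
         "E1_TE": ["loss", "euploid", "euploid"]},
        index=["17", "1", "2"],
    ).T
    samples = _meta(
        [
            {"sample_id": "E1_WE", "embryo_id": "E1", "sample_type": "WE"},
            {"sample_id": "E1_TE", "embryo_id": "E1", "sample_type": "TE"},
        ]
    )
    records = build_pair_records(z, calls, samples)
    assert len(records) == 1
    rec = records[0]
    assert rec.reciprocal_chromosomes == ["17"]
    assert rec.z_distance["17"] == pytest.approx(5.0)
    assert not rec.concordant_euploid
    assert rec.discordant_outliers == []
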