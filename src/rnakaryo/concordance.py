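"""Trophectoderm-biopsy vs whole-embryo concordance and mosaicism.

A TE biopsy samples only a few outer cells of the blastocyst; how well it
reports on the remaining whole embryo (WE) is quantified three ways:

* Pearson correlation between chromosome Z-score profiles, comparing
  same-embryo ("paired") against different-embryo ("unpaired") TE x WE
  combinations, with a one-sided test of paired > unpaired;
* per-chromosome Z-score distances |z_WE - z_TE|;
* reciprocal-aneuploidy flags — one chromosome an outlier in both members
  but in opposite directions, the signature of mitotic nondisjunction.

Mosaicism (different karyotypes among cells of one embryo) is classified
per embryo from the inventory of available karyotype results (PGT-A, WE
RNA, TE RNA; at least two required):

* conservative — Y-loss evidence (a Y seen in one result but absent from
  an RNA result) or discordant outlier calls between the TE and WE
  profiles;
* permissive — conservative, or any mismatch between the PGT-A karyotype
  and the WE RNA karyotype (undefined PGT-A fields never count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import ExpressionDataset
from .sexing import SexCall


@dataclass
class EmbryoPairRecord:
    embryo_id: str
    we_sample: str
    te_sample: str
    pearson_r: float
    z_distance: dict[str, float]
    reciprocal_chromosomes: list[str]
    discordant_outliers: list[str]  # outlier in exactly one member
    concordant_euploid: bool


@dataclass
class MosaicismCall:
    embryo_id: str
    n_karyotype_results: int
    y_loss_evidence: bool
    discordant_outlier_evidence: bool
    pgta_we_mismatch: bool
    mosaic_conservative: bool
    mosaic_permissive: bool


def zprofile_correlations(
    z_we: pd.DataFrame,
    z_te: pd.DataFrame,
    pairing: Mapping[str, str],
    test: str = "welch",
) -> dict:
    """Full TE x WE Pearson matrix, partitioned into paired and unpaired.

    ``pairing`` maps TE sample id -> WE sample id for same-embryo pairs.
    Zero-variance profiles have undefined correlation and are excluded with
    a warning.  The paired > unpaired comparison is a one-sided Welch
    two-sample t-test by default (``test="ranksum"`` for the Wilcoxon
    rank-sum alternative).
    """
    if z_we.shape[1] < 2:
        raise ValueError("correlation profiles need >= 2 chromosomes")
    z_te = z_te[z_we.columns]

    def _usable(frame: pd.DataFrame) -> pd.DataFrame:
        sd = frame.std(axis=1)
        bad = frame.index[(sd == 0) | frame.isna().any(axis=1)]
        if len(bad):
            warnings.warn(
                f"profiles with undefined correlation excluded: {bad.tolist()}",
                stacklevel=3,
            )
        return frame.drop(index=bad)

    z_we, z_te = _usable(z_we), _usable(z_te)
    matrix = pd.DataFrame(
        np.corrcoef(z_te.values, z_we.values)[: len(z_te), len(z_te):],
        index=z_te.index,
        columns=z_we.index,
    )
    paired, unpaired = [], []
    for te in matrix.index:
        for we in matrix.columns:
            (paired if pairing.get(te) == we else unpaired).append(
                matrix.at[te, we]
            )
    if paired and unpaired:
        if test == "welch":
            stat = scipy.stats.ttest_ind(
                paired, unpaired, equal_var=False, alternative="greater"
            )
        elif test == "ranksum":
            stat = scipy.stats.mannwhitneyu(
                paired, unpaired, alternative="greater"
            )
        else:
            raise ValueError("test must be 'welch' or 'ranksum'")
        test_p = float(stat.pvalue)
    else:
        test_p = None
    return {
        "matrix": matrix,
        "paired_r": paired,
        "unpaired_r": unpaired,
        "test_p": test_p,
    }


def zscore_distances(z_we: pd.Series, z_te: pd.Series) -> pd.Series:
    """Per-chromosome |z_WE - z_TE|; symmetric and non-negative."""
    if set(z_we.index) != set(z_te.index):
        raise ValueError("chromosome sets of the two profiles differ")
    return (z_we - z_te.loc[z_we.index]).abs()


def reciprocal_aneuploidy(
    we_calls: Mapping[str, str], te_calls: Mapping[str, str]
) -> list[str]:
    """Chromosomes called gain in one member and loss in the other."""
    if set(we_calls) != set(te_calls):
        raise ValueError("chromosome sets of the two call profiles differ")
    return [
        c
        for c in we_calls
        if {we_calls[c], te_calls[c]} == {"gain", "loss"}
    ]


def build_pair_records(
    z: pd.DataFrame,
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    correlations: pd.DataFrame | None = None,
) -> list[EmbryoPairRecord]:
    """Assemble one record per embryo having both a WE and a TE profile."""
    records = []
    for embryo, group in samples.groupby("embryo_id", sort=False):
        by_type = {
            group.at[s, "sample_type"]: s for s in group.index if s in z.index
        }
        if "WE" not in by_type or "TE" not in by_type:
            continue
        we, te = by_type["WE"], by_type["TE"]
        we_calls = calls.loc[we].to_dict()
        te_calls = calls.loc[te].to_dict()
        dist = zscore_distances(z.loc[we], z.loc[te])
        if correlations is not None and te in correlations.index:
            r = float(correlations.at[te, we])
        else:
            r = float(np.corrcoef(z.loc[we], z.loc[te])[0, 1])
        outlier_we = {c for c, v in we_calls.items() if v != "euploid"}
        outlier_te = {c for c, v in te_calls.items() if v != "euploid"}
        records.append(
            EmbryoPairRecord(
                embryo_id=str(embryo),
                we_sample=we,
                te_sample=te,
                pearson_r=r,
                z_distance=dist.to_dict(),
                reciprocal_chromosomes=reciprocal_aneuploidy(we_calls, te_calls),
                discordant_outliers=sorted(outlier_we ^ outlier_te),
                concordant_euploid=not outlier_we and not outlier_te,
            )
        )
    return records


def _pgta_record(samples: pd.DataFrame, embryo: str) -> dict | None:
    """Embryo-level PGT-A result (first non-null among its samples)."""
    rows = samples[samples["embryo_id"] == embryo]
    for s in rows.index:
        sex = rows.at[s, "pgta_sex"]
        if pd.notna(sex) and sex is not None:
            return {
                "sex": sex,
                "gains": rows.at[s, "pgta_gains"],
                "losses": rows.at[s, "pgta_losses"],
            }
    return None


def classify_mosaicism(
    samples: pd.DataFrame,
    sex_calls: Sequence[SexCall],
    karyotype_calls: pd.DataFrame,
    y_threshold_tpm: float = 25.0,
) -> tuple[list[MosaicismCall], dict]:
    """Per-embryo mosaicism flags and cohort rates.

    ``karyotype_calls`` is the permissive samples x chromosomes call frame
    for RNA samples passing QC.  Only embryos with at least two karyotype
    results (PGT-A / WE RNA / TE RNA) enter the denominator.  Rates are
    returned as exact fractions and percent to one decimal.
    """
    sex_by_id = {c.sample_id: c for c in sex_calls}
    calls_out: list[MosaicismCall] = []
    for embryo, group in samples.groupby("embryo_id", sort=False):
        rna = {
            group.at[s, "sample_type"]: s
            for s in group.index
            if s in karyotype_calls.index
        }
        pgta = _pgta_record(samples, str(embryo))
        n_results = len(rna) + (1 if pgta else 0)
        if n_results < 2:
            continue

        # Y-loss: a Y seen somewhere for this embryo but absent from at
        # least one RNA result
        y_sums = [
            sex_by_id[s].y_sum_tpm for s in group.index if s in sex_by_id
        ]
        y_present = (pgta is not None and pgta["sex"] == "XY") or any(
            y > y_threshold_tpm for y in y_sums
        )
        y_absent = any(y <= y_threshold_tpm for y in y_sums)
        y_loss = bool(y_present and y_absent)

        discordant = False
        if "WE" in rna and "TE" in rna:
            we_calls = karyotype_calls.loc[rna["WE"]]
            te_calls = karyotype_calls.loc[rna["TE"]]
            unequal = we_calls != te_calls
            non_euploid = (we_calls != "euploid") | (te_calls != "euploid")
            discordant = bool((unequal & non_euploid).any())

        mismatch = False
        if pgta is not None and "WE" in rna:
            we_calls = karyotype_calls.loc[rna["WE"]]
            rna_gains = {c for c in we_calls.index if we_calls[c] == "gain"}
            rna_losses = {c for c in we_calls.index if we_calls[c] == "loss"}
            if pgta["gains"] is not None:
                pg = set(pgta["gains"]) & set(we_calls.index)
                mismatch |= pg != rna_gains
            if pgta["losses"] is not None:
                pl = set(pgta["losses"]) & set(we_calls.index)
                mismatch |= pl != rna_losses
            if pgta["sex"] in ("XX", "XY") and rna["WE"] in sex_by_id:
                rna_sex = sex_by_id[rna["WE"]].call
                if rna_sex in ("XX", "XY"):
                    mismatch |= rna_sex != pgta["sex"]

        conservative = y_loss or discordant
        calls_out.append(
            MosaicismCall(
                embryo_id=str(embryo),
                n_karyotype_results=n_results,
                y_loss_evidence=y_loss,
                discordant_outlier_evidence=discordant,
                pgta_we_mismatch=bool(mismatch),
                mosaic_conservative=conservative,
                mosaic_permissive=conservative or bool(mismatch),
            )
        )
    n = len(calls_out)
    n_cons = sum(c.mosaic_conservative for c in calls_out)
    n_perm = sum(c.mosaic_permissive for c in calls_out)
    rates = {
        "n_eligible": n,
        "conservative": {
            "n": n_cons,
            "fraction": n_cons / n if n else None,
            "percent": round(100.0 * n_cons / n, 1) if n else None,
        },
        "permissive": {
            "n": n_perm,
            "fraction": n_perm / n if n else None,
            "percent": round(100.0 * n_perm / n, 1) if n else None,
        },
    }
    return calls_out, rates


def mosaicism_frame(calls: Sequence[MosaicismCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "embryo_id": c.embryo_id,
                "n_karyotype_results": c.n_karyotype_results,
                "y_loss_evidence": c.y_loss_evidence,
                "discordant_outlier_evidence": c.discordant_outlier_evidence,
                "pgta_we_mismatch": c.pgta_we_mismatch,
                "mosaic_conservative": c.mosaic_conservative,
                "mosaic_permissive": c.mosaic_permissive,
            }
            for c in calls
        ]
    ).set_index("embryo_id")


def pairs_frame(records: Sequence[EmbryoPairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "embryo_id": r.embryo_id,
                "we_sample": r.we_sample,
                "te_sample": r.te_sample,
                "pearson_r": r.pearson_r,
                "max_z_distance": max(r.z_distance.values()),
                "reciprocal_chromosomes": ",".join(r.reciprocal_chromosomes),
                "discordant_outliers": ",".join(r.discordant_outliers),
                "concordant_euploid": r.concordant_euploid,
            }
            for r in records
        ]
    ).set_index("embryo_id")
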