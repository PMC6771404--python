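"""Embryo sex-chromosome content from RNA-seq.

Single-gene genotyping (SRY, XIST) is uninformative at the blastocyst
stage, so presence of a Y chromosome is read from the summed TPM of three
robustly expressed Y-specific markers (DDX3Y, RPS4Y1, EIF1AY): a sum
strictly above 25 TPM is evidence for a Y.  Copy number of the X — present
in every embryo — is instead read from the chromosome-X expression Z-score
produced by the digital-karyotype module (pseudoautosomal genes excluded).

Whole embryos (WE) combine both signals: Y sum > threshold with a negative
X Z-score calls XY; Y sum <= threshold with a positive X Z-score calls XX;
any other combination (including X Z-score exactly 0) is ambiguous with an
explanatory note.  Trophectoderm biopsies (TE) are called on the Y sum
alone, because X-chromosome inactivation attenuates the X dosage signal in
TE at this stage.  A positive-but-subthreshold Y sum is flagged as low Y
evidence — possible partial Y loss in a mosaic — but never called XY.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import DEFAULT_Y_MARKERS, ExpressionDataset
from .karyotype import KaryotypeConfig, chromosome_normcounts, compute_zscores


@dataclass
class SexConfig:
    y_threshold_tpm: float = 25.0
    y_marker_ids: tuple[str, ...] = DEFAULT_Y_MARKERS
    exclude_par: bool = True

    def __post_init__(self) -> None:
        if self.y_threshold_tpm <= 0:
            raise ValueError("y_threshold_tpm must be > 0")
        if not self.y_marker_ids:
            raise ValueError("marker set must be non-empty")


@dataclass
class SexCall:
    sample_id: str
    y_sum_tpm: float
    x_zscore: float | None
    call: str  # XX / XY / ambiguous
    low_y_evidence: bool
    conflict_note: str | None = None


def y_tpm_sum(
    dataset: ExpressionDataset, sample: str, config: SexConfig | None = None
) -> float:
    """Summed marker TPM for one sample.

    Markers absent from the (filtered) matrix contribute zero and are
    reported in a warning — a biopsy may legitimately lack marker
    detection.  Pseudoautosomal genes never count as markers when
    ``exclude_par`` is set.
    """
    config = config or SexConfig()
    markers = [m for m in config.y_marker_ids]
    if config.exclude_par:
        par = set(dataset.genes.index[dataset.genes["is_par"]])
        markers = [m for m in markers if m not in par]
    present = [m for m in markers if m in dataset.tpm.index]
    missing = sorted(set(markers) - set(present))
    if missing:
        warnings.warn(
            f"Y markers absent from matrix (contribute 0): {missing}",
            stacklevel=2,
        )
    if not present:
        return 0.0
    return float(dataset.tpm.loc[present, sample].sum())


def call_sex(
    sample_id: str,
    y_sum: float,
    x_zscore: float | None,
    sample_type: str,
    config: SexConfig | None = None,
) -> SexCall:
    """Apply the WE or TE decision rule to one sample's evidence.

    The threshold comparison is strict (> 25 TPM); boundary equality falls
    to the no-Y side.
    """
    config = config or SexConfig()
    thr = config.y_threshold_tpm
    low_y = 0 < y_sum <= thr
    if sample_type == "TE":
        call = "XY" if y_sum > thr else "XX"
        return SexCall(sample_id, y_sum, None, call, low_y)
    if sample_type != "WE":
        raise ValueError(f"unknown sample type {sample_type!r}")
    if x_zscore is None or (isinstance(x_zscore, float) and np.isnan(x_zscore)):
        raise ValueError(f"WE sex call for {sample_id} requires an X Z-score")
    note = None
    if y_sum > thr and x_zscore < 0:
        call = "XY"
    elif y_sum <= thr and x_zscore > 0:
        call = "XX"
    else:
        call = "ambiguous"
        note = (
            f"conflicting evidence: Y sum {y_sum:.1f} TPM "
            f"vs X Z-score {x_zscore:+.2f}"
        )
    return SexCall(sample_id, y_sum, float(x_zscore), call, low_y, note)


def call_cohort_sex(
    dataset: ExpressionDataset,
    sex_config: SexConfig | None = None,
    karyotype_config: KaryotypeConfig | None = None,
) -> list[SexCall]:
    """Sex calls for every sample: Y marker sums plus WE X Z-scores.

    The X Z-score comes from the same per-type chromosome-share Z
    computation used for the digital karyotype.
    """
    sex_config = sex_config or SexConfig()
    shares = chromosome_normcounts(dataset)
    z, _ = compute_zscores(
        shares, dataset.samples["sample_type"], karyotype_config
    )
    calls = []
    for sample in dataset.counts.columns:
        stype = dataset.samples.at[sample, "sample_type"]
        y_sum = y_tpm_sum(dataset, sample, sex_config)
        x_z = float(z.at[sample, "X"]) if stype == "WE" else None
        calls.append(call_sex(sample, y_sum, x_z, stype, sex_config))
    return calls


def pgta_agreement(
    calls: Sequence[SexCall], samples: pd.DataFrame
) -> dict[str, dict]:
    """Tally RNA sex calls against PGT-A per sample type.

    Only samples whose PGT-A sex is XX or XY are compared ("undefined" is
    excluded and counted separately); an ambiguous RNA call counts as
    disagreement.  The fraction is a percent rounded to one decimal, or
    None when nothing was comparable.
    """
    by_id = {c.sample_id: c for c in calls}
    table: dict[str, dict] = {}
    for stype in ("WE", "TE"):
        ids = [
            s
            for s in samples.index
            if samples.at[s, "sample_type"] == stype and s in by_id
        ]
        n_undefined = sum(
            1 for s in ids if samples.at[s, "pgta_sex"] == "undefined"
        )
        comparable = [
            s for s in ids if samples.at[s, "pgta_sex"] in ("XX", "XY")
        ]
        n_agree = sum(
            1 for s in comparable if by_id[s].call == samples.at[s, "pgta_sex"]
        )
        n = len(comparable)
        table[stype] = {
            "n_compared": n,
            "n_agree": n_agree,
            "percent": round(100.0 * n_agree / n, 1) if n else None,
            "n_undefined": n_undefined,
        }
    return table


def sex_calls_frame(calls: Sequence[SexCall]) -> pd.DataFrame:
    """Tidy one-row-per-sample view for the ``sex`` CLI output."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "y_sum_tpm": c.y_sum_tpm,
                "x_zscore": c.x_zscore,
                "call": c.call,
                "low_y_evidence": c.low_y_evidence,
                "conflict_note": c.conflict_note or "",
            }
            for c in calls
        ]
    ).set_index("sample_id")
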