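"""Core containers for blastocyst RNA-seq cohorts.

A cohort is an aligned triple:

``counts``
    genes x samples read-count matrix (:class:`pandas.DataFrame`, float,
    non-negative), rows indexed by gene id, columns by sample id.
``genes``
    per-gene annotation, indexed by gene id, with columns

    ============  =====================================================
    chromosome    label in ``{"1".."22", "X", "Y", "MT"}`` (no ``chr``)
    length_bp     transcript length in base pairs (>= 1)
    is_par        pseudoautosomal-region member (bool; X/Y only)
    is_y_marker   member of the Y-chromosome sexing marker set (bool)
    ============  =====================================================
``samples``
    per-sample metadata, indexed by sample id, with columns ``embryo_id``,
    ``sample_type`` (``WE`` whole embryo / ``TE`` trophectoderm biopsy) and
    optional PGT-A karyotype (``pgta_sex`` in {XX, XY, undefined},
    ``pgta_gains``/``pgta_losses`` tuples of chromosome labels), Gardner
    morphology grade (``grade_expansion`` 1-6, ``grade_icm``/``grade_te`` in
    {A, B, C}) and ``harvest_day`` (5-7).  Missing optional fields are
    explicit nulls (``None``/``NaN``), never imputed.

TPM is derived from counts and annotated lengths
(``TPM_g = 1e6 * (c_g/L_g) / sum_h(c_h/L_h)``) unless a TPM table quantified
upstream is supplied, in which case the supplied table wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y", "MT")
SAMPLE_TYPES: tuple[str, ...] = ("WE", "TE")
GRADE_LETTERS: tuple[str, ...] = ("A", "B", "C")
PGTA_SEXES: tuple[str, ...] = ("XX", "XY", "undefined")

#: Default Y-chromosome sexing markers: robustly expressed, Y-specific
#: (non-pseudoautosomal) protein-coding genes.
DEFAULT_Y_MARKERS: tuple[str, ...] = ("DDX3Y", "RPS4Y1", "EIF1AY")

#: Genes of pseudoautosomal regions 1 and 2, which reside on both sex
#: chromosomes and therefore map ambiguously; excluded from X/Y sums.
DEFAULT_PAR_GENES: frozenset[str] = frozenset(
    {
        # PAR1
        "PLCXD1", "GTPBP6", "PPP2R3B", "SHOX", "CRLF2", "CSF2RA", "IL3RA",
        "SLC25A6", "ASMTL", "P2RY8", "AKAP17A", "ASMT", "DHRSX", "ZBED1",
        "CD99", "XG",
        # PAR2
        "SPRY3", "VAMP7", "IL9R", "WASH6P",
    }
)

GENE_COLUMNS = ("chromosome", "length_bp", "is_par", "is_y_marker")
SAMPLE_COLUMNS = (
    "embryo_id",
    "sample_type",
    "pgta_sex",
    "pgta_gains",
    "pgta_losses",
    "grade_expansion",
    "grade_icm",
    "grade_te",
    "harvest_day",
)


@dataclass(frozen=True)
class FilterRecord:
    """One provenance entry: a QC rule applied to the dataset.

    ``removed`` holds every removed identifier so any filtering step can be
    reconstructed exactly from the log.
    """

    step: str
    axis: str  # "gene" or "sample"
    removed: tuple[str, ...]
    params: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def compute_tpm(counts: np.ndarray, lengths: np.ndarray) -> tuple[np.ndarray, bool]:
    """Transcripts-per-million for one sample.

    Parameters
    ----------
    counts
        Non-negative read counts, one entry per gene.
    lengths
        Positive gene lengths in bp, aligned with ``counts``.

    Returns
    -------
    tpm, degenerate
        ``tpm`` sums to 1e6 unless the column is all-zero, in which case it
        is all-zero and ``degenerate`` is True.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError(
            f"length mismatch: {counts.shape[0]} counts vs {lengths.shape[0]} lengths"
        )
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("negative count")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(counts), True
    return rate / total * 1e6, False


def tpm_matrix(
    counts: pd.DataFrame, lengths: pd.Series
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Column-wise TPM for a genes x samples count matrix.

    Returns the TPM frame plus the ids of degenerate (all-zero) samples.
    """
    rate = counts.div(lengths.loc[counts.index], axis=0)
    totals = rate.sum(axis=0)
    degenerate = tuple(totals.index[totals == 0])
    safe = totals.replace(0, np.nan)
    tpm = rate.div(safe, axis=1) * 1e6
    return tpm.fillna(0.0), degenerate


def validate_gene_table(genes: pd.DataFrame) -> None:
    """Enforce the annotation invariants; raise ``ValueError`` on violation."""
    if genes.index.has_duplicates:
        dupes = genes.index[genes.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    bad_chrom = set(genes["chromosome"]) - set(CHROMOSOMES)
    if bad_chrom:
        raise ValueError(f"unknown chromosome labels: {sorted(bad_chrom)}")
    if (genes["length_bp"] < 1).any():
        raise ValueError("length_bp must be >= 1")
    par_off_sex = genes["is_par"] & ~genes["chromosome"].isin(["X", "Y"])
    if par_off_sex.any():
        raise ValueError(
            f"is_par set outside X/Y for: {genes.index[par_off_sex].tolist()}"
        )
    marker = genes["is_y_marker"]
    bad_marker = marker & ((genes["chromosome"] != "Y") | genes["is_par"])
    if bad_marker.any():
        raise ValueError(
            "Y-marker genes must be non-PAR Y genes: "
            f"{genes.index[bad_marker].tolist()}"
        )


def validate_sample_table(samples: pd.DataFrame) -> None:
    """Enforce the sample-metadata invariants; raise ``ValueError`` on violation."""
    if samples.index.has_duplicates:
        dupes = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    for col in ("embryo_id", "sample_type"):
        if col not in samples.columns:
            raise ValueError(f"sample metadata missing column: {col}")
    bad_type = set(samples["sample_type"]) - set(SAMPLE_TYPES)
    if bad_type:
        raise ValueError(f"unknown sample_type values: {sorted(bad_type)}")
    per = samples.groupby(["embryo_id", "sample_type"]).size()
    if (per > 1).any():
        key = per[per > 1].index[0]
        raise ValueError(
            f"embryo {key[0]} has more than one {key[1]} RNA sample"
        )
    for col in ("grade_icm", "grade_te"):
        if col in samples.columns:
            vals = samples[col].dropna()
            bad = set(vals) - set(GRADE_LETTERS)
            if bad:
                raise ValueError(f"{col} letters must be A/B/C, got {sorted(bad)}")
    if "pgta_sex" in samples.columns:
        vals = samples["pgta_sex"].dropna()
        bad = set(vals) - set(PGTA_SEXES)
        if bad:
            raise ValueError(f"pgta_sex must be XX/XY/undefined, got {sorted(bad)}")


@dataclass
class ExpressionDataset:
    """Aligned counts + gene annotation + sample metadata (+ derived TPM).

    Construction validates alignment and all schema invariants.  ``tpm`` is
    computed from counts and lengths when not supplied; samples whose library
    is empty are flagged in ``degenerate_samples`` and carry all-zero TPM.
    """

    counts: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame
    tpm: pd.DataFrame | None = None
    provenance: list[FilterRecord] = field(default_factory=list)
    degenerate_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if (self.counts.values < 0).any():
            raise ValueError("negative count in matrix")
        validate_gene_table(self.genes)
        validate_sample_table(self.samples)
        if not self.counts.index.equals(self.genes.index):
            raise ValueError("counts rows and gene annotation are not aligned")
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("counts columns and sample metadata are not aligned")
        if self.tpm is None:
            self.tpm, self.degenerate_samples = tpm_matrix(
                self.counts, self.genes["length_bp"]
            )
        else:
            if self.tpm.shape != self.counts.shape:
                raise ValueError("supplied TPM table shape differs from counts")
            self.tpm = self.tpm.astype(float)

    # -- basic introspection -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_types(self) -> pd.Series:
        return self.samples["sample_type"]

    # -- subsetting (always through here so provenance stays consistent) -----
    def subset_genes(
        self, keep: Sequence[bool] | pd.Series, step: str, params: dict | None = None
    ) -> "ExpressionDataset":
        keep = np.asarray(keep, dtype=bool)
        removed = tuple(self.counts.index[~keep])
        record = FilterRecord(step=step, axis="gene", removed=removed, params=params or {})
        return ExpressionDataset(
            counts=self.counts.loc[keep],
            genes=self.genes.loc[keep],
            samples=self.samples,
            tpm=self.tpm.loc[keep],
            provenance=[*self.provenance, record],
            degenerate_samples=self.degenerate_samples,
        )

    def subset_samples(
        self, keep: Sequence[bool] | pd.Series, step: str, params: dict | None = None
    ) -> "ExpressionDataset":
        keep = np.asarray(keep, dtype=bool)
        removed = tuple(self.counts.columns[~keep])
        record = FilterRecord(step=step, axis="sample", removed=removed, params=params or {})
        return ExpressionDataset(
            counts=self.counts.loc[:, keep],
            genes=self.genes,
            samples=self.samples.loc[keep],
            tpm=self.tpm.loc[:, keep],
            provenance=[*self.provenance, record],
            degenerate_samples=tuple(
                s for s in self.degenerate_samples if s in set(self.counts.columns[keep])
            ),
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            counts=self.counts.copy(),
            genes=self.genes.copy(),
            samples=self.samples.copy(),
            tpm=self.tpm.copy(),
            provenance=list(self.provenance),
            degenerate_samples=self.degenerate_samples,
        )


def empty_sample_columns(samples: pd.DataFrame) -> pd.DataFrame:
    """Add any missing optional metadata columns as explicit nulls."""
    out = samples.copy()
    for col in SAMPLE_COLUMNS:
        if col not in out.columns:
            out[col] = None
    return out
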