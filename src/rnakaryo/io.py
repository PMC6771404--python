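"""Readers and writers for the pipeline's tabular formats.

Counts are accepted either as a tab-separated genes x samples table (header
row of sample ids, first column of gene ids) or as a Matrix Market sparse
triple ``<stem>.mtx`` accompanied by ``<stem>.mtx.rows`` / ``<stem>.mtx.cols``
(one identifier per line).  Annotation and metadata are tab-separated with
named columns.  All result writers emit tab-separated tables plus one
machine-readable JSON run summary.

Identifiers are case-sensitive opaque strings and are never munged;
chromosome labels are stored without a ``chr`` prefix, but readers accept
and strip it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import (
    DEFAULT_PAR_GENES,
    DEFAULT_Y_MARKERS,
    ExpressionDataset,
    empty_sample_columns,
)

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if pd.isna(value):
        return False
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean value {value!r}")


def _strip_chr(label) -> str:
    text = str(label).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    return "MT" if text in {"M", "mt", "m"} else text


def _read_counts(path: Path) -> pd.DataFrame:
    if path.suffix == ".mtx":
        matrix = scipy.io.mmread(path)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        dense = np.asarray(
            matrix.todense() if scipy.sparse.issparse(matrix) else matrix, dtype=float
        )
        if dense.shape != (len(rows), len(cols)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match "
                f"{len(rows)} row names x {len(cols)} column names"
            )
        return pd.DataFrame(dense, index=rows, columns=cols)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def read_annotation(path: Path) -> pd.DataFrame:
    """Read the gene annotation table, filling defaulted flag columns.

    ``is_par`` defaults from the shipped PAR-1/2 gene list for X/Y genes and
    ``is_y_marker`` from the default three-marker set when the columns are
    absent.
    """
    genes = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in genes.columns:
        raise ValueError("annotation must have a gene_id column")
    genes = genes.set_index("gene_id")
    genes.index = genes.index.astype(str)
    genes["chromosome"] = genes["chromosome"].map(_strip_chr)
    genes["length_bp"] = genes["length_bp"].astype(int)
    if "is_par" in genes.columns:
        genes["is_par"] = genes["is_par"].map(_parse_bool).astype(bool)
    else:
        genes["is_par"] = genes.index.isin(DEFAULT_PAR_GENES) & genes[
            "chromosome"
        ].isin(["X", "Y"])
    if "is_y_marker" in genes.columns:
        genes["is_y_marker"] = genes["is_y_marker"].map(_parse_bool).astype(bool)
    else:
        genes["is_y_marker"] = genes.index.isin(DEFAULT_Y_MARKERS)
    return genes


def _parse_chrom_list(value) -> tuple[str, ...] | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text == "":
        return ()
    return tuple(_strip_chr(part) for part in text.split(",") if part.strip())


def read_metadata(path: Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in samples.columns:
        raise ValueError("metadata must have a sample_id column")
    samples = samples.set_index("sample_id")
    samples.index = samples.index.astype(str)
    samples = empty_sample_columns(samples)
    has_pgta = samples["pgta_sex"].notna()
    for col in ("pgta_gains", "pgta_losses"):
        # with a PGT-A result present, an empty gains/losses field is a
        # euploid report (empty tuple), not a missing value
        values = []
        for s in samples.index:
            parsed = _parse_chrom_list(samples.at[s, col])
            if has_pgta[s]:
                values.append(parsed if parsed is not None else ())
            else:
                values.append(parsed)
        samples[col] = pd.Series(values, index=samples.index, dtype=object)
    for col in ("grade_expansion", "harvest_day"):
        samples[col] = pd.to_numeric(samples[col], errors="coerce").astype("Int64")
    return samples


def load_cohort(
    counts_path: str | Path,
    annotation_path: str | Path,
    metadata_path: str | Path,
    tpm_path: str | Path | None = None,
) -> ExpressionDataset:
    """Load and align a cohort from its three (or four) tables.

    Every matrix row id must appear in the annotation and every column id in
    the metadata; gene and sample order is preserved from the counts file.
    A user-supplied TPM table (same layout as counts) overrides the TPM
    derived from counts and lengths.
    """
    counts = _read_counts(Path(counts_path))
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in counts: {dupes[:5]}")
    if counts.columns.has_duplicates:
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in counts: {dupes[:5]}")
    if (counts.values < 0).any():
        raise ValueError("negative count in counts matrix")

    genes = read_annotation(Path(annotation_path))
    missing_genes = counts.index.difference(genes.index)
    if len(missing_genes):
        raise ValueError(
            f"annotation missing gene id(s): {missing_genes.tolist()[:5]}"
        )
    samples = read_metadata(Path(metadata_path))
    missing_samples = counts.columns.difference(samples.index)
    if len(missing_samples):
        raise ValueError(
            f"metadata missing sample id(s): {missing_samples.tolist()[:5]}"
        )

    tpm = None
    if tpm_path is not None:
        tpm = _read_counts(Path(tpm_path)).loc[counts.index, counts.columns]
    return ExpressionDataset(
        counts=counts,
        genes=genes.loc[counts.index],
        samples=samples.loc[counts.columns],
        tpm=tpm,
    )


def write_cohort(dataset: ExpressionDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write counts/annotation/metadata TSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "annotation": out / "annotation.tsv",
        "metadata": out / "metadata.tsv",
    }
    dataset.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    dataset.genes.to_csv(paths["annotation"], sep="\t", index_label="gene_id")
    meta = dataset.samples.copy()
    for col in ("pgta_gains", "pgta_losses"):
        meta[col] = meta[col].map(
            lambda v: ",".join(v) if isinstance(v, tuple) else None
        )
    meta.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    return paths


def write_run_summary(summary: Mapping, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.ndarray, tuple, set, frozenset)):
            return list(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(summary, indent=2, default=_default) + "\n")
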