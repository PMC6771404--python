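"""Quality control for blastocyst RNA-seq cohorts.

Three rules, applied in order:

1. drop spuriously expressed genes — below the expression threshold
   (1 TPM) in *every* sample;
2. drop mitochondrial genes, whose very high abundance would otherwise
   dominate chromosome-level sums;
3. drop low-complexity samples expressing fewer than a minimum number of
   genes (default 5000, roughly a third of a full blastocyst transcriptome).

"Expressed" consistently means TPM >= ``min_tpm_expressed``.  Every removal
is appended to the dataset provenance log with the full list of removed
identifiers, so filtering is exactly reconstructible.  TPM is *not*
recomputed after gene removal by default, matching the convention that TPM
comes from the full upstream quantification; set ``renormalize_tpm`` to
rescale surviving genes back to one million.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, tpm_matrix

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    min_tpm_expressed: float = 1.0
    min_genes_per_sample: int = 5000
    coverage_min_samples: int = 10
    drop_mitochondrial: bool = True
    jackpot_top_k: int = 1
    renormalize_tpm: bool = False

    def __post_init__(self) -> None:
        if self.min_tpm_expressed < 0 or self.min_genes_per_sample < 0:
            raise ValueError("QC thresholds must be >= 0")
        if self.coverage_min_samples < 1:
            raise ValueError("coverage_min_samples must be >= 1")


def apply_gene_filters(
    dataset: ExpressionDataset, config: QCConfig | None = None
) -> ExpressionDataset:
    """Remove spurious (never-expressed) genes and mitochondrial genes.

    A gene survives the spurious-expression rule if it reaches the
    expression threshold in at least one sample; mitochondrial genes are
    removed regardless of expression when ``drop_mitochondrial`` is set.
    Raises if nothing survives.
    """
    config = config or QCConfig()
    spurious = (dataset.tpm >= config.min_tpm_expressed).sum(axis=1) == 0
    out = dataset.subset_genes(
        ~spurious.values,
        step="spurious_genes",
        params={"min_tpm_expressed": config.min_tpm_expressed},
    )
    if config.drop_mitochondrial:
        mito = out.genes["chromosome"] == "MT"
        out = out.subset_genes(~mito.values, step="mitochondrial_genes")
    if out.n_genes == 0:
        raise ValueError("no genes survive QC")
    if config.renormalize_tpm:
        out.tpm, out.degenerate_samples = tpm_matrix(
            out.counts, out.genes["length_bp"]
        )
    return out


def apply_sample_filter(
    dataset: ExpressionDataset, config: QCConfig | None = None
) -> ExpressionDataset:
    """Remove samples expressing fewer than ``min_genes_per_sample`` genes.

    The boundary is read strictly: a sample expressing exactly the minimum
    is retained.  Removing every sample is legal but logged loudly.
    """
    config = config or QCConfig()
    expressed = (dataset.tpm >= config.min_tpm_expressed).sum(axis=0)
    keep = expressed >= config.min_genes_per_sample
    out = dataset.subset_samples(
        keep.values,
        step="low_complexity_samples",
        params={
            "min_genes_per_sample": config.min_genes_per_sample,
            "min_tpm_expressed": config.min_tpm_expressed,
        },
    )
    if out.n_samples == 0:
        logger.warning(
            "sample filter removed every sample (threshold %d genes)",
            config.min_genes_per_sample,
        )
    return out


def qc_pipeline(
    dataset: ExpressionDataset, config: QCConfig | None = None
) -> ExpressionDataset:
    """Gene filters followed by the sample-complexity filter."""
    config = config or QCConfig()
    return apply_sample_filter(apply_gene_filters(dataset, config), config)


def expressed_gene_sets(
    dataset: ExpressionDataset, config: QCConfig | None = None
) -> dict:
    """Expressed-gene sets: cohort-wide and per sample type.

    ``any``: genes expressed (>= threshold TPM) in one or more samples.
    ``per_type``: genes expressed in at least ``coverage_min_samples``
    samples of that type — the stricter transcriptome-coverage definition.
    The any-set is a superset of every per-type set.
    """
    config = config or QCConfig()
    expressed = dataset.tpm >= config.min_tpm_expressed
    any_set = set(dataset.tpm.index[expressed.sum(axis=1) >= 1])
    per_type: dict[str, set] = {}
    for stype in ("WE", "TE"):
        cols = dataset.samples.index[dataset.samples["sample_type"] == stype]
        if len(cols) == 0:
            per_type[stype] = set()
            continue
        n_hit = expressed[cols].sum(axis=1)
        per_type[stype] = set(
            dataset.tpm.index[n_hit >= config.coverage_min_samples]
        ) & any_set
    return {"any": any_set, "per_type": per_type}


def jackpot_fraction(counts_column: np.ndarray, top_k: int = 1) -> float:
    """Fraction of a library contributed by its ``top_k`` largest counts.

    A diagnostic for overamplification of one or a few transcripts during
    low-input library preparation ("jackpotting"); never used as a hard
    filter.  Ties are broken by taking the k largest values regardless of
    gene identity.
    """
    counts = np.asarray(counts_column, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("undefined jackpot on empty library")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    top = np.sort(counts)[::-1][:top_k]
    return float(top.sum() / total)


def qc_report(dataset: ExpressionDataset, config: QCConfig | None = None) -> dict:
    """Per-rule removal counts, per-sample expressed-gene counts and jackpot
    fractions, for the ``qc`` CLI output."""
    config = config or QCConfig()
    expressed = (dataset.tpm >= config.min_tpm_expressed).sum(axis=0)
    jackpot = {
        s: jackpot_fraction(dataset.counts[s].values, config.jackpot_top_k)
        for s in dataset.counts.columns
        if dataset.counts[s].sum() > 0
    }
    per_sample = pd.DataFrame(
        {
            "expressed_genes": expressed,
            "jackpot_fraction": pd.Series(jackpot),
        }
    )
    removals = [
        {
            "step": rec.step,
            "axis": rec.axis,
            "n_removed": rec.n_removed,
            "removed": list(rec.removed),
        }
        for rec in dataset.provenance
    ]
    return {"per_sample": per_sample, "removals": removals}
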