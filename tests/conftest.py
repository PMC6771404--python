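"""Shared fixtures: small hand-built and simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from rnakaryo import ExpressionDataset, QCConfig, SimulationConfig, simulate_cohort

#: QC thresholds scaled to the synthetic genome (50 genes/chromosome).
SCALED_QC = QCConfig(min_genes_per_sample=500)


def make_dataset(counts, chromosomes, lengths=None, sample_types=None, tpm=None,
                 **gene_flags):
    """Build a validated ExpressionDataset from plain dicts/arrays.

    ``counts`` is a mapping sample_id -> list of counts; gene order follows
    ``chromosomes`` (mapping gene_id -> chromosome label).
    """
    gene_ids = list(chromosomes)
    genes = pd.DataFrame(
        {
            "chromosome": [chromosomes[g] for g in gene_ids],
            "length_bp": lengths if lengths is not None else [1000] * len(gene_ids),
            "is_par": gene_flags.get("is_par", [False] * len(gene_ids)),
            "is_y_marker": gene_flags.get("is_y_marker", [False] * len(gene_ids)),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    count_frame = pd.DataFrame(counts, index=genes.index, dtype=float)
    sample_ids = list(count_frame.columns)
    stypes = sample_types or {s: "WE" for s in sample_ids}
    samples = pd.DataFrame(
        {
            "embryo_id": [f"EMB{i}" for i in range(len(sample_ids))],
            "sample_type": [stypes[s] for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    tpm_frame = None
    if tpm is not None:
        tpm_frame = pd.DataFrame(tpm, index=genes.index, dtype=float)
    return ExpressionDataset(
        counts=count_frame, genes=genes, samples=samples, tpm=tpm_frame
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 8-embryo cohort with one trisomy-16 embryo."""
    config = SimulationConfig(
        n_embryos=8,
        p_te_pair=1.0,
        aneuploidies={0: [("16", 3)]},
        seed=11,
    )
    return simulate_cohort(config)
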