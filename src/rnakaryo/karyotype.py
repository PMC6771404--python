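"""RNA digital karyotype: chromosome-level expression Z-scores.

The model treats each chromosome as one transcriptional unit.  For every
sample, counts of the genes on a chromosome are summed and divided by the
sample's total depth over all included genes ("normcount", a share in
[0, 1]; shares sum to 1 per sample).  For each chromosome, the mean and SD
of that share across all QC-passing samples *of the same sample type* give
a Z-score per sample.  A permissive call flags |Z| > 2 as a candidate gain
(Z > 2) or loss (Z < -2) — under normality the +/-2 band covers ~95% of
euploid observations.  A stringent call additionally requires a small
permutation p-value: chromosome labels are reshuffled across genes
(preserving each chromosome's gene count), the full Z computation is
repeated B times (default 3000), and

    p = (1 + #{b : |z_b| >= |z_obs|}) / (B + 1)

two-sided on |Z|, with the add-one estimator so p is never zero.

Mitochondrial genes must already be removed (QC), pseudoautosomal genes are
excluded from the X and Y sums, and Y is excluded from karyotyping entirely
— its near-zero expression in XX samples breaks the normal-share model and
its presence/absence is handled by the sex-calling module instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import AUTOSOMES, ExpressionDataset

#: Chromosomes receiving Z-scores: autosomes plus X.
KARYOTYPE_CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X",)


@dataclass
class KaryotypeConfig:
    z_cutoff: float = 2.0
    n_shuffles: int = 3000
    alpha: float = 0.05
    shuffle_pool: str = "autosomes+X"  # or "autosomes"
    seed: int = 0
    sd_mode: str = "sample"  # unbiased n-1 SD; "population" uses n

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.shuffle_pool not in ("autosomes", "autosomes+X"):
            raise ValueError("shuffle_pool must be 'autosomes' or 'autosomes+X'")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError("sd_mode must be 'sample' or 'population'")

    @property
    def ddof(self) -> int:
        return 1 if self.sd_mode == "sample" else 0


def included_gene_mask(dataset: ExpressionDataset) -> pd.Series:
    """Genes entering the karyotype: autosomes + non-PAR X genes."""
    genes = dataset.genes
    on_pool = genes["chromosome"].isin(KARYOTYPE_CHROMOSOMES)
    return on_pool & ~genes["is_par"]


def chromosome_normcounts(
    dataset: ExpressionDataset, sample: str | None = None
) -> pd.Series | pd.DataFrame:
    """Per-chromosome count shares for one sample (or all samples).

    Depth is the sample's total count over all included genes, so shares
    sum to 1 over the included chromosomes.  Chromosomes with no annotated
    genes are absent from the result.  Raises on a zero-depth sample.
    """
    mask = included_gene_mask(dataset)
    counts = dataset.counts.loc[mask.values]
    chroms = dataset.genes.loc[mask.values, "chromosome"]
    sums = counts.groupby(chroms, sort=False).sum()
    present = [c for c in KARYOTYPE_CHROMOSOMES if c in sums.index]
    sums = sums.loc[present]
    depth = sums.sum(axis=0)
    zero = depth.index[depth == 0]
    if len(zero):
        raise ValueError(f"zero-depth sample(s): {zero.tolist()}")
    shares = (sums / depth).T  # samples x chromosomes
    if sample is not None:
        return shares.loc[sample]
    return shares


def compute_zscores(
    normcounts: pd.DataFrame,
    sample_types: Mapping[str, str] | pd.Series,
    config: KaryotypeConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort Z-scores per sample type.

    ``normcounts`` is samples x chromosomes.  For each sample type with at
    least two samples, z = (x - mean) / sd column-wise within the type; a
    zero-variance column yields z = 0 with the degenerate flag set.  Types
    with fewer than two samples are skipped (error only if no type is
    scorable).

    Returns ``(z, degenerate)``, both samples x chromosomes; ``degenerate``
    is boolean.
    """
    config = config or KaryotypeConfig()
    types = pd.Series(sample_types).loc[normcounts.index]
    z = pd.DataFrame(np.nan, index=normcounts.index, columns=normcounts.columns)
    degenerate = pd.DataFrame(
        False, index=normcounts.index, columns=normcounts.columns
    )
    scored_any = False
    for stype, block in normcounts.groupby(types, sort=False):
        if block.shape[0] < 2:
            warnings.warn(
                f"sample type {stype!r} has < 2 samples; no Z-scores for it",
                stacklevel=2,
            )
            continue
        scored_any = True
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=config.ddof)
        zero_sd = sd == 0
        safe_sd = sd.replace(0, np.nan)
        zb = (block - mean) / safe_sd
        zb.loc[:, zero_sd] = 0.0
        z.loc[block.index] = zb
        degenerate.loc[block.index, zero_sd[zero_sd].index] = True
    if not scored_any:
        raise ValueError(
            "no sample type has the >= 2 samples required for Z-scores"
        )
    return z, degenerate


def call_outliers(
    z: pd.DataFrame, config: KaryotypeConfig | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Permissive gain/loss calls from the Z table (strict inequalities).

    Returns a samples x chromosomes frame of labels in
    {euploid, gain, loss} and a per-sample ploidy label ("aneuploid" iff at
    least one non-euploid chromosome).
    """
    config = config or KaryotypeConfig()
    calls = pd.DataFrame("euploid", index=z.index, columns=z.columns)
    calls = calls.mask(z > config.z_cutoff, "gain")
    calls = calls.mask(z < -config.z_cutoff, "loss")
    calls[z.isna()] = "euploid"
    ploidy = (calls != "euploid").any(axis=1).map(
        {True: "aneuploid", False: "euploid"}
    )
    return calls, ploidy


def _prep_pool(dataset: ExpressionDataset, config: KaryotypeConfig):
    """Count matrix restricted to shuffle-pool genes plus chromosome labels."""
    pool_chroms = (
        KARYOTYPE_CHROMOSOMES if config.shuffle_pool == "autosomes+X" else AUTOSOMES
    )
    mask = included_gene_mask(dataset) & dataset.genes["chromosome"].isin(pool_chroms)
    counts = dataset.counts.loc[mask.values].values
    labels = dataset.genes.loc[mask.values, "chromosome"].values
    chrom_order = [c for c in pool_chroms if c in set(labels)]
    if len(chrom_order) < 2:
        raise ValueError("shuffle pool must span at least 2 chromosomes")
    return counts, labels, chrom_order


def _zscores_array(
    shares: np.ndarray, type_groups: list[np.ndarray], ddof: int
) -> np.ndarray:
    """Plain ndarray Z-scores, mean/SD within each sample-type row group."""
    z = np.zeros_like(shares)
    for rows in type_groups:
        block = shares[rows]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=ddof)
        with np.errstate(invalid="ignore", divide="ignore"):
            zb = (block - mean) / sd
        zb[:, sd == 0] = 0.0
        z[rows] = zb
    return z


def bootstrap_pvalues(
    dataset: ExpressionDataset,
    z_obs: pd.DataFrame,
    config: KaryotypeConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Label-shuffling permutation p-values for the observed Z table.

    Each replicate permutes the gene -> chromosome assignment within the
    shuffle pool (each chromosome keeps its gene count), recomputes shares
    and Z-scores over the full same-type cohort, and tallies replicates at
    least as extreme (two-sided, |z_b| >= |z_obs|).  The returned p-values
    lie in [1/(B+1), 1] and are reproducible for a fixed seed.
    """
    config = config or KaryotypeConfig()
    rng = rng or np.random.default_rng(config.seed)
    counts, labels, chrom_order = _prep_pool(dataset, config)

    types = dataset.samples["sample_type"]
    scorable = types.map(types.value_counts()) >= 2
    sample_ids = [s for s in dataset.counts.columns if scorable[s]]
    col_idx = [dataset.counts.columns.get_loc(s) for s in sample_ids]
    counts = counts[:, col_idx]
    type_vals = types.loc[sample_ids].values
    type_groups = [
        np.flatnonzero(type_vals == t) for t in pd.unique(type_vals)
    ]

    # sort genes so each chromosome occupies one contiguous block; a label
    # shuffle is then a row permutation + fixed-offset block sums
    chrom_index = {c: i for i, c in enumerate(chrom_order)}
    order = np.argsort([chrom_index[c] for c in labels], kind="stable")
    counts = counts[order]
    sizes = np.bincount(
        [chrom_index[c] for c in labels], minlength=len(chrom_order)
    )
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    depth = counts.sum(axis=0)
    if np.any(depth == 0):
        raise ValueError("zero-depth sample in shuffle pool")

    z_obs_arr = np.abs(
        z_obs.loc[sample_ids, chrom_order].fillna(0.0).values
    )
    extreme = np.zeros_like(z_obs_arr)
    n_genes = counts.shape[0]
    # ties at float precision count as extreme (standard permutation-test
    # convention; otherwise ~1e-16 rounding breaks exact-tie replicates)
    tie_tol = 1e-9
    for _ in range(config.n_shuffles):
        perm = rng.permutation(n_genes)
        sums = np.add.reduceat(counts[perm], offsets, axis=0)  # chrom x sample
        shares = (sums / depth).T  # sample x chrom
        z_b = _zscores_array(shares, type_groups, config.ddof)
        extreme += np.abs(z_b) >= z_obs_arr - tie_tol
    p = (1.0 + extreme) / (config.n_shuffles + 1.0)
    out = pd.DataFrame(np.nan, index=z_obs.index, columns=z_obs.columns)
    out.loc[sample_ids, chrom_order] = p
    return out


def stringent_karyotype(
    calls: pd.DataFrame, p: pd.DataFrame, config: KaryotypeConfig | None = None
) -> pd.DataFrame:
    """Significance flags: a permissive outlier whose permutation p <= alpha.

    The permissive and stringent views are complementary: the +/-2 band is a
    sensitive first pass, while the shuffled null guards against samples
    whose expression is noisy across many chromosomes (a broad null makes
    every chromosome non-significant)."""
    config = config or KaryotypeConfig()
    return (calls != "euploid") & (p <= config.alpha)


def digital_karyotype(
    dataset: ExpressionDataset,
    config: KaryotypeConfig | None = None,
    rng: np.random.Generator | None = None,
    with_pvalues: bool = True,
) -> dict:
    """Full digital karyotype for a QC-filtered dataset.

    Returns a dict with ``normcounts``, ``z``, ``degenerate_sd``, ``calls``,
    ``ploidy`` (all samples x chromosomes or per-sample), plus ``p`` and
    ``significant`` when ``with_pvalues``, and ``long`` — the tidy
    per-(sample, chromosome) table the CLI writes.
    """
    config = config or KaryotypeConfig()
    shares = chromosome_normcounts(dataset)
    z, degenerate = compute_zscores(shares, dataset.samples["sample_type"], config)
    calls, ploidy = call_outliers(z, config)
    result = {
        "normcounts": shares,
        "z": z,
        "degenerate_sd": degenerate,
        "calls": calls,
        "ploidy": ploidy,
    }
    if with_pvalues:
        p = bootstrap_pvalues(dataset, z, config, rng=rng)
        result["p"] = p
        result["significant"] = stringent_karyotype(calls, p, config)
    rows = []
    for s in shares.index:
        for c in shares.columns:
            rows.append(
                {
                    "sample_id": s,
                    "chromosome": c,
                    "normcount": shares.at[s, c],
                    "zscore": z.at[s, c],
                    "call": calls.at[s, c],
                    "p_boot": result["p"].at[s, c] if with_pvalues else np.nan,
                    "significant": bool(result["significant"].at[s, c])
                    if with_pvalues
                    else False,
                    "degenerate_sd": bool(degenerate.at[s, c]),
                }
            )
    result["long"] = pd.DataFrame(rows)
    return result
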