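"""Synthetic blastocyst cohorts with known sex, karyotype and mosaicism.

The generator emulates the structure the analysis assumes, on a scaled-down
genome (default 50 genes per chromosome over 1..22, X, Y, MT and ~1e6 reads
per library, standing in for cohorts sequenced to tens of millions of
reads): whole-embryo (WE) samples of 60-100 cells, trophectoderm (TE)
biopsies of 3-7 cells, XX/XY sexes, whole-chromosome gains and losses with
linear dosage (copy 3 -> 1.5x, copy 1 -> 0.5x expression), mosaic cell
mixtures, and partial X dosage compensation.

Counts are negative binomial.  Per-gene baseline rates lambda_g are drawn
once per cohort from a log-normal, so cohort-level Z-scores see only
counting noise plus true dosage differences.  A sample's expected counts
are

    mu_g = depth * r_g / sum_h r_h,     r_g = lambda_g * L_g * d_g * j_e,c

where the dose d_g mixes the embryo's cell populations weighted by the
fractions actually sampled into that library (a TE biopsy of 3-7 cells
draws its mixture multinomially, so mosaic embryos naturally produce
discordant WE/TE fixtures), and j_e,c is an optional per-embryo,
per-chromosome log-normal dosage jitter shared between the embryo's WE and
TE samples (biological covariation; powers the paired-correlation
analysis).  X genes in an XX population carry dose (1 + alpha)/2 with
alpha the X-inactivation attenuation (alpha=1 full escape, 0 full
silencing); Y genes have dose 0 without a Y; pseudoautosomal genes count
copies from both sex chromosomes; mitochondrial genes run at an elevated
rate so the MT filter is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AUTOSOMES,
    CHROMOSOMES,
    DEFAULT_Y_MARKERS,
    ExpressionDataset,
    empty_sample_columns,
)
from .morphokinetics import (
    DEFAULT_CLINICAL_REFERENCE,
    EVENTS,
    MorphokineticTimeline,
    ReferenceTimeline,
)


@dataclass
class SimulationConfig:
    n_embryos: int = 35
    p_te_pair: float = 0.55
    sex_ratio: float = 0.5  # probability of XY
    genes_per_chromosome: int = 50
    y_marker_count: int = 3
    par_genes_per_chromosome: int = 4
    aneuploidies: Mapping[int | str, Sequence[tuple[str, int]]] | None = None
    aneuploidy_rate: float = 0.0
    mosaic_fraction: float | Mapping[int | str, float] = 0.0
    cells_we: tuple[int, int] = (60, 100)
    cells_te: tuple[int, int] = (3, 7)
    depth_we: float = 1_000_000.0
    depth_te: float = 1_000_000.0
    nb_dispersion: float = 0.1
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    length_log_mean: float = 7.3  # ~1.5 kb transcripts
    length_log_sd: float = 0.4
    mt_rate_multiplier: float = 3.0
    y_marker_rate_multiplier: float = 5.0
    xci_attenuation: float = 0.8
    dosage_jitter_sd: float = 0.0
    p_pgta: float = 0.55
    p_aberrant_morphokinetics: float = 0.6
    morphokinetic_displacement_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_te_pair", "sex_ratio", "aneuploidy_rate", "p_pgta",
                     "p_aberrant_morphokinetics"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.xci_attenuation <= 1:
            raise ValueError("xci_attenuation must lie in [0, 1]")
        for name in ("cells_we", "cells_te"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty")
        if self.aneuploidies is not None:
            for key, entries in self.aneuploidies.items():
                for chrom, copy in entries:
                    if str(chrom) not in CHROMOSOMES:
                        raise ValueError(f"unknown chromosome {chrom!r}")
                    if copy not in (1, 3):
                        raise ValueError(
                            f"copy_number must be 1 or 3, got {copy}"
                        )
        if isinstance(self.mosaic_fraction, (int, float)):
            if not 0 <= self.mosaic_fraction < 1:
                raise ValueError("mosaic_fraction must lie in [0, 1)")


@dataclass
class EmbryoTruth:
    embryo_id: str
    sex: str  # XX / XY
    #: list of (karyotype: chromosome -> copy number, cell fraction)
    populations: tuple[tuple[dict[str, int], float], ...]
    aberrant_morphokinetics: bool | None = None


@dataclass
class SimulationTruth:
    embryos: dict[str, EmbryoTruth]
    samples: pd.DataFrame  # sample_id, embryo_id, sample_type, depth, n_cells


def _base_karyotype(sex: str) -> dict[str, int]:
    kary = {c: 2 for c in AUTOSOMES}
    kary["X"] = 2 if sex == "XX" else 1
    kary["Y"] = 0 if sex == "XX" else 1
    return kary


def build_gene_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Scaled-down genome annotation covering every QC/sexing code path."""
    rows = []
    for chrom in CHROMOSOMES:
        n_par = (
            config.par_genes_per_chromosome if chrom in ("X", "Y") else 0
        )
        marker_names: list[str] = []
        if chrom == "Y":
            marker_names = list(DEFAULT_Y_MARKERS[: config.y_marker_count])
            marker_names += [
                f"YM{i}" for i in range(len(marker_names), config.y_marker_count)
            ]
        n_plain = config.genes_per_chromosome - n_par - len(marker_names)
        if n_plain < 0:
            raise ValueError("genes_per_chromosome too small for PAR/marker genes")
        for i in range(n_par):
            rows.append((f"PAR{chrom}_{i:02d}", chrom, True, False))
        for name in marker_names:
            rows.append((name, chrom, False, True))
        for i in range(n_plain):
            rows.append((f"G{chrom}_{i:03d}", chrom, False, False))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "is_par", "is_y_marker"]
    ).set_index("gene_id")
    genes["length_bp"] = np.maximum(
        rng.lognormal(config.length_log_mean, config.length_log_sd, len(genes)),
        200.0,
    ).astype(int)
    return genes[["chromosome", "length_bp", "is_par", "is_y_marker"]]


def draw_baseline_rates(
    genes: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    lam = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, len(genes)
    )
    lam[genes["chromosome"].values == "MT"] *= config.mt_rate_multiplier
    lam[genes["is_y_marker"].values] *= config.y_marker_rate_multiplier
    return lam


def _population_dose(
    genes: pd.DataFrame, karyotype: Mapping[str, int], alpha: float
) -> np.ndarray:
    """Per-gene expression dose for one cell population (euploid = 1)."""
    chrom = genes["chromosome"].values
    is_par = genes["is_par"].values
    n_x = karyotype.get("X", 2)
    n_y = karyotype.get("Y", 0)
    dose = np.empty(len(genes), dtype=float)
    for i, c in enumerate(chrom):
        if c == "MT":
            dose[i] = 1.0
        elif is_par[i]:
            dose[i] = (n_x + n_y) / 2.0
        elif c == "Y":
            dose[i] = float(n_y)
        elif c == "X":
            dose[i] = 0.0 if n_x == 0 else (1.0 + alpha * (n_x - 1)) / 2.0
        else:
            dose[i] = karyotype.get(c, 2) / 2.0
    return dose


def simulate_expression_counts(
    genes: pd.DataFrame,
    lam: np.ndarray,
    populations: Sequence[tuple[Mapping[str, int], float]],
    fractions: Sequence[float],
    depth: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    jitter: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Negative-binomial counts for one library.

    ``fractions`` are the cell-population fractions actually sampled into
    the library (they override the truth fractions in ``populations``,
    which are used only for the dose of each population's karyotype).
    """
    dose = np.zeros(len(genes), dtype=float)
    for (karyotype, _), f in zip(populations, fractions):
        if f > 0:
            dose += f * _population_dose(genes, karyotype, config.xci_attenuation)
    rate = lam * genes["length_bp"].values * dose
    if jitter is not None:
        rate = rate * genes["chromosome"].map(jitter).values
    total = rate.sum()
    if total == 0:
        raise ValueError("all-zero rate vector")
    mu = depth * rate / total
    if config.nb_dispersion == 0:
        return rng.poisson(mu).astype(float)
    shape = 1.0 / config.nb_dispersion
    return rng.negative_binomial(shape, shape / (shape + mu)).astype(float)


def _embryo_aneuploidies(
    config: SimulationConfig, index: int, embryo_id: str, rng: np.random.Generator
) -> list[tuple[str, int]]:
    if config.aneuploidies is not None:
        for key in (index, embryo_id):
            if key in config.aneuploidies:
                return [(str(c), int(k)) for c, k in config.aneuploidies[key]]
        return []
    if config.aneuploidy_rate > 0 and rng.random() < config.aneuploidy_rate:
        chrom = rng.choice(AUTOSOMES)
        copy = int(rng.choice([1, 3]))
        return [(str(chrom), copy)]
    return []


def _mosaic_fraction_for(config: SimulationConfig, index: int, embryo_id: str) -> float:
    mf = config.mosaic_fraction
    if isinstance(mf, Mapping):
        return float(mf.get(index, mf.get(embryo_id, 0.0)))
    return float(mf)


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Generate a full cohort and its ground truth.

    Every embryo contributes a WE sample; a fraction ``p_te_pair``
    additionally contribute a paired TE biopsy.  Identical seeds give
    bit-identical outputs.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genes = build_gene_table(config, rng)
    lam = draw_baseline_rates(genes, config, rng)

    jitter_chroms = list(CHROMOSOMES)
    embryos: dict[str, EmbryoTruth] = {}
    sample_rows = []
    count_cols = {}
    meta_rows = []
    for i in range(config.n_embryos):
        embryo_id = f"E{i + 1}"
        sex = "XY" if rng.random() < config.sex_ratio else "XX"
        base = _base_karyotype(sex)
        primary = dict(base)
        for chrom, copy in _embryo_aneuploidies(config, i, embryo_id, rng):
            primary[chrom] = copy
        mf = _mosaic_fraction_for(config, i, embryo_id)
        if mf > 0:
            if primary != base:
                alternate = dict(base)  # euploid lineage alongside aneuploid
            elif sex == "XY":
                alternate = dict(base)
                alternate["Y"] = 0  # Y loss, the most common mitotic error
            else:
                alternate = dict(base)
                alternate[str(rng.choice(AUTOSOMES))] = 3
            populations = ((primary, 1.0 - mf), (alternate, mf))
        else:
            populations = ((primary, 1.0),)
        embryos[embryo_id] = EmbryoTruth(embryo_id, sex, populations)

        jitter = None
        if config.dosage_jitter_sd > 0:
            vals = np.exp(
                rng.normal(0.0, config.dosage_jitter_sd, len(jitter_chroms))
            )
            jitter = dict(zip(jitter_chroms, vals))

        has_te = rng.random() < config.p_te_pair
        for stype, present in (("WE", True), ("TE", has_te)):
            if not present:
                continue
            lo, hi = config.cells_we if stype == "WE" else config.cells_te
            n_cells = int(rng.integers(lo, hi + 1))
            truth_fracs = np.array([f for _, f in populations])
            drawn = rng.multinomial(n_cells, truth_fracs)
            fractions = drawn / n_cells
            depth = config.depth_we if stype == "WE" else config.depth_te
            sample_id = f"{embryo_id}_{stype}"
            counts = simulate_expression_counts(
                genes, lam, populations, fractions, depth, config, rng, jitter
            )
            count_cols[sample_id] = counts
            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "embryo_id": embryo_id,
                    "sample_type": stype,
                    "depth": float(counts.sum()),
                    "n_cells": n_cells,
                    "population_fractions": ";".join(
                        f"{f:.6g}" for f in fractions
                    ),
                }
            )
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "embryo_id": embryo_id,
                    "sample_type": stype,
                    "harvest_day": int(rng.integers(5, 8)),
                }
            )

        # embryo-level PGT-A from the majority population's karyotype
        if rng.random() < config.p_pgta:
            major = max(populations, key=lambda pk: pk[1])[0]
            gains = tuple(c for c in AUTOSOMES if major.get(c, 2) > 2)
            losses = tuple(c for c in AUTOSOMES if major.get(c, 2) < 2)
            pgta_sex = "XY" if major.get("Y", 0) > 0 else "XX"
            for row in meta_rows:
                if row["embryo_id"] == embryo_id:
                    row["pgta_sex"] = pgta_sex
                    row["pgta_gains"] = gains
                    row["pgta_losses"] = losses

    counts = pd.DataFrame(count_cols, index=genes.index)
    samples = (
        pd.DataFrame(meta_rows).set_index("sample_id").pipe(empty_sample_columns)
    )
    for col in ("pgta_gains", "pgta_losses"):
        samples[col] = samples[col].where(samples[col].notna(), None)
    dataset = ExpressionDataset(counts=counts, genes=genes, samples=samples)
    truth = SimulationTruth(
        embryos=embryos, samples=pd.DataFrame(sample_rows).set_index("sample_id")
    )
    return dataset, truth


def simulate_morphokinetics(
    truth: SimulationTruth,
    config: SimulationConfig | None = None,
    reference: ReferenceTimeline | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, MorphokineticTimeline]:
    """Timelines per embryo, with aberrance labels written into the truth.

    Non-aberrant embryos are drawn within +/-1 SD of every reference mean
    (uniform on +/-0.95 SD); aberrant embryos have two randomly chosen
    events displaced by ``morphokinetic_displacement_sigma`` SD (late),
    which must exceed 1 or the label could not be guaranteed.  Times are
    made nondecreasing by a running maximum, which can only add deviations.
    """
    config = config or SimulationConfig()
    reference = reference or DEFAULT_CLINICAL_REFERENCE
    missing = [e for e in EVENTS if e not in reference.stats]
    if missing:
        raise ValueError(f"reference must cover all events; missing {missing}")
    if config.morphokinetic_displacement_sigma <= 1:
        raise ValueError(
            "displacement multiple must be > 1 SD to guarantee the aberrant label"
        )
    rng = rng or np.random.default_rng(config.seed + 1)
    timelines: dict[str, MorphokineticTimeline] = {}
    for embryo_id, emb in truth.embryos.items():
        aberrant = bool(rng.random() < config.p_aberrant_morphokinetics)
        emb.aberrant_morphokinetics = aberrant
        displaced = (
            set(rng.choice(len(EVENTS), size=2, replace=False)) if aberrant else set()
        )
        times = []
        for k, event in enumerate(EVENTS):
            mean, sd, _ = reference.stats[event]
            if k in displaced:
                t = mean + config.morphokinetic_displacement_sigma * sd
            else:
                t = mean + rng.uniform(-0.95, 0.95) * sd
            times.append(t)
        times = np.maximum.accumulate(times)
        timelines[embryo_id] = MorphokineticTimeline(
            embryo_id, dict(zip(EVENTS, map(float, times)))
        )
    return timelines


def truth_frame(truth: SimulationTruth) -> pd.DataFrame:
    """Serializable per-embryo truth table (for ``truth.tsv``)."""
    rows = []
    for embryo_id, emb in truth.embryos.items():
        pops = []
        for karyotype, f in emb.populations:
            abn = [
                f"{c}:{k}"
                for c, k in karyotype.items()
                if _base_karyotype(emb.sex).get(c) != k
            ]
            pops.append(f"{'+'.join(abn) if abn else 'euploid'}@{f:g}")
        rows.append(
            {
                "embryo_id": embryo_id,
                "sex": emb.sex,
                "populations": ";".join(pops),
                "aberrant_morphokinetics": emb.aberrant_morphokinetics,
            }
        )
    return pd.DataFrame(rows).set_index("embryo_id")
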