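"""Benchmark experiments on synthetic cohorts.

Each function runs the full pipeline on generated data with known truth and
measures one operating characteristic of the method: aneuploidy-recovery
sensitivity and false-flag rate of the permissive |Z| > 2 call, calibration
of the label-shuffling permutation null, sex-call accuracy, and the power
of the paired-vs-unpaired biopsy concordance test.  Multi-seed experiments
derive per-replicate seeds from ``base_seed`` so a single integer
reproduces the whole experiment.
"""

from __future__ import annotations

import numpy as np

from .concordance import zprofile_correlations
from .karyotype import (
    KaryotypeConfig,
    bootstrap_pvalues,
    call_outliers,
    chromosome_normcounts,
    compute_zscores,
)
from .qc import QCConfig, qc_pipeline
from .sexing import call_cohort_sex
from .simulate import SimulationConfig, simulate_cohort

#: Sample-complexity threshold scaled to the 50-genes-per-chromosome genome
#: (the clinical 5000-gene rule assumes a full transcriptome).
SCALED_QC = QCConfig(min_genes_per_sample=500)


def _sub_seed(base_seed: int, i: int) -> int:
    return int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % (2**31))


def aneuploidy_recovery(
    n_embryos: int = 30,
    n_gain: int = 5,
    n_loss: int = 5,
    gain_chrom: str = "16",
    loss_chrom: str = "4",
    seeds: int = 20,
    base_seed: int = 0,
    config_kwargs: dict | None = None,
) -> dict:
    """Permissive-call recovery of whole-chromosome gains and losses.

    Simulates WE-only cohorts in which ``n_gain`` embryos carry a copy-3
    chromosome and ``n_loss`` a copy-1 chromosome, and measures, averaged
    over seeds, the fraction of truly affected (sample, chromosome) cells
    receiving a non-euploid |Z| > 2 call (sensitivity) and the fraction of
    euploid cells flagged (false-flag rate).
    """
    aneuploidies = {i: [(gain_chrom, 3)] for i in range(n_gain)}
    aneuploidies |= {n_gain + i: [(loss_chrom, 1)] for i in range(n_loss)}
    sens, fpr = [], []
    for i in range(seeds):
        config = SimulationConfig(
            n_embryos=n_embryos,
            p_te_pair=0.0,
            aneuploidies=aneuploidies,
            seed=_sub_seed(base_seed, i),
            **(config_kwargs or {}),
        )
        dataset, truth = simulate_cohort(config)
        filtered = qc_pipeline(dataset, SCALED_QC)
        shares = chromosome_normcounts(filtered)
        z, _ = compute_zscores(shares, filtered.samples["sample_type"])
        calls, _ = call_outliers(z)
        # truly affected cells: the spec'd autosomal gains/losses (X dosage
        # differs by sex and is scored by the sexing module, not here)
        affected = np.zeros(calls.shape, dtype=bool)
        for sample in calls.index:
            embryo = filtered.samples.at[sample, "embryo_id"]
            karyotype = truth.embryos[embryo].populations[0][0]
            for j, chrom in enumerate(calls.columns):
                if chrom != "X" and karyotype.get(chrom, 2) != 2:
                    affected[calls.index.get_loc(sample), j] = True
        flagged = (calls != "euploid").values
        sens.append(flagged[affected].mean())
        fpr.append(flagged[~affected].mean())
    return {
        "sensitivity": float(np.mean(sens)),
        "false_flag_rate": float(np.mean(fpr)),
        "n_cells_affected": int(affected.sum()),
        "n_seeds": seeds,
    }


def null_calibration(
    n_embryos: int = 20,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    seeds: int = 10,
    base_seed: int = 0,
) -> dict:
    """Permutation-null calibration on all-euploid cohorts.

    Measures the fraction of (sample, chromosome) cells with p <= alpha;
    for a calibrated null this sits near alpha (slightly below, because of
    the add-one estimator).  Also reports the observed p-value range, which
    must respect [1/(B+1), 1].
    """
    fractions, p_min, p_max = [], 1.0, 0.0
    for i in range(seeds):
        config = SimulationConfig(
            n_embryos=n_embryos, p_te_pair=0.0, seed=_sub_seed(base_seed, i)
        )
        dataset, _ = simulate_cohort(config)
        filtered = qc_pipeline(dataset, SCALED_QC)
        kconfig = KaryotypeConfig(
            n_shuffles=n_shuffles, seed=_sub_seed(base_seed, 10_000 + i)
        )
        shares = chromosome_normcounts(filtered)
        z, _ = compute_zscores(shares, filtered.samples["sample_type"], kconfig)
        p = bootstrap_pvalues(filtered, z, kconfig)
        vals = p.values[~np.isnan(p.values)]
        fractions.append(float((vals <= alpha).mean()))
        p_min, p_max = min(p_min, vals.min()), max(p_max, vals.max())
    return {
        "fraction_p_le_alpha": float(np.mean(fractions)),
        "p_min": float(p_min),
        "p_max": float(p_max),
        "n_shuffles": n_shuffles,
        "n_seeds": seeds,
    }


def sex_recovery(n_embryos: int = 40, base_seed: int = 0) -> dict:
    """Sex-call accuracy on a non-mosaic cohort with paired biopsies."""
    config = SimulationConfig(
        n_embryos=n_embryos, p_te_pair=1.0, seed=_sub_seed(base_seed, 0)
    )
    dataset, truth = simulate_cohort(config)
    filtered = qc_pipeline(dataset, SCALED_QC)
    calls = call_cohort_sex(filtered)
    correct = {"WE": [], "TE": []}
    false_y_in_xx = 0
    for call in calls:
        embryo = filtered.samples.at[call.sample_id, "embryo_id"]
        stype = filtered.samples.at[call.sample_id, "sample_type"]
        true_sex = truth.embryos[embryo].sex
        correct[stype].append(call.call == true_sex)
        if true_sex == "XX" and call.y_sum_tpm > 25.0:
            false_y_in_xx += 1
    return {
        "accuracy_we": float(np.mean(correct["WE"])),
        "accuracy_te": float(np.mean(correct["TE"])),
        "false_y_detections_in_xx": false_y_in_xx,
        "n_samples": len(calls),
    }


def paired_concordance_power(
    n_pairs: int = 14,
    seeds: int = 50,
    dosage_jitter_sd: float = 0.05,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Power of the one-sided paired > unpaired correlation test.

    Embryo-level chromosomal dosage jitter shared between an embryo's WE
    and TE samples induces the biological covariation that makes paired
    Z-profiles correlate; the experiment measures how often the one-sided
    test rejects at ``alpha`` across seeds.
    """
    rejections, paired_r, unpaired_r = [], [], []
    for i in range(seeds):
        config = SimulationConfig(
            n_embryos=n_pairs,
            p_te_pair=1.0,
            dosage_jitter_sd=dosage_jitter_sd,
            seed=_sub_seed(base_seed, i),
        )
        dataset, _ = simulate_cohort(config)
        filtered = qc_pipeline(dataset, SCALED_QC)
        shares = chromosome_normcounts(filtered)
        z, _ = compute_zscores(shares, filtered.samples["sample_type"])
        types = filtered.samples["sample_type"]
        pairing = {}
        for embryo, group in filtered.samples.groupby("embryo_id"):
            by_type = {group.at[s, "sample_type"]: s for s in group.index}
            if "WE" in by_type and "TE" in by_type:
                pairing[by_type["TE"]] = by_type["WE"]
        out = zprofile_correlations(
            z.loc[types == "WE"], z.loc[types == "TE"], pairing
        )
        rejections.append(out["test_p"] < alpha)
        paired_r.append(np.mean(out["paired_r"]))
        unpaired_r.append(np.mean(out["unpaired_r"]))
    return {
        "power": float(np.mean(rejections)),
        "mean_paired_r": float(np.mean(paired_r)),
        "mean_unpaired_r": float(np.mean(unpaired_r)),
        "n_pairs": n_pairs,
        "n_seeds": seeds,
    }
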