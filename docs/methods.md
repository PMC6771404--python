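# Methods

## Model and assumptions

The digital karyotype treats each chromosome of each sample as a single
transcriptional unit. Its core assumption is that, across a cohort of
comparable samples, the fraction of a library's reads mapping to one
chromosome ("normcount") is approximately stable, so a whole-chromosome
dosage change (copy 3 ≈ 1.5×, copy 1 ≈ 0.5× expression) shifts that
fraction detectably. No perfect normality is assumed — normcount
distributions are only required to be roughly bell-shaped — and the
Z-score is used as a standard measure of deviance from the cohort mean.
Because whole embryos and trophectoderm biopsies differ systematically in
cell composition and library complexity, all means and SDs are computed
*within* sample type (WE or TE), never pooled.

Two calling tiers are deliberate. The permissive ±2 cutoff (≈95% central
coverage under normality) maximizes sensitivity; the stringent tier
requires a permutation p-value obtained by reshuffling gene→chromosome
labels and recomputing the entire cross-sample Z calculation per
replicate. The shuffled null inherits each sample's own noise level: a
sample that is noisy across many chromosomes produces a broad null, and
none of its chromosomes reaches significance — a feature, since such
profiles are uninterpretable at the single-chromosome level.

Sex calling rests on two facts of blastocyst biology: single-gene
genotyping (SRY, XIST) is uninformative at this stage, while DDX3Y,
RPS4Y1 and EIF1AY are robustly and Y-specifically expressed; and X
dosage is confounded by the onset of X-chromosome inactivation,
especially in trophectoderm. Hence Y presence is a TPM-sum threshold
test, X copy number is a Z-score sign test used only for WE, and TE is
called on the Y sum alone.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_tpm_expressed` | 1.0 | TPM | "expressed" threshold for all QC rules |
| `min_genes_per_sample` | 5000 | genes | ≈ one third of a full blastocyst transcriptome; scale down for reduced genomes (the test/benchmark runs use 500 of 1250 genes) |
| `coverage_min_samples` | 10 | samples | per-type expressed-set definition |
| `y_threshold_tpm` | 25 | TPM | Y-marker sum above which a Y is called; strict `>`, boundary falls to no-Y |
| `z_cutoff` | 2.0 | SD | permissive outlier band; strict inequalities |
| `n_shuffles` | 3000 | replicates | permutation-null resolution (p ≥ 1/3001) |
| `alpha` | 0.05 | — | stringent-call threshold; a default, not a claim about the optimal operating point |
| `sd_mode` | sample | — | unbiased (n−1) SD; population mode available |
| `xci_attenuation` | 0.8 | — | simulated XX X-dose is (1+α)/2 per allele pair: partial dosage compensation that still separates XX from XY in WE |
| `nb_dispersion` | 0.1 | — | negative-binomial dispersion (var = μ + φμ²), a typical bulk RNA-seq value |

## The synthetic generator

`simulate_cohort` emulates the structure the analysis needs: ~35 embryos,
every embryo a WE sample and ~55% a paired TE biopsy, XX/XY sexes,
whole-chromosome gains/losses with linear dosage, mosaic cell mixtures
(TE biopsies of 3–7 cells draw their mixture multinomially, so mosaic
embryos naturally yield discordant WE/TE and Y-loss fixtures),
pseudoautosomal and mitochondrial genes to exercise every QC path, and an
optional per-embryo per-chromosome log-normal dosage jitter shared
between an embryo's two samples (the biological covariation that makes
paired Z-profiles correlate). The genome is scaled down to 50 genes per
chromosome and ~1e6 reads per library so that the full pipeline including
the 3000-replicate permutation null runs in seconds; gene baseline rates
are log-normal (σ = 1 on the log scale) and drawn once per cohort, so
cross-sample variation is counting noise plus true dosage.

What it does **not** emulate: lineage-specific transcriptional programs
(the real WE/TE expressed-gene asymmetry), amplification jackpotting,
batch and developmental-stage effects, segmental aneuploidies, and
per-gene dispersion differences. Passing tests therefore demonstrate the
statistical machinery under the stated noise model, not clinical
performance on real embryos.

Morphokinetic timelines are drawn around a synthetic clinical reference
(plausible hour-scale means/SDs from pronuclei fade; not measured
clinical values). Non-aberrant embryos stay within ±0.95 SD per event;
aberrant embryos get two events displaced late by 2 SD; a running maximum
enforces nondecreasing event times and can only add deviations, so labels
are guaranteed.

## Numerical choices

* TPM: `1e6·(c_g/L_g)/Σ(c_h/L_h)`; an all-zero library yields an all-zero
  column with a degenerate flag rather than NaN. TPM is not recomputed
  after gene filtering by default (upstream-quantified TPM convention);
  a flag renormalizes.
* Zero-variance Z columns yield z = 0 with a `degenerate_sd` flag rather
  than NaN propagation.
* Permutation p uses the add-one estimator (1+k)/(B+1), so p ∈
  [1/(B+1), 1] and is never zero; "at least as extreme" is two-sided on
  |Z|, and ties are counted at float precision (|z_b| ≥ |z_obs| − 1e-9),
  the standard permutation-test convention — without the tolerance,
  replicates that are exact mirror images of the observed assignment
  would be dropped by ~1e-16 rounding.
* All threshold comparisons are strict (`>25` TPM, `|z|>2`, `>1` SD),
  with boundary equality falling to the negative side.
* Multiple-testing correction is not applied to permutation p-values by
  default; the stringent tier is a per-cell test.

## Open design points and how they were resolved

* X is included in the karyotype and in the shuffle pool; Y is excluded
  entirely (near-zero expression in XX breaks the share model; Y is the
  sexing module's job). Shuffling is effectively per sample type because
  Z-scores are computed within type.
* The paired-vs-unpaired comparison is a one-sided Welch t-test (rank-sum
  available); the unpaired set is *all* different-embryo TE×WE
  combinations. Correlation profiles use autosomes + X, excluding Y.
* Conflicting WE sex evidence yields "ambiguous" rather than privileging
  either signal; low-but-nonzero Y sums are flagged (`low_y_evidence`,
  possible partial Y loss in a mosaic) but never called XY.
* "Y-loss evidence" for mosaicism = Y present in at least one result for
  the embryo (PGT-A XY or any RNA Y-sum above threshold) and absent
  (≤ threshold) in at least one RNA result. Undefined PGT-A fields never
  count as mismatch.
* Morphokinetic deviation is two-sided by default (one-sided "late-only"
  mode available); whether only delays should count is biologically open.
* The gene filters run before the 5000-gene sample filter, and the
  expressed-gene count is taken after MT removal.

## Known limitations

* **Cohort-contamination ceiling.** Because the Z-score's mean and SD are
  estimated from the whole cohort, samples sharing the *same* affected
  chromosome inflate that chromosome's SD. If a fraction p of samples
  carry the aneuploidy, the attainable noiseless Z is bounded by
  √((1−p)/p) — at p = 1/6 the ceiling is ≈ 2.2, barely above the ±2
  cutoff, and with realistic counting noise (dispersion 0.1) the
  permissive call recovers only ~60% of such cells. Recovery is excellent
  when an aneuploidy is rare in the cohort (a single trisomic embryo
  among 8 scores |Z| ≈ 5) but degrades sharply as the same lesion becomes
  common; robust location/scale estimates would lift the ceiling and are
  a natural extension.
* Normcount shares are compositional: a strong gain on one chromosome
  slightly depresses all others, which can nudge borderline cells.
* The permutation null assumes gene exchangeability across chromosomes
  within the pool; systematic per-chromosome biology (e.g. gene-length
  or GC composition differences) is absorbed only through the observed
  shares.
* X-based sex evidence assumes both sexes are represented in the cohort;
  a single-sex cohort centres the X Z-scores and removes the sign signal.
* Mosaic-fraction estimation and segmental (sub-chromosomal) events are
  out of scope.

## Problem sizes

Benchmark experiments (`rnakaryo.evaluation`) use 14–40 embryos at 50
genes/chromosome and 1e6 reads, 500–3000 permutation replicates, and
10–50 seeds per experiment; the full test suite plus the benchmark script
completes in well under a minute on one CPU.
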