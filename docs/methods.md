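# Methods

## The analysis

`pgxdiff` screens biallelic SNPs in pharmacologically important genes for
allele-frequency differentiation between two focal cohorts (by default
labelled GIH and ITU, emulating two South-Asian panels of 109 and 112 diploid
genomes) and a set of global reference populations for which only allele
frequencies and allele numbers need be available. The stages are:

1. **Frequencies.** Per population, the alt-allele count and allele number are
   computed from dosages; missing genotypes are removed from both numerator
   and denominator, so the allele number is 2 × called samples. MAF is
   min(f, 1 − f).
2. **MAF filter.** A variant is retained when MAF ≥ 0.05 in *every* focal
   cohort (boundary inclusive). The complementary low-MAF partition is not
   discarded: it is screened with the same statistic under its own correction
   and reported as a separate category.
3. **Harmonization.** Each retained (variant, focal cohort) frequency is
   paired with each reference population's frequency. An allele absent from a
   reference population (frequency exactly 0, or no entry) is substituted at
   ε = 10⁻¹⁰ so the statistic is computable; the substitution is flagged.
   Focal frequencies of exactly 0 or 1 are clamped into (0, 1) by the same ε.
4. **Two-way chi-square.** See below.
5. **Bonferroni.** The family-wise level is α/(m·k) with α = 0.05, m the
   number of MAF-retained variants (computed, never hand-entered) and k the
   number of reference populations in the run. Calls are two-stage: p ≤ α
   ("pass_alpha"), then p ≤ α/(m·k) ("significant"); ties at either level
   pass.
6. **Fst screen.** Per-site Weir–Cockerham θ for every (focal, reference)
   pair; a variant is high-Fst when each focal cohort has at least one pair
   with defined θ ≥ 0.5.
7. **Classification.** Variants significant (against ≥ 1 reference) in both
   cohorts are *shared-significant*; in exactly one, *unique-to-A/B*; the
   low-MAF partition's hits form *low-MAF-significant*; the rest
   *not-significant*. Classification is restricted to variants annotated as
   pharmacogene-set members; unannotated variants are kept with gene
   "unknown". CADD ≥ 15 marks a variant deleterious (inclusive boundary).
8. **PCA.** Structure check on the standardized dosage matrix.

## The two-way statistic

For a biallelic site with focal frequency f₁ on N₁ alleles and reference
frequency f₂ on N₂ alleles, the statistic is a *cumulative* chi-square: a
goodness-of-fit sum with the focal side observed ("forward") plus the sum
with the reference side observed ("reverse"), referred to the χ²(df = 1)
upper tail. Two constructions of the expected counts are implemented:

- **pooled** (default): expected counts in both directions come from the
  pooled frequency f̄ = (N₁f₁ + N₂f₂)/(N₁ + N₂). The forward and reverse
  halves are then exactly the focal-row and reference-row contributions of
  Pearson's chi-square for the 2×2 allele-count table, so the cumulative
  total inherits the standard df = 1 null calibration. This is the
  construction used for screening.
- **per-side**: each direction takes the *other* side's frequency, rescaled
  to the observed side's allele number, as expected. This doubles a
  goodness-of-fit statistic; under the null it behaves like
  (N₁+N₂)²/(N₁N₂) · χ²₁ ≥ 4·χ²₁, i.e. it is strongly anti-conservative and
  will flood a Bonferroni screen with false calls. It is retained as a
  configuration (`expected="per-side"`) for fidelity experiments only.

Both constructions are symmetric under exchange of the two sides, are zero
exactly when f₁ = f₂ (the pooled implementation snaps the pooled frequency to
the common value when the two sides agree bitwise, so the zero is exact), and
increase strictly as |f₁ − f₂| grows at fixed allele numbers. A
`scale="frequencies"` option evaluates the same sums on frequency cells
(≤ 1); such a statistic cannot reach Bonferroni significance for common
alleles with a nonzero reference frequency and exists for comparison, not
screening.

The ε-substitution makes comparisons against reference populations lacking
the allele decisively significant in either construction (the pooled total at
f₁ = 0.3, N₁ = 200, N₂ = 1000 is ≈ 316, p ≈ 10⁻⁷⁰; per-side it exceeds 10⁸).

**Calibration caveat.** Even with the pooled default, a Bonferroni screen at
α = 0.05 per cohort run leaves a family-wise false-positive probability near
0.05 per run by construction. With two cohort runs, a fully null study shows
at least one significant call in roughly 10–20 % of replicates; the null
acceptance check measures exactly this (it counts replicates with zero calls
over 100 seeds). The per-site discreteness of small-sample binomial counts
makes the far tail mildly conservative, which pushes the zero-call fraction
somewhat above the asymptotic e^(−0.1) ≈ 0.90 but not reliably above 0.95.

## Weir–Cockerham fixation index

Per-site variance components for r populations with diploid sizes nᵢ,
alt-allele frequencies pᵢ and observed heterozygote proportions hᵢ:

    n̄ = Σnᵢ/r                       n_c = (r·n̄ − Σnᵢ²/(r·n̄))/(r−1)
    p̄ = Σnᵢpᵢ/(r·n̄)                 s² = Σnᵢ(pᵢ−p̄)²/((r−1)·n̄)
    h̄ = Σnᵢhᵢ/(r·n̄)

    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
    c = h̄/2,      θ = a/(a+b+c)

θ is undefined when a+b+c = 0 (e.g. both populations monomorphic for the
same allele) or when every population has a single individual; negative
estimates are legitimate for this moment estimator and are never clamped.
Screening uses pairwise (r = 2) per-site values; multi-locus combination is
the ratio of sums Σa/Σ(a+b+c), which is the consistent estimator used for
parameter recovery. Estimation is from genotypes (h̄ requires them), so the
synthetic generator emits genotypes for reference populations too; report
tables render θ at 2 decimal places while internal values keep full
precision.

## Synthetic cohorts

The generator draws, per locus, an ancestral frequency p from U(0.05, 0.95)
(common-variant territory, matching a post-MAF-filter call set) and, per
population with differentiation F > 0, a Balding–Nichols frequency
Beta(p(1−F)/F, (1−p)(1−F)/F) — mean p, variance F·p(1−p), so the generative
F *is* the Weir–Cockerham estimand. Genotypes are Hardy–Weinberg
(dosage ~ Binomial(2, p_pop)); missingness is an independent per-call Bernoulli
(default 0). All draws flow from one `numpy` Generator seeded by the config,
so cohorts are byte-reproducible.

Planted loci override the drawn frequencies with per-population targets and
carry truth labels. The packaged demo plants 13 shared / 9 unique-A /
6 unique-B contrasts with gene assignments giving 10 / 8 / 6 distinct genes,
at 0.65 (elevated cohort) vs 0.20 (references and non-elevated cohort) —
contrast 0.45, large enough that Bonferroni significance is essentially
certain at the default sample sizes while the matched side stays null. Three
shared loci use the stronger 0.85 vs 0.10 contrast so their per-site θ
(≈ 0.7) also clears the 0.5 screen. Background loci are undifferentiated
(F = 0): planted contrasts are the only true signal, so classification can be
validated exactly against the truth table. Reference panels default to
1000-Genomes-like sizes (170–661 diploids).

What the generator does *not* emulate: linkage disequilibrium (loci are
independent), admixture and continuous structure, allele-frequency spectra
skewed toward rare variants, genotyping error, and reference databases
aggregated over heterogeneous call sets. Passing the planted-truth checks
therefore demonstrates the statistical machinery, not robustness to these
real-data complications.

## Problem sizes and numerical choices

- Parameter-recovery checks use 2,000 loci and 100 diploids per population
  over 10 seeds at F ∈ {0.05, 0.2, 0.5}; observed mean absolute error is
  below 0.01, comfortably within the 0.02 band asserted.
- The null check uses 250 loci, two cohorts of 100 diploids, six reference
  panels, 100 seeds. PCA separation uses 500 loci, 50 + 50 samples, F = 0.3.
- PCA mean-imputes missing dosages per site, scales by √(p(1−p)), and fixes
  each component's sign by making its largest-magnitude loading positive;
  monomorphic sites are dropped and an all-monomorphic matrix is an error.
- Chromosome ordering is natural 1..22 then lexicographic; non-autosomal
  records are accepted but logged. Multi-allelic sites are decomposed per
  alternate allele, with samples carrying a different alternate allele set to
  missing for that record.
- Report floats are rendered at fixed precision (statistic 4 d.p., p-values
  3-s.f. scientific, θ 2 d.p.) so repeated writes are byte-identical.

## Known limitations

- The cumulative two-way statistic is not a calibrated standard test in its
  per-side form; only the pooled default carries the df = 1 calibration.
- Classification of "unique" variants is relative to the two focal cohorts
  only; no attempt is made to merge evidence across reference databases with
  different population panels beyond reporting the per-cohort lists.
- Fst screening needs reference genotypes; reference sets supplied only as
  frequency tables are skipped by that stage (with a log line).
- The epsilon substitution makes "absent from reference" overwhelmingly
  significant by design; with very small reference panels this can dominate
  a screen, so reference allele numbers should reflect real panel sizes.
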