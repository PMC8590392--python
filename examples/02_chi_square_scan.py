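"""Scan one focal cohort against every reference population with the two-way
cumulative chi-square and Bonferroni correction.

Frequencies are computed from genotypes, filtered at MAF >= 0.05, paired with
reference frequencies (absent alleles substituted at 1e-10), tested, and
called significant at alpha / (retained variants x reference populations).
"""

from pgxdiff import (
    BonferroniScheme,
    call_significance,
    chi_square_table,
    classification_demo_config,
    compute_population_frequencies,
    filter_by_maf,
    harmonize_with_reference,
    simulate_cohort,
)

cohort = simulate_cohort(classification_demo_config(seed=1))
freqs = compute_population_frequencies(cohort.variants, cohort.panel)
partition = filter_by_maf(freqs, 0.05, cohort.config.focal_populations)
print(f"MAF >= 0.05: retained {len(partition.retained)}, low-MAF {len(partition.low_maf)}")

pairs = harmonize_with_reference(
    freqs, cohort.references, ["GIH"], variants=partition.retained
)
scheme = BonferroniScheme(
    alpha=0.05,
    n_variants=len(partition.retained),
    n_reference_pops=len(cohort.references.populations),
)
print(f"Bonferroni-adjusted level: {scheme.adjusted_level:.3e}")

called = call_significance(chi_square_table(pairs), scheme)
hits = called[called["significant"]].sort_values("chi2_total", ascending=False)
print(f"significant (variant, reference) pairs: {len(hits)}")
print(hits[["variant", "reference_population", "chi2_total", "p_value"]]
      .head(5).to_string(index=False))
# Each row is one focal-vs-reference comparison; chi2_total is the sum of the
# forward (focal observed) and reverse (reference observed) halves.
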