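"""Run the whole pipeline and read off the shared/unique classification.

One call chains every stage — frequencies, MAF filter, chi-square against all
reference populations for both focal cohorts, Fst screen, classification,
gene-level summary, PCA — and writes the TSV artifacts plus a manifest.
"""

from pgxdiff import RunConfig, classification_demo_config, run_all

result = run_all(
    RunConfig(simulate=classification_demo_config(seed=1), out_dir="example_run")
)

print(result.gene_summary.to_string(index=False))
print(f"\nhigh-Fst flagged variants: {sorted(result.high_fst)}")
deleterious = result.classifications.query("deleterious and category != 'not-significant'")
print(f"deleterious significant variants (CADD >= 15): {len(deleterious)}")
print(f"\nBonferroni level used: {result.manifest['bonferroni']['adjusted_level']:.3e}")
# n_variants/n_genes per category mirror the headline shape of the analysis:
# variants significant in both cohorts, in exactly one, low-MAF, or neither.
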