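"""Shared/unique classification of significant variants and gene summaries.

A variant is *shared-significant* when it is Bonferroni-significant against
at least one reference population in **both** focal cohorts, *unique* when in
exactly one, *low-MAF-significant* when it was significant but sat below the
focal MAF threshold (that partition is screened separately and kept out of
the headline categories), else *not-significant*.  Deleteriousness is a CADD
phred score at or above 15.
"""

from __future__ import annotations

import logging

import pandas as pd

from .types import AnnotationTable

logger = logging.getLogger(__name__)

CATEGORIES = (
    "shared-significant",
    "unique-to-A",
    "unique-to-B",
    "low-MAF-significant",
    "not-significant",
)

DEFAULT_CADD_THRESHOLD = 15.0


def _significant_refs(calls: pd.DataFrame) -> dict[str, list[str]]:
    """variant -> sorted reference populations it is significant against."""
    sig = calls[calls["significant"].astype(bool)]
    out: dict[str, list[str]] = {}
    for row in sig.itertuples(index=False):
        out.setdefault(row.variant, []).append(row.reference_population)
    return {v: sorted(set(pops)) for v, pops in out.items()}


def classify_shared_unique(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    annotations: AnnotationTable,
    low_maf_variants: set[str] | None = None,
    require_pharmgkb: bool = True,
) -> pd.DataFrame:
    """Combine the two focal cohorts' significance calls into categories.

    *calls_a* / *calls_b* are significance-called statistic tables (one row
    per variant x reference population) for focal cohorts A and B.  Variants
    annotated as non-members of the pharmacogene set are excluded up front
    when *require_pharmgkb* is set; variants with no annotation at all are
    kept with gene "unknown".  Variants in *low_maf_variants* go to the
    separate low-MAF category regardless of which cohort flagged them.

    Returns one row per tested variant: ``variant, gene, consequence, cadd,
    category, significant_against_A, significant_against_B, deleterious``.
    """
    low_maf = low_maf_variants or set()
    order: list[str] = []
    for frame in (calls_a, calls_b):
        for v in frame["variant"].drop_duplicates():
            if v not in order:
                order.append(v)

    sig_a = _significant_refs(calls_a)
    sig_b = _significant_refs(calls_b)

    rows = []
    n_unannotated = 0
    for variant in order:
        ann = annotations.get(variant)
        if ann is None:
            n_unannotated += 1
            gene, consequence, cadd = "unknown", "other", None
        else:
            if require_pharmgkb and not ann.pharmgkb:
                continue
            gene, consequence, cadd = ann.gene, ann.consequence, ann.cadd
        in_a = variant in sig_a
        in_b = variant in sig_b
        if variant in low_maf:
            category = "low-MAF-significant" if (in_a or in_b) else "not-significant"
        elif in_a and in_b:
            category = "shared-significant"
        elif in_a:
            category = "unique-to-A"
        elif in_b:
            category = "unique-to-B"
        else:
            category = "not-significant"
        rows.append(
            (
                variant,
                gene,
                consequence,
                cadd,
                category,
                ",".join(sig_a.get(variant, [])),
                ",".join(sig_b.get(variant, [])),
            )
        )
    if n_unannotated:
        logger.warning("%d tested variants had no annotation (gene set to 'unknown')",
                       n_unannotated)
    df = pd.DataFrame(
        rows,
        columns=[
            "variant",
            "gene",
            "consequence",
            "cadd",
            "category",
            "significant_against_A",
            "significant_against_B",
        ],
    )
    return flag_deleterious(df)


def flag_deleterious(
    classifications: pd.DataFrame, threshold: float = DEFAULT_CADD_THRESHOLD
) -> pd.DataFrame:
    """Set ``deleterious`` where the CADD score is present and >= threshold."""
    out = classifications.copy()
    cadd = pd.to_numeric(out["cadd"], errors="coerce")
    out["deleterious"] = cadd.notna() & (cadd >= threshold)
    n_absent = int(cadd.isna().sum())
    if n_absent:
        logger.info("%d variants without CADD score (never deleterious)", n_absent)
    return out


def apply_high_fst(
    classifications: pd.DataFrame, high_fst_variants: set[str]
) -> pd.DataFrame:
    """Attach the per-variant high-Fst screen result as a boolean column."""
    out = classifications.copy()
    out["high_fst"] = out["variant"].isin(high_fst_variants)
    return out


def summarize_by_gene(classifications: pd.DataFrame) -> pd.DataFrame:
    """Variant and distinct-gene counts per category.

    Every category appears in the output, zero-filled when empty, so the
    summary shape is stable across runs.
    """
    rows = []
    for category in CATEGORIES:
        sub = classifications[classifications["category"] == category]
        rows.append((category, len(sub), sub["gene"].nunique()))
    return pd.DataFrame(rows, columns=["category", "n_variants", "n_genes"])
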