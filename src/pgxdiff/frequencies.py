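"""Per-population allele frequencies, the MAF filter, and reference harmonization.

Missing genotypes are excluded from both the allele count and the allele
number, so the allele number at a site is 2 x (called diploid samples in the
population).  The minor allele frequency (MAF) is min(f, 1 - f) of the
alt-allele frequency f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, ReferenceFrequencySet, SamplePanel, VariantRecord

logger = logging.getLogger(__name__)

#: default substitution frequency for alleles absent from a reference population
DEFAULT_EPSILON = 1e-10


def compute_population_frequencies(
    variants: list[VariantRecord],
    panel: SamplePanel,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Alt-allele count, allele number, frequency and MAF per (variant, population).

    Returns a frame with columns ``variant, chrom, pos, population, alt_count,
    allele_number, frequency, maf, defined``.  ``defined`` is False when a
    population has no called samples at the site (frequency and MAF are NaN).
    """
    pops = populations if populations is not None else panel.populations
    idx = {pop: panel.sample_indices(pop) for pop in pops}
    rows = []
    for rec in variants:
        for pop in pops:
            g = rec.genotypes[idx[pop]]
            called = g != MISSING
            an = 2 * int(called.sum())
            ac = int(g[called].sum())
            if an > 0:
                freq = ac / an
                maf = min(freq, 1.0 - freq)
            else:
                freq = np.nan
                maf = np.nan
                logger.warning(
                    "no called samples for %s at %s:%d", pop, rec.chrom, rec.pos
                )
            rows.append(
                (rec.key, rec.chrom, rec.pos, pop, ac, an, freq, maf, an > 0)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variant",
            "chrom",
            "pos",
            "population",
            "alt_count",
            "allele_number",
            "frequency",
            "maf",
            "defined",
        ],
    )


@dataclass(frozen=True)
class MafPartition:
    """Disjoint partition of the variant set by the focal MAF filter."""

    retained: list[str]
    low_maf: list[str]
    threshold: float


def filter_by_maf(
    frequencies: pd.DataFrame,
    threshold: float,
    focal_populations: list[str],
) -> MafPartition:
    """Partition variants into retained (MAF >= threshold in *every* focal
    population) and the complementary low-MAF set.

    The boundary is inclusive: a variant at exactly the threshold is retained.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    known = set(frequencies["population"].unique())
    unknown = [p for p in focal_populations if p not in known]
    if unknown:
        raise ValueError(f"unknown focal population label(s): {', '.join(unknown)}")
    focal = frequencies[frequencies["population"].isin(focal_populations)]
    passes = (
        focal.assign(ok=lambda d: d["maf"].fillna(-1.0) >= threshold)
        .groupby("variant", sort=False)["ok"]
        .all()
    )
    order = focal["variant"].drop_duplicates().tolist()
    retained = [v for v in order if passes[v]]
    low = [v for v in order if not passes[v]]
    logger.info(
        "MAF >= %g filter: %d retained, %d low-MAF", threshold, len(retained), len(low)
    )
    return MafPartition(retained=retained, low_maf=low, threshold=threshold)


def harmonize_with_reference(
    frequencies: pd.DataFrame,
    references: ReferenceFrequencySet,
    focal_populations: list[str],
    reference_populations: list[str] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    variants: list[str] | None = None,
) -> pd.DataFrame:
    """Pair each focal (variant, population) frequency with each reference
    population's frequency, substituting *epsilon* for alleles absent from a
    reference population.

    A reference frequency of exactly 0 (or a variant entirely missing from
    that reference population) is replaced by ``epsilon`` — the complementary
    allele implicitly becomes ``1 - epsilon`` — so the chi-square statistic is
    computable; the ``substituted`` flag records the replacement.  Variants
    absent from *all* reference populations keep every pair, each substituted.
    Focal frequencies of exactly 0 or 1 are nudged by the same epsilon, for
    the same reason, without setting the flag (the flag tracks the reference
    side, which is what the substitution rule is about).

    Returns columns ``variant, chrom, pos, focal_population,
    reference_population, f_focal, n_focal, f_reference, n_reference,
    substituted``.
    """
    if not epsilon > 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if epsilon >= 0.5:
        raise ValueError(f"epsilon must be below any observable frequency, got {epsilon}")
    ref_pops = reference_populations if reference_populations is not None else references.populations
    focal = frequencies[frequencies["population"].isin(focal_populations)]
    if variants is not None:
        keep = set(variants)
        focal = focal[focal["variant"].isin(keep)]
    rows = []
    n_missing_everywhere = 0
    for row in focal.itertuples(index=False):
        if not row.defined:
            continue
        f_focal = min(max(row.frequency, epsilon), 1.0 - epsilon)
        found_any = False
        for ref_pop in ref_pops:
            entry = references.lookup(row.variant, ref_pop)
            if entry is not None and entry.frequency > 0.0:
                f_ref, n_ref, substituted = entry.frequency, entry.allele_number, False
                f_ref = min(f_ref, 1.0 - epsilon)
                found_any = True
            else:
                n_ref = entry.allele_number if entry is not None else row.allele_number
                f_ref, substituted = epsilon, True
            rows.append(
                (
                    row.variant,
                    row.chrom,
                    row.pos,
                    row.population,
                    ref_pop,
                    f_focal,
                    row.allele_number,
                    f_ref,
                    n_ref,
                    substituted,
                )
            )
        if not found_any:
            n_missing_everywhere += 1
    if n_missing_everywhere:
        logger.info(
            "%d (variant, focal pop) records absent from every reference population "
            "(epsilon=%g substituted)",
            n_missing_everywhere,
            epsilon,
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant",
            "chrom",
            "pos",
            "focal_population",
            "reference_population",
            "f_focal",
            "n_focal",
            "f_reference",
            "n_reference",
            "substituted",
        ],
    )
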