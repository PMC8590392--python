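"""Weir & Cockerham (1984) moment estimator of the fixation index.

Per-site variance components for r sampled populations:

    n_bar = mean sample size, n_c = (r*n_bar - sum(n_i^2)/(r*n_bar))/(r-1)
    p_bar = sample-size-weighted mean allele frequency
    s2    = sample-size-weighted among-population variance of p_i
    h_bar = weighted observed heterozygote proportion

    a = (n_bar/n_c) * [s2 - (p_bar*(1-p_bar) - s2*(r-1)/r - h_bar/4)/(n_bar-1)]
    b = (n_bar/(n_bar-1)) * [p_bar*(1-p_bar) - s2*(r-1)/r - h_bar*(2*n_bar-1)/(4*n_bar)]
    c = h_bar/2

    theta = a / (a + b + c)

theta is undefined when a + b + c = 0 (e.g. both populations monomorphic for
the same allele).  Negative estimates are legitimate for this estimator and
are reported unclamped.  Multi-locus combination is the standard ratio of
sums, sum(a) / sum(a+b+c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, SamplePanel, VariantRecord


@dataclass(frozen=True)
class FstComponents:
    """Variance components and theta for one site and population set."""

    a: float
    b: float
    c: float
    theta: float  # NaN when undefined
    defined: bool


def wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> FstComponents:
    """Components for one site from per-population (n_i, p_i, h_i).

    *n* are diploid sample sizes, *p* alt-allele frequencies, *h* observed
    heterozygote proportions, each of length r >= 2.
    """
    a, b, c = _components_arrays(
        np.asarray(n, dtype=float)[:, None],
        np.asarray(p, dtype=float)[:, None],
        np.asarray(h, dtype=float)[:, None],
    )
    return _to_result(float(a[0]), float(b[0]), float(c[0]))


def _to_result(a: float, b: float, c: float) -> FstComponents:
    denom = a + b + c
    if denom == 0.0 or not np.isfinite(denom):
        return FstComponents(a=a, b=b, c=c, theta=float("nan"), defined=False)
    return FstComponents(a=a, b=b, c=c, theta=a / denom, defined=True)


def _components_arrays(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized components; n, p, h have shape (r, L) for L sites."""
    r = n.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")
    if np.any(n < 1):
        raise ValueError("each population needs at least one called sample")
    if np.any((p < 0) | (p > 1)) or np.any((h < 0) | (h > 1)):
        raise ValueError("frequencies and heterozygosities must lie in [0, 1]")
    n_bar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / (r * n_bar)
        inner = p_bar * (1.0 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
    # all-singleton samples (n_bar == 1) or n_c == 0 leave a/b undefined
    degenerate = (n_bar <= 1.0) | (n_c == 0.0)
    a = np.where(degenerate, np.nan, a)
    b = np.where(degenerate, np.nan, b)
    return a, b, c


def wc_theta_from_genotypes(
    variants: list[VariantRecord],
    panel: SamplePanel,
    population_pair: tuple[str, str],
) -> pd.DataFrame:
    """Per-site components and theta for one population pair from dosages.

    For each site, n_i counts called diploid samples, p_i is the alt-allele
    frequency among called samples and h_i the fraction of called samples
    that are heterozygous.  Sites where either population has no called
    sample are flagged undefined.

    Returns columns ``variant, chrom, pos, pop1, pop2, a, b, c, theta,
    defined``.
    """
    pop1, pop2 = population_pair
    idx1 = panel.sample_indices(pop1)
    idx2 = panel.sample_indices(pop2)
    if len(variants) == 0:
        return pd.DataFrame(
            columns=["variant", "chrom", "pos", "pop1", "pop2", "a", "b", "c", "theta", "defined"]
        )
    geno = np.stack([rec.genotypes for rec in variants])  # (L, samples)
    n = np.empty((2, len(variants)))
    p = np.empty_like(n)
    h = np.empty_like(n)
    usable = np.ones(len(variants), dtype=bool)
    for k, idx in enumerate((idx1, idx2)):
        g = geno[:, idx]
        called = g != MISSING
        n_i = called.sum(axis=1).astype(float)
        usable &= n_i >= 1
        safe_n = np.maximum(n_i, 1.0)
        p[k] = np.where(called, g, 0).sum(axis=1) / (2.0 * safe_n)
        h[k] = (g == 1).sum(axis=1) / safe_n
        n[k] = safe_n
    a, b, c = _components_arrays(n, p, h)
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0.0, a / denom, np.nan)
    defined = usable & np.isfinite(denom) & (denom != 0.0)
    return pd.DataFrame(
        {
            "variant": [rec.key for rec in variants],
            "chrom": [rec.chrom for rec in variants],
            "pos": [rec.pos for rec in variants],
            "pop1": pop1,
            "pop2": pop2,
            "a": a,
            "b": b,
            "c": c,
            "theta": np.where(defined, theta, np.nan),
            "defined": defined,
        }
    )


def wc_theta_weighted(components: pd.DataFrame) -> float:
    """Multi-locus theta: sum(a) / sum(a + b + c) over defined sites."""
    usable = components[components["defined"].astype(bool)]
    if len(usable) == 0:
        raise ValueError("no sites with defined variance components")
    num = usable["a"].sum()
    den = (usable["a"] + usable["b"] + usable["c"]).sum()
    if den == 0.0:
        raise ValueError("total variance is zero across usable sites")
    return float(num / den)


def flag_high_fst(
    components: pd.DataFrame,
    threshold: float,
    focal_populations: list[str],
    mode: str = "both",
) -> set[str]:
    """Variants with per-site theta >= threshold against a reference population.

    In ``"both"`` mode (the default) a variant is flagged when *each* focal
    population has at least one (focal, reference) pair with defined theta at
    or above the threshold; ``"any"`` mode requires only one focal population
    to qualify.  Pairs between the two focal populations themselves are not
    considered.  Undefined thetas never qualify.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if mode not in ("both", "any"):
        raise ValueError(f"mode must be 'both' or 'any', got {mode!r}")
    focal = set(focal_populations)
    hits: dict[str, set[str]] = {}
    ok = components[
        components["defined"].astype(bool) & (components["theta"] >= threshold)
    ]
    for row in ok.itertuples(index=False):
        in1, in2 = row.pop1 in focal, row.pop2 in focal
        if in1 == in2:  # focal-vs-focal or reference-vs-reference pair
            continue
        focal_pop = row.pop1 if in1 else row.pop2
        hits.setdefault(row.variant, set()).add(focal_pop)
    if mode == "both":
        return {v for v, pops in hits.items() if pops >= focal}
    return set(hits)
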