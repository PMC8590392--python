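"""Genotype-matrix principal component analysis.

Standard population-structure PCA: the sample x site dosage matrix is
mean-imputed per site, centred, scaled by sqrt(p*(1-p)) (the binomial
standard deviation of the allele frequency p at the site), and decomposed
by SVD.  The component sign is fixed by making each component's
largest-magnitude loading positive, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, SamplePanel, VariantRecord


@dataclass(frozen=True)
class PcaResult:
    """Per-sample coordinates plus explained-variance fractions."""

    coordinates: pd.DataFrame  # columns: sample, population, PC1..PCk
    explained_variance_ratio: np.ndarray


def genotype_pca(
    variants: list[VariantRecord],
    panel: SamplePanel,
    k: int = 2,
) -> PcaResult:
    """Top-*k* principal components of the standardized dosage matrix."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(panel) < 2:
        raise ValueError("PCA needs at least two samples")
    geno = np.stack([rec.genotypes for rec in variants]).astype(float).T  # (samples, sites)
    geno[geno == MISSING] = np.nan
    col_mean = np.nanmean(geno, axis=0)
    freq = col_mean / 2.0
    polymorphic = (freq > 0.0) & (freq < 1.0)
    if polymorphic.sum() < 2:
        raise ValueError("PCA needs at least two polymorphic sites")
    geno = geno[:, polymorphic]
    col_mean = col_mean[polymorphic]
    freq = freq[polymorphic]
    # mean-impute missing dosages per site, then standardize
    nan_mask = np.isnan(geno)
    geno[nan_mask] = np.broadcast_to(col_mean, geno.shape)[nan_mask]
    scaled = (geno - col_mean) / np.sqrt(freq * (1.0 - freq))
    u, s, vt = np.linalg.svd(scaled, full_matrices=False)
    k_eff = min(k, len(s))
    scores = u[:, :k_eff] * s[:k_eff]
    # sign convention: largest-magnitude loading of each component positive
    for j in range(k_eff):
        load = vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    var = s**2
    ratio = var[:k_eff] / var.sum()
    coords = pd.DataFrame(
        {
            "sample": panel.samples,
            "population": [panel.population_of(s_) for s_ in panel.samples],
        }
    )
    for j in range(k_eff):
        coords[f"PC{j + 1}"] = scores[:, j]
    return PcaResult(coordinates=coords, explained_variance_ratio=ratio)
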