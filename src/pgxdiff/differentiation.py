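"""Two-way cumulative chi-square test of allele-frequency differentiation.

For a biallelic site, the focal population's allele frequencies and a
reference population's allele frequencies are compared twice: once with the
focal side as observed, once with the reference side as observed ("forward"
and "reverse"), and the two goodness-of-fit sums are accumulated into a
single statistic referred to the upper tail of a chi-square distribution.

Two constructions of the expected counts are provided:

``pooled`` (default)
    Expected counts in both directions come from the pooled allele frequency
    of the two samples.  The forward and reverse halves are then exactly the
    focal-row and reference-row contributions of the standard Pearson
    chi-square statistic for the 2x2 allele-count table, so the cumulative
    total is the Pearson statistic and its df=1 null calibration carries
    over.

``per-side``
    Expected counts in each direction come from the *other* side's frequency
    rescaled to the observed side's allele number.  This doubles a
    goodness-of-fit statistic and is strongly anti-conservative under the
    null; it is kept for fidelity experiments, not screening.

With ``scale="frequencies"`` the cells are the frequencies themselves
(no rescaling by allele numbers); such a statistic cannot reach genome-scale
significance for common alleles with a nonzero reference frequency and is
likewise provided for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

SCALES = ("counts", "frequencies")
EXPECTED_MODES = ("pooled", "per-side")


@dataclass(frozen=True)
class TwoWayChiSquareResult:
    """Forward/reverse/cumulative chi-square for one (variant, pop pair)."""

    chi2_forward: float
    chi2_reverse: float
    chi2_total: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        assert self.chi2_total == self.chi2_forward + self.chi2_reverse


@dataclass(frozen=True)
class BonferroniScheme:
    """Family-wise correction: alpha / (number of variants x reference pops)."""

    alpha: float = 0.05
    n_variants: int = 1
    n_reference_pops: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.n_variants < 1 or self.n_reference_pops < 1:
            raise ValueError("variant and reference-population counts must be >= 1")

    @property
    def adjusted_level(self) -> float:
        return self.alpha / (self.n_variants * self.n_reference_pops)


def bonferroni_threshold(scheme: BonferroniScheme) -> float:
    """Adjusted significance level alpha / (n_variants * n_reference_pops)."""
    return scheme.adjusted_level


def _chi2_halves(
    f_focal: np.ndarray,
    n_focal: np.ndarray,
    f_reference: np.ndarray,
    n_reference: np.ndarray,
    scale: str,
    expected: str,
) -> tuple[np.ndarray, np.ndarray]:
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}, got {scale!r}")
    if expected not in EXPECTED_MODES:
        raise ValueError(f"expected must be one of {EXPECTED_MODES}, got {expected!r}")
    ff = np.asarray(f_focal, dtype=float)
    fr = np.asarray(f_reference, dtype=float)
    if np.any((ff <= 0) | (ff >= 1)) or np.any((fr <= 0) | (fr >= 1)):
        raise ValueError(
            "frequencies must lie strictly in (0, 1); apply the epsilon "
            "substitution before testing"
        )
    if scale == "counts":
        nf = np.asarray(n_focal, dtype=float)
        nr = np.asarray(n_reference, dtype=float)
        if np.any(nf <= 0) or np.any(nr <= 0):
            raise ValueError("allele numbers must be positive under counts scale")
    else:
        nf = nr = np.ones_like(ff)

    obs_f = np.stack([ff * nf, (1.0 - ff) * nf])
    obs_r = np.stack([fr * nr, (1.0 - fr) * nr])
    if expected == "pooled":
        pooled = (ff * nf + fr * nr) / (nf + nr)
        # equal frequencies must give an exactly-zero statistic
        pooled = np.where(ff == fr, ff, pooled)
        exp_f = np.stack([pooled * nf, (1.0 - pooled) * nf])
        exp_r = np.stack([pooled * nr, (1.0 - pooled) * nr])
    else:
        exp_f = np.stack([fr * nf, (1.0 - fr) * nf])
        exp_r = np.stack([ff * nr, (1.0 - ff) * nr])
    forward = ((obs_f - exp_f) ** 2 / exp_f).sum(axis=0)
    reverse = ((obs_r - exp_r) ** 2 / exp_r).sum(axis=0)
    return forward, reverse


def two_way_chi_square(
    f_focal: float,
    n_focal: int,
    f_reference: float,
    n_reference: int,
    scale: str = "counts",
    expected: str = "pooled",
    df: int = 1,
) -> TwoWayChiSquareResult:
    """Cumulative two-way chi-square for one harmonized frequency pair.

    Frequencies must be strictly inside (0, 1); zero reference frequencies
    are expected to have been epsilon-substituted upstream.
    """
    fwd, rev = _chi2_halves(
        np.atleast_1d(f_focal),
        np.atleast_1d(n_focal),
        np.atleast_1d(f_reference),
        np.atleast_1d(n_reference),
        scale,
        expected,
    )
    total = float(fwd[0]) + float(rev[0])
    return TwoWayChiSquareResult(
        chi2_forward=float(fwd[0]),
        chi2_reverse=float(rev[0]),
        chi2_total=total,
        df=df,
        p_value=float(_chi2_dist.sf(total, df)),
    )


def chi_square_table(
    pairs: pd.DataFrame,
    scale: str = "counts",
    expected: str = "pooled",
    df: int = 1,
) -> pd.DataFrame:
    """Vectorized statistic over a harmonized-pairs frame.

    *pairs* must carry ``f_focal, n_focal, f_reference, n_reference`` (as
    produced by :func:`pgxdiff.frequencies.harmonize_with_reference`); the
    returned frame adds ``chi2_forward, chi2_reverse, chi2_total, df,
    p_value``.
    """
    out = pairs.copy()
    if len(out) == 0:
        for col in ("chi2_forward", "chi2_reverse", "chi2_total", "df", "p_value"):
            out[col] = pd.Series(dtype=float)
        return out
    fwd, rev = _chi2_halves(
        out["f_focal"].to_numpy(),
        out["n_focal"].to_numpy(),
        out["f_reference"].to_numpy(),
        out["n_reference"].to_numpy(),
        scale,
        expected,
    )
    out["chi2_forward"] = fwd
    out["chi2_reverse"] = rev
    out["chi2_total"] = fwd + rev
    out["df"] = df
    out["p_value"] = _chi2_dist.sf(out["chi2_total"].to_numpy(), df)
    return out


def call_significance(results: pd.DataFrame, scheme: BonferroniScheme) -> pd.DataFrame:
    """Two-stage significance call.

    Stage 1 retains tests with p <= alpha (``pass_alpha``); stage 2 flags
    ``significant`` those with p <= the Bonferroni-adjusted level.  Ties at
    exactly either level pass (both comparisons are ``<=``).
    """
    out = results.copy()
    if len(out) == 0:
        out["pass_alpha"] = pd.Series(dtype=bool)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["pass_alpha"] = out["p_value"] <= scheme.alpha
    out["significant"] = out["p_value"] <= scheme.adjusted_level
    return out
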