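"""Two-way chi-square statistic: oracle agreement, symmetry, calibration bits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from pgxdiff.differentiation import (
    BonferroniScheme,
    bonferroni_threshold,
    call_significance,
    two_way_chi_square,
)

import pandas as pd


def brute_force_two_way(f_focal, n_focal, f_ref, n_ref, expected="pooled"):
    """Independent loop-based evaluation of the two Σ(O-E)²/E sums."""
    obs_focal = [f_focal * n_focal, (1 - f_focal) * n_focal]
    obs_ref = [f_ref * n_ref, (1 - f_ref) * n_ref]
    if expected == "pooled":
        pooled = (obs_focal[0] + obs_ref[0]) / (n_focal + n_ref)
        exp_focal = [pooled * n_focal, (1 - pooled) * n_focal]
        exp_ref = [pooled * n_ref, (1 - pooled) * n_ref]
    else:
        exp_focal = [f_ref * n_focal, (1 - f_ref) * n_focal]
        exp_ref = [f_focal * n_ref, (1 - f_focal) * n_ref]
    fwd = sum((o - e) ** 2 / e for o, e in zip(obs_focal, exp_focal))
    rev = sum((o - e) ** 2 / e for o, e in zip(obs_ref, exp_ref))
    return fwd, rev


freq_strategy = st.floats(min_value=0.01, max_value=0.99)
size_strategy = st.integers(min_value=10, max_value=5000)


class TestStatistic:
    def test_identical_frequencies_give_zero(self):
        res = two_way_chi_square(0.25, 200, 0.25, 1000)
        assert res.chi2_forward == res.chi2_reverse == res.chi2_total == 0.0
        assert res.p_value == 1.0

    def test_per_side_arithmetic(self):
        """Frozen per-side counts-scale example: focal 0.30 with 200 alleles
        (O = 60, 140) against reference 0.05 with 1000 alleles."""
        res = two_way_chi_square(0.30, 200, 0.05, 1000, expected="per-side")
        assert res.chi2_forward == pytest.approx(263.1579, abs=5e-5)
        assert res.chi2_reverse == pytest.approx(297.6190, abs=5e-5)
        assert res.chi2_total == pytest.approx(560.7769, abs=1e-4)
        assert res.p_value < 1e-100

    def test_absent_reference_is_overwhelmingly_significant(self):
        """An epsilon-substituted reference frequency drives the statistic far
        beyond any Bonferroni level; in per-side mode the near-zero expected
        cell makes it astronomically large."""
        pooled = two_way_chi_square(0.30, 200, 1e-10, 1000)
        assert pooled.chi2_total > 100
        assert pooled.p_value < 1e-50
        per_side = two_way_chi_square(0.30, 200, 1e-10, 1000, expected="per-side")
        assert per_side.chi2_total > 1e8
        assert per_side.p_value == 0.0

    @pytest.mark.parametrize("expected", ["pooled", "per-side"])
    @pytest.mark.parametrize("scale", ["counts", "frequencies"])
    def test_oracle_equivalence(self, expected, scale):
        """1,000 random (frequency, allele-number) pairs match an independent
        brute-force evaluation to relative error <= 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            ff, fr = rng.uniform(0.01, 0.99, 2)
            nf, nr = rng.integers(10, 5000, 2)
            res = two_way_chi_square(ff, int(nf), fr, int(nr), scale=scale, expected=expected)
            if scale == "frequencies":
                fwd, rev = brute_force_two_way(ff, 1, fr, 1, expected)
            else:
                fwd, rev = brute_force_two_way(ff, nf, fr, nr, expected)
            assert res.chi2_forward == pytest.approx(fwd, rel=1e-12)
            assert res.chi2_reverse == pytest.approx(rev, rel=1e-12)
            assert res.chi2_total == pytest.approx(fwd + rev, rel=1e-12)

    @given(freq_strategy, freq_strategy, size_strategy, size_strategy)
    @settings(max_examples=200, deadline=None)
    def test_symmetry(self, f1, f2, n1, n2):
        """Exchanging the focal and reference sides leaves the total unchanged."""
        for expected in ("pooled", "per-side"):
            a = two_way_chi_square(f1, n1, f2, n2, expected=expected)
            b = two_way_chi_square(f2, n2, f1, n1, expected=expected)
            assert a.chi2_total == pytest.approx(b.chi2_total, rel=1e-12)
            assert a.chi2_forward == pytest.approx(b.chi2_reverse, rel=1e-12)

    @given(freq_strategy, freq_strategy, size_strategy, size_strategy)
    @settings(max_examples=200, deadline=None)
    def test_zero_iff_equal(self, f1, f2, n1, n2):
        res = two_way_chi_square(f1, n1, f2, n2)
        if f1 == f2:
            assert res.chi2_total == 0.0
        else:
            assert res.chi2_total > 0.0

    def test_monotone_in_frequency_gap(self):
        """At fixed allele numbers the statistic strictly increases as the
        focal frequency moves away from the reference frequency."""
        for expected in ("pooled", "per-side"):
            for f_ref in (0.1, 0.5, 0.9):
                up = [
                    two_way_chi_square(f, 200, f_ref, 1000, expected=expected).chi2_total
                    for f in np.linspace(f_ref, 0.999, 60)
                ]
                down = [
                    two_way_chi_square(f, 200, f_ref, 1000, expected=expected).chi2_total
                    for f in np.linspace(f_ref, 0.001, 60)
                ]
                assert all(b > a for a, b in zip(up, up[1:]))
                assert all(b > a for a, b in zip(down, down[1:]))

    def test_p_value_matches_density_quadrature(self):
        """p equals the df=1 upper-tail mass at the statistic, checked against
        quadrature of a hand-coded chi-square density on 100 random pairs."""
        rng = np.random.default_rng(7)

        def density(x):
            return math.exp(-x / 2.0) / math.sqrt(2.0 * math.pi * x)

        for _ in range(100):
            ff, fr = rng.uniform(0.2, 0.8, 2)
            res = two_way_chi_square(ff, 50, fr, 60)
            if res.chi2_total == 0.0 or res.chi2_total > 500:
                continue
            tail, _ = quad(density, res.chi2_total, np.inf, epsabs=0, epsrel=1e-12)
            assert res.p_value == pytest.approx(tail, rel=1e-8)

    def test_frequencies_must_be_interior(self):
        with pytest.raises(ValueError, match="strictly"):
            two_way_chi_square(0.0, 100, 0.5, 100)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n_var,n_pop,expected",
        [
            (0.05, 250, 6, 0.05 / 1500),
            (0.05, 1, 1, 0.05),
            (0.05, 10, 10, 5e-4),
        ],
    )
    def test_threshold_arithmetic(self, alpha, n_var, n_pop, expected):
        scheme = BonferroniScheme(alpha=alpha, n_variants=n_var, n_reference_pops=n_pop)
        assert bonferroni_threshold(scheme) == pytest.approx(expected, rel=1e-12)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            BonferroniScheme(alpha=0.05, n_variants=0, n_reference_pops=6)

    def test_two_stage_calls(self):
        scheme = BonferroniScheme(alpha=0.05, n_variants=250, n_reference_pops=6)
        frame = pd.DataFrame(
            {
                "variant": ["rs1", "rs2", "rs3"],
                "p_value": [0.04, 1e-6, scheme.adjusted_level],
            }
        )
        called = call_significance(frame, scheme)
        assert called["pass_alpha"].tolist() == [True, True, True]
        # rs1 passes stage 1 only; ties at the adjusted level are significant
        assert called["significant"].tolist() == [False, True, True]

    def test_empty_input(self):
        scheme = BonferroniScheme()
        out = call_significance(pd.DataFrame(columns=["variant", "p_value"]), scheme)
        assert len(out) == 0 and "significant" in out.columns
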