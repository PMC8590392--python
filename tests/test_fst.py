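"""Weir-Cockerham estimator: frozen arithmetic, oracle agreement, invariances."""

import numpy as np
import pandas as pd
import pytest

from pgxdiff.fst import (
    flag_high_fst,
    wc_components,
    wc_theta_from_genotypes,
    wc_theta_weighted,
)
from pgxdiff.simulate import PopulationSpec, SimulationConfig, simulate_cohort
from pgxdiff.types import SamplePanel

from conftest import make_variant


def oracle_wc(n, p, h):
    """Independent scalar transcription of the 1984 moment formulas."""
    n = [float(x) for x in n]
    p = [float(x) for x in p]
    h = [float(x) for x in h]
    r = len(n)
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(x * x for x in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


class TestComponents:
    def test_fixed_difference(self):
        res = wc_components([50, 50], [1.0, 0.0], [0.0, 0.0])
        assert (res.a, res.b, res.c) == (0.5, 0.0, 0.0)
        assert res.theta == 1.0 and res.defined

    def test_frozen_two_population_arithmetic(self):
        res = wc_components([50, 50], [0.9, 0.1], [0.18, 0.18])
        assert res.a == pytest.approx(0.319082, abs=1e-6)
        assert res.b == pytest.approx(0.000918, abs=1e-6)
        assert res.c == pytest.approx(0.09, abs=1e-12)
        assert res.theta == pytest.approx(0.778248, abs=1e-6)

    def test_identical_monomorphic_undefined(self):
        res = wc_components([50, 50], [0.0, 0.0], [0.0, 0.0])
        assert (res.a, res.b, res.c) == (0.0, 0.0, 0.0)
        assert not res.defined and np.isnan(res.theta)

    def test_oracle_equivalence_random_inputs(self):
        """500 random two-population inputs match the independent
        transcription of the 1984 formulas to 1e-10."""
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = rng.integers(2, 500, size=2)
            p = rng.uniform(0.0, 1.0, size=2)
            h = np.minimum(rng.uniform(0.0, 1.0, size=2), 2 * np.minimum(p, 1 - p))
            res = wc_components(n, p, h)
            a, b, c = oracle_wc(n, p, h)
            assert res.a == pytest.approx(a, abs=1e-10)
            assert res.b == pytest.approx(b, abs=1e-10)
            assert res.c == pytest.approx(c, abs=1e-10)
            if a + b + c != 0:
                assert res.theta == pytest.approx(a / (a + b + c), abs=1e-10)

    def test_permutation_invariance(self):
        res1 = wc_components([30, 70], [0.8, 0.3], [0.2, 0.4])
        res2 = wc_components([70, 30], [0.3, 0.8], [0.4, 0.2])
        assert res1.theta == pytest.approx(res2.theta, rel=1e-12)

    def test_allele_relabel_invariance(self):
        res1 = wc_components([30, 70], [0.8, 0.3], [0.2, 0.4])
        res2 = wc_components([30, 70], [0.2, 0.7], [0.2, 0.4])
        assert res1.a == pytest.approx(res2.a, rel=1e-12)
        assert res1.b == pytest.approx(res2.b, rel=1e-12)
        assert res1.c == pytest.approx(res2.c, rel=1e-12)

    def test_theta_never_exceeds_one_and_negatives_kept(self):
        rng = np.random.default_rng(3)
        saw_negative = False
        for _ in range(300):
            n = rng.integers(2, 200, size=2)
            p = rng.uniform(0.0, 1.0, size=2)
            h = np.minimum(rng.uniform(0.0, 1.0, size=2), 2 * np.minimum(p, 1 - p))
            res = wc_components(n, p, h)
            if res.defined:
                assert res.theta <= 1.0 + 1e-12
                saw_negative |= res.theta < 0
        assert saw_negative  # the estimator legitimately goes negative

    def test_all_singleton_populations_flagged(self):
        res = wc_components([1, 1], [0.5, 0.5], [1.0, 1.0])
        assert not res.defined


class TestFromGenotypes:
    def _two_pop_panel(self, n1, n2):
        return SamplePanel(
            [(f"a{i}", "A", None) for i in range(n1)]
            + [(f"b{i}", "B", None) for i in range(n2)]
        )

    def test_opposite_fixation_gives_one(self):
        panel = self._two_pop_panel(50, 50)
        rec = make_variant(genotypes=[2] * 50 + [0] * 50)
        out = wc_theta_from_genotypes([rec], panel, ("A", "B"))
        assert out.iloc[0].theta == pytest.approx(1.0)

    def test_identical_vectors_never_positive(self):
        panel = self._two_pop_panel(20, 20)
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = rng.integers(0, 3, size=20)
            rec = make_variant(genotypes=np.concatenate([g, g]))
            out = wc_theta_from_genotypes([rec], panel, ("A", "B"))
            row = out.iloc[0]
            assert (not row.defined) or row.theta <= 1e-12

    def test_matches_component_route_on_simulated_sites(self):
        """Dosage-derived components equal direct (n, p, h) arithmetic on 500
        simulated sites to 1e-10."""
        config = SimulationConfig(
            n_loci=500,
            populations=(
                PopulationSpec("A", 60, 0.2, "focal"),
                PopulationSpec("B", 80, 0.2, "focal"),
            ),
            seed=9,
        )
        cohort = simulate_cohort(config)
        out = wc_theta_from_genotypes(cohort.variants, cohort.panel, ("A", "B"))
        geno = np.stack([rec.genotypes for rec in cohort.variants])
        for i, rec in enumerate(cohort.variants):
            gA, gB = geno[i, :60], geno[i, 60:]
            n = [len(gA), len(gB)]
            p = [gA.mean() / 2, gB.mean() / 2]
            h = [(gA == 1).mean(), (gB == 1).mean()]
            a, b, c = oracle_wc(n, p, h)
            row = out.iloc[i]
            assert row.a == pytest.approx(a, abs=1e-10)
            assert row.b == pytest.approx(b, abs=1e-10)
            assert row.c == pytest.approx(c, abs=1e-10)

    def test_fully_missing_population_undefined(self):
        panel = self._two_pop_panel(2, 2)
        rec = make_variant(genotypes=[-1, -1, 1, 2])
        out = wc_theta_from_genotypes([rec], panel, ("A", "B"))
        assert not out.iloc[0].defined


class TestWeightedTheta:
    def test_single_site_equals_its_theta(self):
        df = pd.DataFrame({"a": [0.3], "b": [0.1], "c": [0.2], "defined": [True]})
        assert wc_theta_weighted(df) == pytest.approx(0.5)

    def test_all_fixed_sites_give_one(self):
        df = pd.DataFrame(
            {"a": [0.5, 0.4], "b": [0.0, 0.0], "c": [0.0, 0.0], "defined": [True, True]}
        )
        assert wc_theta_weighted(df) == 1.0

    def test_no_usable_sites_rejected(self):
        df = pd.DataFrame({"a": [np.nan], "b": [np.nan], "c": [np.nan], "defined": [False]})
        with pytest.raises(ValueError, match="no sites"):
            wc_theta_weighted(df)


class TestHighFstFlag:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["variant", "pop1", "pop2", "theta", "defined"]
        )

    def test_both_focal_populations_qualify(self):
        table = self._table(
            [("rs1", "A", "EAS", 0.52, True), ("rs1", "B", "EAS", 0.55, True)]
        )
        assert flag_high_fst(table, 0.5, ["A", "B"]) == {"rs1"}

    def test_single_population_modes(self):
        table = self._table(
            [("rs1", "A", "EAS", 0.52, True), ("rs1", "B", "EAS", 0.31, True)]
        )
        assert flag_high_fst(table, 0.5, ["A", "B"], mode="both") == set()
        assert flag_high_fst(table, 0.5, ["A", "B"], mode="any") == {"rs1"}

    def test_undefined_never_flagged(self):
        table = self._table(
            [("rs1", "A", "EAS", np.nan, False), ("rs1", "B", "EAS", np.nan, False)]
        )
        assert flag_high_fst(table, 0.5, ["A", "B"]) == set()

    def test_focal_focal_pairs_ignored(self):
        table = self._table(
            [("rs1", "A", "B", 0.9, True), ("rs1", "B", "A", 0.9, True)]
        )
        assert flag_high_fst(table, 0.5, ["A", "B"]) == set()
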