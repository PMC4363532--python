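"""KS threshold selection, survival curves, chi-square verification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffcoex import (
    chi_square,
    dichotomize,
    find_threshold,
    ks_pvalue,
    optimal_threshold,
    survival_curves,
)
from diffcoex.threshold import survival_fraction
from tests.conftest import random_pair_table


def kolmogorov_tail_series(lam, terms=100):
    """Independent oracle: 2 * sum (-1)^(k-1) exp(-2 k^2 lam^2)."""
    if lam == 0:
        return 1.0
    k = np.arange(1, terms + 1)
    return float(2 * np.sum((-1.0) ** (k - 1) * np.exp(-2 * k**2 * lam**2)))


class TestSurvivalCurves:
    def test_inclusive_at_observed_value(self):
        assert survival_fraction(np.full(5, 0.5), np.array([0.5]))[0] == 1.0

    def test_everything_survives_zero_threshold(self, rng):
        table = random_pair_table(rng, 30)
        curve = survival_curves(table)
        assert curve.f_disease[0] == 1.0 and curve.f_normal[0] == 1.0

    def test_direct_count(self):
        vals = np.array([0.2, 0.6, 0.8])
        assert survival_fraction(vals, np.array([0.6]))[0] == pytest.approx(2 / 3)

    def test_fractions_are_multiples_of_one_over_n(self, rng):
        table = random_pair_table(rng, 17)
        curve = survival_curves(table)
        for f in (curve.f_disease, curve.f_normal):
            np.testing.assert_allclose(np.round(f * 17) / 17, f, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 60))
    def test_monotone_non_increasing(self, seed, n):
        table = random_pair_table(np.random.default_rng(seed), n)
        curve = survival_curves(table)
        assert (np.diff(curve.f_disease) <= 1e-15).all()
        assert (np.diff(curve.f_normal) <= 1e-15).all()

    def test_uniform_grid_matches_observed_optimum(self, rng):
        # the step functions only change at observed levels, so the dense
        # uniform grid finds the same maximal deviation; its achieving
        # threshold may sit anywhere in the flat stretch below the observed
        # optimum, never above it
        table = random_pair_table(rng, 40)
        c1, d1 = optimal_threshold(survival_curves(table, grid="observed"))
        c2, d2 = optimal_threshold(survival_curves(table, grid=0.0001))
        assert d2 == pytest.approx(d1, abs=1e-12)
        assert c2 <= c1 + 1e-12


class TestOptimalThreshold:
    def test_identical_distributions_give_zero_deviation(self):
        df = pd.DataFrame(
            {
                "gene_a": list("abc"),
                "gene_b": list("xyz"),
                "r_disease": [0.1, 0.5, 0.9],
                "r_normal": [0.1, 0.5, 0.9],
                "c_disease": [0.1, 0.5, 0.9],
                "c_normal": [0.1, 0.5, 0.9],
            }
        )
        from diffcoex import CoexpressionTable

        _, d = optimal_threshold(survival_curves(CoexpressionTable(df, 3)))
        assert d == 0.0

    def test_complete_separation_gives_unit_deviation(self):
        from diffcoex import CoexpressionTable

        df = pd.DataFrame(
            {
                "gene_a": list("ab"),
                "gene_b": list("xy"),
                "r_disease": [0.1, 0.1],
                "r_normal": [0.9, 0.9],
                "c_disease": [0.1, 0.1],
                "c_normal": [0.9, 0.9],
            }
        )
        c_star, d = optimal_threshold(survival_curves(CoexpressionTable(df, 2)))
        assert d == 1.0
        assert 0.1 < c_star <= 0.9

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 100_000), n=st.integers(2, 50))
    def test_matches_brute_force_scan(self, seed, n):
        """D equals an exhaustive scan over every pooled level (oracle)."""
        table = random_pair_table(np.random.default_rng(seed), n)
        c_star, d = optimal_threshold(survival_curves(table))
        c_d = table.pairs["c_disease"].to_numpy()
        c_n = table.pairs["c_normal"].to_numpy()
        best_d, best_t = 0.0, 0.0
        for t in sorted(set(np.concatenate([[0.0, 1.0], c_d, c_n]))):
            dev = abs((c_d >= t).mean() - (c_n >= t).mean())
            if dev > best_d + 1e-15:
                best_d, best_t = dev, t
        assert d == pytest.approx(best_d, abs=1e-12)
        assert c_star == pytest.approx(best_t, abs=1e-12)

    def test_smallest_achieving_threshold_on_ties(self):
        from diffcoex import CoexpressionTable

        # deviation 0.5 achieved at both 0.4 and 0.9; smallest level wins
        df = pd.DataFrame(
            {
                "gene_a": list("ab"),
                "gene_b": list("xy"),
                "r_disease": [0.1, 0.6],
                "r_normal": [0.4, 0.9],
                "c_disease": [0.1, 0.6],
                "c_normal": [0.4, 0.9],
            }
        )
        c_star, d = optimal_threshold(survival_curves(CoexpressionTable(df, 2)))
        assert d == pytest.approx(0.5)
        assert c_star == pytest.approx(0.4)


class TestKSPvalue:
    def test_matches_tail_series_oracle(self):
        for d, n, m in [(0.2789, 190, 190), (0.1, 100, 50), (0.5, 30, 30)]:
            lam = np.sqrt(n * m / (n + m)) * d
            assert ks_pvalue(d, n, m) == pytest.approx(
                kolmogorov_tail_series(lam), rel=1e-12
            )

    def test_zero_deviation_gives_p_one(self):
        assert ks_pvalue(0.0, 190, 190) == 1.0

    def test_full_deviation_is_overwhelming_at_n190(self):
        assert ks_pvalue(1.0, 190, 190) < 1e-10


class TestDichotomizeAndChiSquare:
    def test_zero_threshold_marks_everything_strong(self, rng):
        table = random_pair_table(rng, 25)
        t = dichotomize(table, 0.0)
        assert t.loc["strong", "disease"] == 25
        assert t.loc["strong", "normal"] == 25

    def test_threshold_is_inclusive(self):
        from diffcoex import CoexpressionTable

        df = pd.DataFrame(
            {
                "gene_a": ["a"], "gene_b": ["b"],
                "r_disease": [0.7], "r_normal": [0.2],
                "c_disease": [0.7], "c_normal": [0.2],
            }
        )
        t = dichotomize(CoexpressionTable(df, 2), 0.7)
        assert t.loc["strong", "disease"] == 1
        assert t.loc["strong", "normal"] == 0

    def test_column_sums_equal_pair_count(self, rng):
        table = random_pair_table(rng, 33)
        t = dichotomize(table, 0.5)
        assert (t.sum(axis=0) == 33).all()

    def test_chi_square_independence_is_zero(self):
        chi2, p = chi_square(np.array([[50, 50], [50, 50]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi_square_closed_form(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) for (10,20;30,40)
        chi2, _ = chi_square(np.array([[10, 20], [30, 40]]))
        expected = 100 * (10 * 40 - 20 * 30) ** 2 / (30 * 70 * 40 * 60)
        assert chi2 == pytest.approx(expected, abs=1e-12)
        assert round(chi2, 4) == 0.7937

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square(np.array([[0, 0], [30, 40]]))


def test_find_threshold_internally_consistent(rng):
    """Contingency strong counts equal n_pairs * survival at C*."""
    for _ in range(10):
        table = random_pair_table(rng, 40)
        res = find_threshold(table)
        k = int(np.searchsorted(res.curve.thresholds, res.c_star))
        assert res.curve.thresholds[k] == pytest.approx(res.c_star)
        assert res.table.loc["strong", "disease"] == pytest.approx(
            40 * res.curve.f_disease[k]
        )
        assert res.table.loc["strong", "normal"] == pytest.approx(
            40 * res.curve.f_normal[k]
        )
        assert res.d == pytest.approx(
            abs(res.curve.f_normal[k] - res.curve.f_disease[k]), abs=1e-15
        )
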