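"""Audic-Claverie mass, tails, BH adjustment, and DE calling."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

from dgetag.diffexpr import _log_mass, ac_probability, ac_pvalue_two_sided, bh_fdr, call_de


def exact_mass(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Exact rational evaluation of the conditional mass."""
    r = Fraction(n2, n1)
    return r**y * comb(x + y, y) / (1 + r) ** (x + y + 1)


def exact_pvalue(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Exact doubled-smaller-tail p-value (canonical orientation)."""
    if (y, n2) < (x, n1):
        x, y, n1, n2 = y, x, n2, n1
    lower = sum(exact_mass(x, k, n1, n2) for k in range(y + 1))
    upper = 1 - lower + exact_mass(x, y, n1, n2)
    return min(Fraction(1), 2 * min(lower, upper))


class TestMass:
    def test_equal_depth_closed_forms(self):
        assert ac_probability(0, 0, 1e6, 1e6) == pytest.approx(0.5)
        assert ac_probability(1, 1, 1e6, 1e6) == pytest.approx(0.25)

    def test_exact_rational_oracle(self):
        cases = [(10, 30, 10**6, 10**6), (0, 5, 10**6, 2 * 10**6), (40, 3, 10**5, 10**6)]
        for x, y, n1, n2 in cases:
            assert ac_probability(x, y, n1, n2) == pytest.approx(
                float(exact_mass(x, y, n1, n2)), rel=1e-10
            )

    def test_matches_negative_binomial_form(self):
        # independent route: the mass is NB(x+1, N1/(N1+N2)) in y
        rng = np.random.default_rng(1)
        for _ in range(50):
            x, y = int(rng.integers(0, 80)), int(rng.integers(0, 80))
            n1, n2 = rng.uniform(1e5, 5e6, 2)
            assert ac_probability(x, y, n1, n2) == pytest.approx(
                nbinom.pmf(y, x + 1, n1 / (n1 + n2)), rel=1e-9
            )

    def test_normalisation_sums_to_one(self):
        for x in (0, 1, 5, 17, 50, 100):
            for ratio in (0.1, 0.5, 1.0, 2.0, 10.0):
                n1, n2 = 1e6, ratio * 1e6
                mean = (x + 1) * ratio
                kmax = int(mean + 50 * np.sqrt(mean * (1 + ratio)) + 500)
                total = np.exp(
                    _log_mass(x, np.arange(kmax + 1, dtype=float), n1, n2)
                ).sum()
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ac_probability(-1, 0, 1e6, 1e6)
        with pytest.raises(ValueError):
            ac_pvalue_two_sided(0, 0, 0, 1e6)


class TestPvalue:
    def test_symmetric_under_library_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x, y = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            n1, n2 = int(rng.integers(10**5, 10**7)), int(rng.integers(10**5, 10**7))
            assert ac_pvalue_two_sided(x, y, n1, n2) == ac_pvalue_two_sided(y, x, n2, n1)

    def test_equal_counts_near_one(self):
        p = ac_pvalue_two_sided(3, 3, 1e6, 1e6)
        assert p >= ac_probability(3, 3, 1e6, 1e6)
        assert p == pytest.approx(float(exact_pvalue(3, 3, 10**6, 10**6)), rel=1e-9)
        assert p > 0.8

    def test_extreme_difference_tiny_p(self):
        assert ac_pvalue_two_sided(0, 200, 1e6, 1e6) < 1e-10

    def test_exact_big_integer_oracle_random_cases(self):
        """>=100 random (x, y, N1, N2) cases against exact rationals."""
        rng = np.random.default_rng(3)
        for _ in range(120):
            x, y = int(rng.integers(0, 60)), int(rng.integers(0, 60))
            n1, n2 = int(rng.integers(10**5, 2 * 10**6)), int(rng.integers(10**5, 2 * 10**6))
            expected = float(exact_pvalue(x, y, n1, n2))
            got = ac_pvalue_two_sided(x, y, n1, n2)
            assert got == pytest.approx(expected, rel=1e-8, abs=1e-300)

    def test_null_type_one_error_super_uniform(self):
        """Empirical type-I error under a Poisson equal-rate null."""
        rng = np.random.default_rng(4)
        n_genes, depth = 2000, 10**6
        rates = rng.lognormal(np.log(100), 1.0, n_genes)
        x = rng.poisson(rates)
        y = rng.poisson(rates)
        p = np.array(
            [ac_pvalue_two_sided(int(a), int(b), depth, depth) for a, b in zip(x, y)]
        )
        for alpha in (0.005, 0.05):
            se = np.sqrt(alpha * (1 - alpha) / n_genes)
            assert (p < alpha).mean() <= alpha + 3 * se


class TestBH:
    def test_single_and_degenerate_vectors(self):
        assert bh_fdr([0.01]) == pytest.approx([0.01])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert bh_fdr([]).size == 0

    def test_hand_computed_step_up(self):
        # p(i) * n / i then cumulative min from the largest rank
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([0.001, 0.01, 0.9]) == pytest.approx([0.003, 0.015, 0.9])

    def test_order_preserved(self):
        out = bh_fdr([0.9, 0.001, 0.01])
        assert out == pytest.approx([0.9, 0.003, 0.015])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCallDE:
    def test_prefilter_blocks_low_intensity_genes(self):
        x = pd.Series({"g": 30, "h": 500})
        y = pd.Series({"g": 35, "h": 5})
        table = call_de(x, y, 10**6, 10**6)
        assert table.loc["g", "prefiltered"] and not table.loc["g", "significant"]
        assert np.isnan(table.loc["g", "p"])
        assert table.loc["h", "significant"]

    def test_floored_fold_change_for_undetected_gene(self):
        # tpm1 floors at 0.01, tpm2 = 775.83 -> |log2 fc| ~ 16.2
        n = 5_000_000
        x = pd.Series({"g": 0})
        y = pd.Series({"g": int(round(775.83 * n / 1e6))})
        table = call_de(x, y, n, n)
        assert table.loc["g", "tpm1"] == 0.01
        assert abs(table.loc["g", "log2fc"]) == pytest.approx(
            np.log2(775.83 / 0.01), rel=1e-3
        )
        assert abs(table.loc["g", "log2fc"]) > 2

    def test_bh_over_tested_set_only(self):
        x = pd.Series({"a": 0, "b": 1000, "c": 10, "d": 900})
        y = pd.Series({"a": 300, "b": 1020, "c": 12, "d": 100})
        table = call_de(x, y, 10**6, 10**6)
        tested = table.index[~table["prefiltered"]]
        assert list(tested) == ["a", "b", "d"]
        manual = bh_fdr(table.loc[tested, "p"].to_numpy())
        assert table.loc[tested, "fdr"].to_numpy() == pytest.approx(manual)
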