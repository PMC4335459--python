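"""Tests for follow-up statistics: OR, trend, HWE, enrichment, power."""

import math

import numpy as np
import pytest
from scipy import stats

from poolassoc.stats import (
    PowerSpec,
    allelic_or_ci,
    allelic_or_from_maf,
    allelic_power,
    armitage_trend,
    binomial_enrichment,
    hwe_exact,
)


class TestAllelicOR:
    def test_identity_and_validation(self):
        assert allelic_or_from_maf(0.17, 0.17) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="maf_control"):
            allelic_or_from_maf(0.1, 0.0)

    @pytest.mark.parametrize(
        "maf_case, maf_control, expected",
        [(0.0108, 0.0047, 2.31), (0.0094, 0.0130, 0.72)],
    )
    def test_reconstructed_ors(self, maf_case, maf_control, expected):
        assert allelic_or_from_maf(maf_case, maf_control) == pytest.approx(
            expected, abs=0.005
        )

    def test_ci_symmetric_on_log_scale_and_narrows_with_counts(self):
        or_, lo, hi = allelic_or_ci(10, 90, 10, 90)
        assert or_ == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0, rel=1e-9)
        _, lo2, hi2 = allelic_or_ci(20, 180, 20, 180)
        assert lo2 > lo and hi2 < hi

    def test_haldane_correction_on_zero_cell(self):
        or_, lo, hi = allelic_or_ci(0, 100, 5, 95)
        assert 0 < lo < or_ < hi

    def test_ci_coverage_simulation(self):
        rng = np.random.default_rng(12)
        p0, or_true = 0.05, 1.5
        p1 = p0 * or_true / (1 + p0 * (or_true - 1))
        m = 2 * 2000
        cover = 0
        reps = 400
        for _ in range(reps):
            a = rng.binomial(m, p1)
            c = rng.binomial(m, p0)
            _, lo, hi = allelic_or_ci(a, m - a, c, m - c)
            cover += lo <= or_true <= hi
        assert 0.92 <= cover / reps <= 0.98


class TestTrend:
    def test_null_table_gives_zero(self):
        chi2, p = armitage_trend((50, 30, 20), (50, 30, 20))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_matches_textbook_formula(self):
        r = np.array([30.0, 50.0, 20.0])
        s = np.array([40.0, 45.0, 15.0])
        x = np.array([0.0, 1.0, 2.0])
        n = r + s
        N, R = n.sum(), r.sum()
        num = (N * np.sum(x * r) - R * np.sum(x * n)) ** 2
        den = R * (N - R) * (N * np.sum(x**2 * n) - np.sum(x * n) ** 2) / N
        expected = num / den
        chi2, _ = armitage_trend(tuple(r), tuple(s))
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_close_to_allelic_chi2_under_hwe(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p_ctrl = rng.uniform(0.2, 0.5)
            p_case = p_ctrl + rng.uniform(-0.03, 0.03)
            n = 4000
            case = rng.multinomial(n, [(1 - p_case) ** 2, 2 * p_case * (1 - p_case), p_case**2])
            ctrl = rng.multinomial(n, [(1 - p_ctrl) ** 2, 2 * p_ctrl * (1 - p_ctrl), p_ctrl**2])
            trend_chi2, _ = armitage_trend(tuple(case), tuple(ctrl))
            a = case[1] + 2 * case[2]
            c = ctrl[1] + 2 * ctrl[2]
            table = [[a, 2 * n - a], [c, 2 * n - c]]
            allelic = stats.chi2_contingency(table, correction=False)[0]
            if allelic > 1:  # avoid ratio blow-up at near-zero statistics
                assert trend_chi2 == pytest.approx(allelic, rel=0.05)

    def test_degenerate_distribution(self):
        chi2, p = armitage_trend((100, 0, 0), (50, 0, 0))
        assert (chi2, p) == (0.0, 1.0)


class TestHWE:
    def test_perfect_hwe_large_p(self):
        assert hwe_exact(25, 50, 25) > 0.5

    def test_monomorphic_returns_one(self):
        assert hwe_exact(100, 0, 0) == 1.0

    def test_matches_exact_enumeration_oracle(self):
        # independent oracle: exact conditional probabilities via math.comb
        def oracle(n_AA, n_Aa, n_aa):
            n = n_AA + n_Aa + n_aa
            m = 2 * n_aa + n_Aa  # minor allele count
            m = min(m, 2 * n - m)
            probs = {}
            for het in range(m % 2, m + 1, 2):
                hom_r = (m - het) // 2
                hom_c = n - het - hom_r
                # multinomial arrangements x 2^het over C(2n, m) orderings
                ways = (
                    math.factorial(n)
                    // (math.factorial(hom_r) * math.factorial(het) * math.factorial(hom_c))
                ) * 2**het
                probs[het] = ways
            total = sum(probs.values())
            obs = probs[n_Aa]
            return sum(v for v in probs.values() if v <= obs) / total

        for counts in [(5, 3, 2), (7, 1, 2), (2, 6, 2), (10, 0, 5), (4, 4, 4)]:
            assert hwe_exact(*counts) == pytest.approx(oracle(*counts), rel=1e-9)

    def test_distribution_normalised_extreme_het_deficit(self):
        # strong heterozygote deficit should give a tiny p
        assert hwe_exact(50, 0, 50) < 1e-6
        assert 0 < hwe_exact(30, 20, 10) <= 1


class TestEnrichment:
    def test_trivial_tails(self):
        assert binomial_enrichment(0, 79, 0.05) == 1.0
        assert binomial_enrichment(10, 10, 0.5) == pytest.approx(0.5**10)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(6)
        draws = rng.binomial(79, 0.05, size=1_000_000)
        mc = (draws >= 11).mean()
        exact = binomial_enrichment(11, 79, 0.05)
        se = np.sqrt(exact * (1 - exact) / 1_000_000)
        assert abs(mc - exact) < 3 * se + 1e-9


class TestPower:
    def test_null_or_returns_alpha(self):
        for alpha in (0.05, 0.01):
            power = allelic_power(PowerSpec(0.1, 1.0, alpha, 1000, 1000))
            assert power == pytest.approx(alpha, abs=0.005)

    def test_monotone_in_or_n_and_alpha(self):
        base = PowerSpec(0.025, 1.3, 0.01, 3000, 3000)
        by_or = [
            allelic_power(PowerSpec(0.025, o, 0.01, 3000, 3000))
            for o in (1.1, 1.3, 1.6, 2.0)
        ]
        assert all(a < b for a, b in zip(by_or, by_or[1:]))
        by_n = [
            allelic_power(PowerSpec(0.025, 1.3, 0.01, n, n)) for n in (500, 2000, 8000)
        ]
        assert all(a < b for a, b in zip(by_n, by_n[1:]))
        by_alpha = [
            allelic_power(PowerSpec(0.025, 1.3, a, 3000, 3000))
            for a in (1e-4, 1e-2, 0.05)
        ]
        assert all(a < b for a, b in zip(by_alpha, by_alpha[1:]))
        by_ctrl = [
            allelic_power(PowerSpec(0.025, 1.3, 0.01, 3000, n)) for n in (1000, 4000)
        ]
        assert by_ctrl[0] < by_ctrl[1]

    def test_protective_or_symmetric_behaviour(self):
        # ORs below 1 also yield power above alpha
        assert allelic_power(PowerSpec(0.1, 0.6, 0.05, 2000, 2000)) > 0.5

    def test_validation(self):
        with pytest.raises(ValueError, match="odds_ratio"):
            allelic_power(PowerSpec(0.1, 0.0, 0.05, 100, 100))
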