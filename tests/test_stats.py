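"""Inference machinery vs independent oracles (enumeration, scipy, algebra)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from breedtrends.io_formats import CBARQ_SCALES
from breedtrends.stats import (
    adjust_bh,
    adjust_bonferroni,
    adjust_by,
    bootstrap_ci,
    correlation_screen,
    one_way_anova,
    pearson_r,
    permutation_pvalue,
    variance_explained,
    wilcoxon_signed_rank,
)


def exhaustive_permutation_p(x, y):
    """Two-sided permutation p over all n! permutations (oracle)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r_obs = abs(pearson_r(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        total += 1
        if abs(pearson_r(x, y[list(perm)])) >= r_obs - 1e-12:
            count += 1
    return count / total


class TestPearson:
    def test_perfect_and_reflected(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 15))
            assert pearson_r(x, y) == pytest.approx(sps.pearsonr(x, y)[0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPermutationPvalue:
    def test_matches_exhaustive_enumeration(self, rng):
        B = 20_000
        for n in (4, 5, 6):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            p_exact = exhaustive_permutation_p(x, y)
            p_mc = permutation_pvalue(x, y, B=B, seed=rng)
            se = math.sqrt(p_exact * (1 - p_exact) / B)
            assert abs(p_mc - p_exact) <= 3 * se + 2 / B

    def test_perfect_correlation_hits_floor(self, rng):
        x = np.arange(20.0)
        p = permutation_pvalue(x, x, B=5_000, seed=rng)
        assert p <= 10 / 5_001  # near the attainable minimum 1/(B+1)

    def test_add_one_convention_lower_bound(self, rng):
        p = permutation_pvalue([1.0, 2.0, 3.0], [1.0, 5.0, 2.0], B=50, seed=rng)
        assert p >= 1 / 51

    def test_affine_invariance_exact(self):
        x = np.array([0.3, -1.2, 0.7, 2.0, -0.5, 1.1])
        y = np.array([1.0, 0.2, -0.4, 1.5, 0.3, -1.0])
        p1 = permutation_pvalue(x, y, B=2_000, seed=42)
        p2 = permutation_pvalue(3.5 * x - 2, y, B=2_000, seed=42)
        p3 = permutation_pvalue(x, 0.1 * y + 7, B=2_000, seed=42)
        assert p1 == p2 == p3

    def test_pair_reordering_invariance(self, rng):
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        sigma = rng.permutation(6)
        # the exact (exhaustive) p is reorder-invariant; both MC estimates
        # must agree with it, hence with each other, to Monte-Carlo error
        assert exhaustive_permutation_p(x, y) == pytest.approx(
            exhaustive_permutation_p(x[sigma], y[sigma])
        )


class TestBootstrapCI:
    def test_perfect_correlation_collapses(self, rng):
        x = np.arange(10.0)
        lo, hi = bootstrap_ci(x, x, B=500, seed=rng)
        assert lo == pytest.approx(1.0, abs=1e-12)
        assert hi == pytest.approx(1.0, abs=1e-12)

    def test_fixed_seed_determinism(self):
        x = np.arange(15.0)
        y = np.array([2.0, 1, 4, 3, 6, 5, 8, 7, 10, 9, 12, 11, 14, 13, 16])
        assert bootstrap_ci(x, y, B=500, seed=7) == bootstrap_ci(
            x, y, B=500, seed=7
        )

    def test_interval_brackets_r(self, rng):
        x = rng.standard_normal(60)
        y = 0.6 * x + 0.8 * rng.standard_normal(60)
        lo, hi = bootstrap_ci(x, y, B=2_000, seed=rng)
        assert lo < pearson_r(x, y) < hi


class TestAdjustments:
    def test_bonferroni_arithmetic_and_cap(self):
        out = adjust_bonferroni([0.003, 0.2], m=14)
        assert out[0] == pytest.approx(0.042)
        assert out[1] == 1.0

    def test_bonferroni_dominates_raw(self, rng):
        p = rng.uniform(size=30)
        assert (adjust_bonferroni(p) >= p).all()

    def test_by_hand_computed_step_up(self):
        # m=2, c(2)=1.5: (0.025*2*1.5/1, 0.5*2*1.5/2) = (0.075, 0.75)
        assert adjust_by([0.025, 0.5]) == pytest.approx([0.075, 0.75])

    def test_by_single_p_unchanged(self):
        assert adjust_by([0.3]) == pytest.approx([0.3])

    def test_by_dominates_bh_dominates_raw(self, rng):
        for _ in range(10):
            p = rng.uniform(size=25)
            by, bh = adjust_by(p), adjust_bh(p)
            assert (by >= bh - 1e-12).all()
            assert (bh >= p - 1e-12).all()
            # both order-preserving
            order = np.argsort(p)
            assert (np.diff(by[order]) >= -1e-12).all()
            assert (np.diff(bh[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_by([0.5, 1.2])


class TestAnova:
    def test_hand_computed_two_groups(self):
        res = one_way_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(13.5)
        assert res.df == (1, 4)
        assert res.eta_squared == pytest.approx(13.5 / 17.5)

    def test_f_equals_squared_t_for_two_groups(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(15) + 0.5
        res = one_way_anova(
            np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15
        )
        t, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t**2)
        assert res.p == pytest.approx(p_t)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.standard_normal(8) + mu for mu in (0, 0.3, 1.0)]
        labels = sum(([g] * 8 for g in "abc"), [])
        res = one_way_anova(np.concatenate(groups), labels)
        F, p = sps.f_oneway(*groups)
        assert (res.F, res.p) == (pytest.approx(F), pytest.approx(p))

    def test_null_groups_small_eta(self, rng):
        vals = rng.standard_normal(300)
        res = one_way_anova(vals, np.repeat(list("abc"), 100))
        assert res.eta_squared < 0.05

    def test_degenerate_zero_within_variance(self):
        res = one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert res.degenerate and res.p > 0 and math.isinf(res.F)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            one_way_anova([2, 2, 2, 2], ["a", "a", "b", "b"])


class TestVarianceExplained:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        assert variance_explained(2 * x + 1, x) == pytest.approx(1.0)

    def test_equals_squared_pearson(self, rng):
        x, y = rng.standard_normal((2, 40))
        assert variance_explained(y, x) == pytest.approx(
            pearson_r(x, y) ** 2, abs=1e-12
        )


class TestWilcoxonSignedRank:
    def test_all_positive_differences_exact_p(self):
        a = np.arange(1, 8) + 1.0
        b = np.arange(1, 8).astype(float)
        w, p = wilcoxon_signed_rank(a, b)
        assert w == 28  # maximal positive-rank sum
        assert p == pytest.approx(2 / 2**7)

    def test_swap_symmetry(self, rng):
        a = rng.standard_normal(15)
        b = rng.standard_normal(15)
        w_ab, p_ab = wilcoxon_signed_rank(a, b)
        w_ba, p_ba = wilcoxon_signed_rank(b, a)
        n = 15
        assert w_ab + w_ba == n * (n + 1) / 2
        assert p_ab == pytest.approx(p_ba)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(10):
            a = rng.standard_normal(12)
            b = rng.standard_normal(12)
            _, p = wilcoxon_signed_rank(a, b)
            assert p == pytest.approx(
                sps.wilcoxon(a, b, method="exact").pvalue
            )

    def test_normal_approximation_near_exact(self, rng):
        for _ in range(10):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20) + 0.3
            _, p_exact = wilcoxon_signed_rank(a, b, exact_max_n=25)
            _, p_approx = wilcoxon_signed_rank(a, b, exact_max_n=5)
            assert p_approx == pytest.approx(p_exact, rel=0.10)

    def test_handles_ties_and_zeros(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([1.0, 1.0, 2.0, 3.0, 6.0, 4.0])  # one zero, tied |d|
        w, p = wilcoxon_signed_rank(a, b)
        assert 0 < p <= 1

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="all differences zero"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestCorrelationScreen:
    def _joined(self, rng, n=40, strong=None):
        data = {m: rng.standard_normal(n) for m in
                ("total", "volatility", "rate_up", "rate_down")}
        df = pd.DataFrame(data)
        for t in CBARQ_SCALES:
            df[t] = rng.standard_normal(n)
        if strong:
            measure, trait, rho = strong
            df[trait] = rho * df[measure] + math.sqrt(1 - rho**2) * \
                rng.standard_normal(n)
        return df

    def test_screen_shape_4_by_14(self, rng):
        table = correlation_screen(
            self._joined(rng),
            ["total", "volatility", "rate_up", "rate_down"],
            list(CBARQ_SCALES),
            B=200, seed=rng,
        )
        assert len(table) == 56
        assert table["n"].eq(40).all()

    def test_planted_signal_is_minimal_and_by_significant(self, rng):
        table = correlation_screen(
            self._joined(rng, n=80, strong=("total", "energy", 0.8)),
            ["total", "volatility", "rate_up", "rate_down"],
            list(CBARQ_SCALES),
            B=2_000, seed=rng,
        )
        best = table.loc[table["p_perm"].idxmin()]
        assert (best["measure"], best["trait"]) == ("total", "energy")
        assert best["p_by"] < 0.05

    def test_pairwise_complete_n(self, rng):
        df = self._joined(rng)
        df.loc[:4, "energy"] = np.nan
        table = correlation_screen(df, ["total"], ["energy", "chasing"],
                                   B=200, seed=rng)
        n_by_trait = table.set_index("trait")["n"]
        assert n_by_trait["energy"] == 35 and n_by_trait["chasing"] == 40

    def test_short_pair_skipped(self, rng):
        df = self._joined(rng, n=10)
        df.loc[2:, "energy"] = np.nan
        table = correlation_screen(df, ["total"], ["energy", "chasing"],
                                   B=200, seed=rng)
        assert list(table["trait"]) == ["chasing"]
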