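"""Trend and rank statistics against exact enumeration and scipy oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from ltpa_pgs import trend_stats
from ltpa_pgs.trend_stats import (
    bonferroni_alpha,
    chisq_contingency,
    jonckheere_terpstra,
    mann_whitney_u,
    templeton_normalize,
)


def _jt(values_by_group):
    values = np.concatenate(values_by_group)
    labels = np.concatenate([np.full(len(v), i) for i, v in enumerate(values_by_group)])
    return jonckheere_terpstra(values, labels, list(range(len(values_by_group))))


class TestJonckheereTerpstra:
    def test_perfectly_ordered_groups_exact(self):
        res = _jt([[1, 2], [3, 4], [5, 6]])
        assert res.jt_statistic == 12.0
        assert res.exact
        assert res.p == pytest.approx(2 / 90)

    def test_exact_one_sided_enumeration(self):
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        p_upper, _ = trend_stats._exact_jt_pvalues(groups, 12.0)
        assert p_upper == pytest.approx(1 / 90)

    def test_all_values_tied(self):
        res = _jt([[5, 5, 5], [5, 5], [5, 5, 5]])
        assert res.z == 0.0 and res.p == 1.0

    def test_reversing_group_order_negates_z(self, rng):
        groups = [rng.normal(i, 1, 30).tolist() for i in range(3)]
        values = np.concatenate(groups)
        labels = np.concatenate([np.full(30, i) for i in range(3)])
        fwd = jonckheere_terpstra(values, labels, [0, 1, 2])
        rev = jonckheere_terpstra(values, labels, [2, 1, 0])
        assert rev.z == pytest.approx(-fwd.z, abs=1e-9)
        assert not fwd.exact  # n = 90 uses the normal approximation
        assert rev.p == pytest.approx(fwd.p, abs=1e-9)

    def test_exact_p_matches_brute_force_oracle(self, rng):
        """Exact p agrees with a from-scratch enumeration over value permutations."""
        import itertools

        for _ in range(10):
            sizes = rng.integers(2, 4, size=3)
            values = rng.integers(0, 5, size=sizes.sum()).astype(float)
            groups, i = [], 0
            for s in sizes:
                groups.append(values[i : i + s].tolist())
                i += s
            res = _jt(groups)

            def brute_jt(vals, sizes=sizes):
                jt, start = 0.0, 0
                parts = []
                for s in sizes:
                    parts.append(vals[start : start + s])
                    start += s
                for gi in range(len(parts)):
                    for gj in range(gi + 1, len(parts)):
                        for x in parts[gi]:
                            for y in parts[gj]:
                                jt += (x < y) + 0.5 * (x == y)
                return jt

            obs = brute_jt(values)
            # all value-permutations are equiprobable under the null
            jts_all = np.array(
                [brute_jt(np.array(p)) for p in itertools.permutations(values)]
            )
            n_ge = (jts_all >= obs - 1e-9).sum()
            n_le = (jts_all <= obs + 1e-9).sum()
            expected_p = min(1.0, 2 * min(n_ge, n_le) / len(jts_all))
            assert res.jt_statistic == pytest.approx(obs)
            assert res.p == pytest.approx(expected_p, abs=1e-9)

    def test_normal_approx_matches_permutation_monte_carlo(self, rng):
        """On samples past the enumeration bound, the tie-corrected normal p is
        close to a large Monte-Carlo permutation estimate."""
        sizes = [40, 40, 40]
        values = np.concatenate([rng.normal(0.12 * i, 1, s) for i, s in enumerate(sizes)])
        labels = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
        res = jonckheere_terpstra(values, labels, [0, 1, 2])
        assert not res.exact
        reps = 20_000
        stat_obs = res.jt_statistic
        more_extreme = 0
        mean = (len(values) ** 2 - sum(s**2 for s in sizes)) / 4
        for _ in range(reps):
            perm = rng.permutation(values)
            groups = [perm[:40], perm[40:80], perm[80:]]
            jt = trend_stats._jt_statistic(groups)
            more_extreme += abs(jt - mean) >= abs(stat_obs - mean) - 1e-9
        p_mc = more_extreme / reps
        assert abs(p_mc - res.p) < 0.02

    def test_single_group_is_error(self):
        with pytest.raises(ValueError, match="two"):
            jonckheere_terpstra(np.arange(5.0), np.zeros(5), [0])

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            jonckheere_terpstra(np.arange(4.0), np.array([0, 0, 1, 1]), [0, 1, 2])


class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_swap_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(0.5, 1, size=6)
        _, p_xy = mann_whitney_u(x, y)
        _, p_yx = mann_whitney_u(y, x)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(30):
            nx, ny = rng.integers(2, 7, size=2)
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            u, p = mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_matches_scipy_asymptotic_large_sample(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(0.3, 1, size=50)
        u, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestTempleton:
    def test_rank_preserved(self, rng):
        v = rng.lognormal(6, 1, size=200)
        out = templeton_normalize(v)
        rho = stats.spearmanr(v, out).statistic
        assert rho == pytest.approx(1.0)

    def test_mean_sd_preserved(self, rng):
        v = rng.lognormal(6, 1, size=500)
        out = templeton_normalize(v)
        assert out.mean() == pytest.approx(v.mean(), abs=1e-9)
        assert out.std(ddof=1) == pytest.approx(v.std(ddof=1), abs=1e-9)

    def test_normalizes_lognormal_input(self):
        passed = 0
        for seed in range(20):
            v = np.random.default_rng(seed).lognormal(6, 1, size=5000)
            w = stats.shapiro(templeton_normalize(v))
            passed += w.pvalue >= 0.01
        assert passed >= 19

    def test_ties_share_transformed_value(self):
        out = templeton_normalize(np.array([1.0, 2.0, 2.0, 3.0]))
        assert out[1] == pytest.approx(out[2])

    def test_constant_input_error(self):
        with pytest.raises(ValueError, match="constant"):
            templeton_normalize(np.full(10, 2.0))


class TestBonferroni:
    def test_three_snps_displays_0017(self):
        t = bonferroni_alpha(0.05, 3)
        assert t.display == 0.017
        assert t.threshold == pytest.approx(0.05 / 3)

    @pytest.mark.parametrize("n,expected", [(1, 0.05), (7, 0.05 / 7)])
    def test_arithmetic(self, n, expected):
        assert bonferroni_alpha(0.05, n).threshold == pytest.approx(expected)

    def test_flagging_uses_unrounded_threshold(self):
        t = bonferroni_alpha(0.05, 3)
        assert t.significant(0.0165)
        assert not t.significant(0.0168)  # below display 0.017 but above 0.05/3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 3)


class TestChisqContingency:
    def test_vehicle_use_men_strongly_differs(self):
        # 81.38% of 145 vs 26.58% of 79 users reconstructed as counts
        table = [[118, 27], [21, 58]]
        chi2, df, p = chisq_contingency(table)
        assert df == 1
        assert p < 0.001

    def test_identical_rows(self):
        chi2, df, p = chisq_contingency([[30, 70], [30, 70]])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        for _ in range(100):
            t = rng.integers(1, 80, size=(2, 3)).astype(float)
            chi2, df, _ = chisq_contingency(t)
            row, col, n = t.sum(1, keepdims=True), t.sum(0, keepdims=True), t.sum()
            expected = row @ col / n
            brute = ((t - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(brute, abs=1e-9)
            assert df == 2

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="marginal"):
            chisq_contingency([[0, 10], [0, 20]])


def test_population_descriptives_structure(cohort):
    desc = trend_stats.population_descriptives(cohort.table)
    assert set(desc["sex"]) == {"men", "women"}
    assert set(desc["population"]) == {"general", "roma"}
    # every continuous variable gets one row per sex per population
    age = desc.query("variable == 'age'")
    assert len(age) == 4
    assert (age["ci95_low"] <= age["estimate"]).all()
    assert (age["estimate"] <= age["ci95_high"]).all()
    # prevalence rows live in [0, 1] with a comparison p-value
    prev = desc.query("variable == 'ltpa_general'")
    assert prev["estimate"].between(0, 1).all()
    assert prev["p"].between(0, 1).all()
    # education compares all three levels in one chi-square per sex
    edu = desc.query("variable == 'education' and sex == 'men'")
    assert len(edu) == 6  # 3 levels x 2 populations
    assert edu["p"].nunique() == 1


def test_shapiro_gate():
    rng = np.random.default_rng(12)
    assert trend_stats.shapiro_normal(rng.normal(size=500))
    assert not trend_stats.shapiro_normal(rng.lognormal(0, 1.5, size=500))
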