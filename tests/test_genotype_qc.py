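"""QC statistics against hand computations, textbook oracles and simulation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ltpa_pgs import cohort_sim, genotype_qc
from ltpa_pgs.genotypes import MISSING, GenotypeMatrix, PanelMetadata, SnpInfo


def _matrix(columns: dict[str, list[int]]) -> GenotypeMatrix:
    panel = PanelMetadata(
        tuple(SnpInfo(s, "1", i + 1, "A", "G") for i, s in enumerate(columns))
    )
    codes = np.column_stack([np.asarray(v, dtype=np.int8) for v in columns.values()])
    ids = [f"s{i}" for i in range(codes.shape[0])]
    return GenotypeMatrix(codes, ids, panel)


class TestAlleleFrequencies:
    def test_direct_count(self):
        g = _matrix({"rs1": [2, 2, 1, 0]})
        out = genotype_qc.allele_frequencies(g, np.zeros(4))
        assert out["effect_allele_freq"].iloc[0] == pytest.approx(5 / 8)

    def test_all_reference(self):
        g = _matrix({"rs1": [0, 0, 0]})
        out = genotype_qc.allele_frequencies(g, np.zeros(3))
        assert out["effect_allele_freq"].iloc[0] == 0.0

    def test_missing_excluded_from_denominator(self):
        g = _matrix({"rs1": [2, MISSING, 1, MISSING]})
        out = genotype_qc.allele_frequencies(g, np.zeros(4))
        assert out["n_called"].iloc[0] == 2
        assert out["effect_allele_freq"].iloc[0] == pytest.approx(3 / 4)

    def test_all_missing_in_group_is_error(self):
        g = _matrix({"rs1": [MISSING, MISSING]})
        with pytest.raises(ValueError, match="missing"):
            genotype_qc.allele_frequencies(g, np.zeros(2))


class TestHwe:
    def test_exact_proportions_give_zero(self):
        chi2, p = genotype_qc.hwe_chisq(25, 50, 25)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_example(self):
        chi2, p = genotype_qc.hwe_chisq(10, 10, 10)
        assert chi2 == pytest.approx(10 / 3, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(10 / 3, 1), abs=1e-9)

    def test_monomorphic_flagged_not_tested(self):
        chi2, p = genotype_qc.hwe_chisq(0, 0, 100)
        assert math.isnan(chi2) and math.isnan(p)

    @given(
        st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
    )
    def test_matches_expected_count_brute_force(self, n2, n1, n0):
        if n2 + n1 + n0 == 0:
            return
        n = n2 + n1 + n0
        p_hat = (2 * n2 + n1) / (2 * n)
        if p_hat in (0.0, 1.0):
            return
        exp = [n * p_hat**2, 2 * n * p_hat * (1 - p_hat), n * (1 - p_hat) ** 2]
        brute = sum((o - e) ** 2 / e for o, e in zip((n2, n1, n0), exp))
        chi2, _ = genotype_qc.hwe_chisq(n2, n1, n0)
        assert chi2 == pytest.approx(brute, abs=1e-9)


class TestCompareFreqs:
    def test_hand_example(self):
        chi2, p = genotype_qc.compare_freqs((60, 40), (40, 60))
        assert chi2 == pytest.approx(8.0, abs=1e-9)
        assert p == pytest.approx(0.004678, abs=1e-5)

    def test_identical_counts(self):
        chi2, p = genotype_qc.compare_freqs((50, 50), (50, 50))
        assert chi2 == 0.0 and p == 1.0

    def test_shared_zero_column_is_degenerate_equality(self):
        chi2, p = genotype_qc.compare_freqs((100, 0), (100, 0))
        assert chi2 == 0.0 and p == 1.0

    def test_zero_group_total_is_error(self):
        with pytest.raises(ValueError, match="zero total"):
            genotype_qc.compare_freqs((0, 0), (10, 10))

    def test_matches_generic_pearson_oracle(self, rng):
        for _ in range(200):
            t = rng.integers(1, 200, size=(2, 2))
            chi2, p = genotype_qc.compare_freqs(tuple(t[0]), tuple(t[1]))
            exp_chi2, exp_p, _, _ = stats.chi2_contingency(t, correction=False)
            assert chi2 == pytest.approx(exp_chi2, abs=1e-9)
            assert p == pytest.approx(exp_p, abs=1e-9)


class TestPower:
    def test_null_equals_alpha(self):
        assert genotype_qc.power_allele_diff(0.3, 0.3, 300, 300, 0.05) == pytest.approx(
            0.05, abs=1e-6
        )

    def test_monotone_in_effect_and_n(self):
        grid = [genotype_qc.power_allele_diff(0.3, 0.3 + d, 300, 300) for d in
                (0.0, 0.05, 0.10, 0.15, 0.20)]
        assert all(a <= b + 1e-12 for a, b in zip(grid, grid[1:]))
        by_n = [genotype_qc.power_allele_diff(0.3, 0.45, n, n) for n in (50, 150, 300, 600)]
        assert all(a <= b + 1e-12 for a, b in zip(by_n, by_n[1:]))

    def test_against_monte_carlo_chi2_rejection(self, rng):
        f_a, f_b, n = 0.30, 0.45, 300
        predicted = genotype_qc.power_allele_diff(f_a, f_b, n, n, 0.05)
        reps = 10_000
        ca = rng.binomial(2 * n, f_a, size=reps)
        cb = rng.binomial(2 * n, f_b, size=reps)
        # vectorised 2x2 Pearson chi-square on allele counts
        m = 2 * n
        tot = ca + cb
        exp_a = tot * 0.5
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = ((ca - exp_a) ** 2 / exp_a + (cb - exp_a) ** 2 / exp_a
                    + ((m - ca) - (2 * m - tot) * 0.5) ** 2 / ((2 * m - tot) * 0.5)
                    + ((m - cb) - (2 * m - tot) * 0.5) ** 2 / ((2 * m - tot) * 0.5))
        reject = (stats.chi2.sf(chi2, 1) < 0.05).mean()
        assert abs(predicted - reject) < 0.02

    def test_alpha_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            genotype_qc.power_allele_diff(0.3, 0.4, 100, 100, alpha=1.5)


class TestLdEm:
    def test_fully_coupled_loci(self, rng):
        codes = rng.binomial(2, 0.5, size=200).astype(np.int8)
        pair = genotype_qc.ld_em(codes, codes)
        assert pair.D_prime == pytest.approx(1.0, abs=1e-6)
        assert pair.r2 == pytest.approx(1.0, abs=1e-6)

    def test_independent_loci(self, rng):
        a = rng.binomial(2, 0.4, size=10_000).astype(np.int8)
        b = rng.binomial(2, 0.3, size=10_000).astype(np.int8)
        pair = genotype_qc.ld_em(a, b)
        assert pair.r2 < 0.01

    def test_double_heterozygote_ambiguity_tie_break(self):
        """Two double-hets alone cannot resolve phase; EM stays at equilibrium."""
        pair = genotype_qc.ld_em(np.array([1, 1], dtype=np.int8), np.array([1, 1], dtype=np.int8))
        assert pair.D == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(pair.haplotype_freqs, 0.25, atol=1e-9)

    def test_monomorphic_locus_flagged(self):
        pair = genotype_qc.ld_em(
            np.zeros(50, dtype=np.int8), np.ones(50, dtype=np.int8)
        )
        assert pair.undefined and math.isnan(pair.r2)

    def test_recovers_truth_from_phased_simulation(self, rng):
        n = 5000
        ga, gb, hap_true = cohort_sim.simulate_phased_genotype_pair(0.4, 0.3, 0.08, n, rng)
        pair = genotype_qc.ld_em(ga, gb)
        for est, truth in zip(pair.haplotype_freqs, hap_true):
            se = math.sqrt(truth * (1 - truth) / (2 * n))
            assert abs(est - truth) < 3 * se

    def test_missing_dropped_pairwise(self, rng):
        a = rng.binomial(2, 0.5, size=500).astype(np.int8)
        b = a.copy()
        a_missing = a.copy()
        a_missing[:50] = MISSING
        pair = genotype_qc.ld_em(a_missing, b)
        assert pair.r2 == pytest.approx(1.0, abs=1e-6)


class TestPanelQc:
    def test_hwe_violating_snp_excluded(self, rng):
        het_deficit = np.tile(np.repeat([2, 0], 60), 2).astype(np.int8)  # no hets, f=0.5
        balanced = rng.binomial(2, 0.5, size=240).astype(np.int8)
        g = _matrix({"rs_bad": het_deficit, "rs_ok": balanced})
        group = np.repeat([0, 1], 120)
        results = genotype_qc.qc_panel(g, group)
        by_id = {r.snp_id: r for r in results}
        assert by_id["rs_bad"].excluded and by_id["rs_bad"].reason == "hwe_deviation"
        assert not by_id["rs_ok"].excluded

    def test_report_frame_has_one_row_per_snp(self, rng):
        g = _matrix({f"rs{i}": rng.binomial(2, 0.4, 100) for i in range(3)})
        frame = genotype_qc.qc_report_frame(
            genotype_qc.qc_panel(g, np.repeat([0, 1], 50))
        )
        assert list(frame["snp_id"]) == ["rs0", "rs1", "rs2"]
        assert {"freq_diff_p", "power", "excluded"} <= set(frame.columns)
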