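"""Panel-level genotype QC and between-population comparison.

Covers per-group effect-allele frequencies, the 1-df Pearson chi-square test
of Hardy-Weinberg equilibrium with exclusion flagging, pairwise linkage
disequilibrium via an EM fit of two-locus haplotype frequencies on unphased
genotypes, a 2x2 allele-count chi-square comparing frequencies between
populations, and a normal-approximation power calculation for that comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class SnpQcResult:
    snp_id: str
    effect_allele_freq: dict[str, float]
    hwe_chi2: dict[str, float]
    hwe_p: dict[str, float]
    monomorphic: dict[str, bool]
    freq_diff_chi2: float
    freq_diff_p: float
    power: float
    excluded: bool
    reason: str


@dataclass
class LdPair:
    snp_a: str
    snp_b: str
    haplotype_freqs: np.ndarray  # (p_AB, p_Ab, p_aB, p_ab)
    D: float
    D_prime: float
    r2: float
    em_iterations: int
    undefined: bool = False


def allele_frequencies(genotypes: GenotypeMatrix, group_labels: np.ndarray) -> pd.DataFrame:
    """Per-SNP, per-group effect-allele frequency over non-missing genotypes.

    freq = (sum of codes over non-missing individuals) / (2 * non-missing n).
    Raises if a SNP is entirely missing within a group.
    """
    group_labels = np.asarray(group_labels)
    rows = []
    for group in pd.unique(group_labels):
        mask = group_labels == group
        codes = genotypes.codes[mask]
        for j, snp_id in enumerate(genotypes.snp_ids):
            col = codes[:, j]
            ok = col != MISSING
            n_called = int(ok.sum())
            if n_called == 0:
                raise ValueError(f"{snp_id}: all genotypes missing in group {group!r}")
            rows.append(
                {
                    "group": group,
                    "snp_id": snp_id,
                    "n_called": n_called,
                    "effect_allele_freq": float(col[ok].sum()) / (2 * n_called),
                }
            )
    return pd.DataFrame(rows)


def genotype_counts(codes: np.ndarray) -> tuple[int, int, int]:
    """(n homozygous effect, n heterozygous, n homozygous other), missing dropped."""
    codes = np.asarray(codes)
    ok = codes != MISSING
    return int((codes[ok] == 2).sum()), int((codes[ok] == 1).sum()), int((codes[ok] == 0).sum())


def hwe_chisq(n_hom_effect: int, n_het: int, n_hom_other: int) -> tuple[float, float]:
    """1-df Pearson chi-square test of Hardy-Weinberg proportions.

    Expected counts are n*(p^2, 2pq, q^2) with p estimated from the observed
    allele counts. Returns (chi2, p). A monomorphic SNP has an expected count
    of zero and no testable departure; (nan, nan) is returned so callers can
    flag it without excluding on HWE grounds.
    """
    if min(n_hom_effect, n_het, n_hom_other) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_effect + n_het + n_hom_other
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    p = (2 * n_hom_effect + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return float("nan"), float("nan")
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_effect, n_het, n_hom_other], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def compare_freqs(
    counts_pop_a: tuple[int, int], counts_pop_b: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 allele table.

    Each argument is (effect-allele count, other-allele count) for one group,
    i.e. 2n alleles per group of n genotyped individuals. A zero allele column
    shared by both groups is a degenerate no-difference table: (0.0, 1.0).
    """
    table = np.array([counts_pop_a, counts_pop_b], dtype=float)
    if (table < 0).any():
        raise ValueError("allele counts must be non-negative")
    if table.sum(axis=1).min() == 0:
        raise ValueError("a group has zero total alleles")
    col_totals = table.sum(axis=0)
    if (col_totals == 0).any():
        # one allele absent everywhere: frequencies are identical by construction
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def power_allele_diff(
    freq_a: float, freq_b: float, n_a_individuals: int, n_b_individuals: int, alpha: float = 0.05
) -> float:
    """Power of the two-sided allele-frequency comparison at significance alpha.

    Normal approximation for the difference of two proportions with unpooled
    variance, on allele counts (2n alleles per group of n individuals).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if min(n_a_individuals, n_b_individuals) < 1:
        raise ValueError("group sizes must be >= 1")
    for f in (freq_a, freq_b):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must be in [0, 1]")
    m_a, m_b = 2 * n_a_individuals, 2 * n_b_individuals
    se = np.sqrt(freq_a * (1 - freq_a) / m_a + freq_b * (1 - freq_b) / m_b)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    if se == 0.0:
        return 1.0 if freq_a != freq_b else alpha
    delta = abs(freq_a - freq_b) / se
    return float(stats.norm.cdf(delta - z_crit) + stats.norm.cdf(-delta - z_crit))


def _genotype_pair_counts(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """3x3 joint genotype table (rows: locus A codes 2/1/0, cols: locus B)."""
    ok = (codes_a != MISSING) & (codes_b != MISSING)
    a, b = codes_a[ok], codes_b[ok]
    table = np.zeros((3, 3), dtype=float)
    for i, ga in enumerate((2, 1, 0)):
        for j, gb in enumerate((2, 1, 0)):
            table[i, j] = np.sum((a == ga) & (b == gb))
    return table


def ld_em(
    codes_a: np.ndarray,
    codes_b: np.ndarray,
    snp_a: str = "a",
    snp_b: str = "b",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LdPair:
    """Two-locus LD from unphased genotypes via EM haplotype-frequency estimation.

    Individuals missing at either locus are dropped pairwise. Haplotypes are
    (AB, Ab, aB, ab) with A/B the effect alleles. Only the double heterozygote
    is phase-ambiguous; the E-step splits it between AB/ab and Ab/aB in
    proportion to the current haplotype frequencies. EM starts from the
    linkage-equilibrium product frequencies, so a fully ambiguous degenerate
    sample stays at the equilibrium solution (the documented tie-break).

    D = p_AB - p_A p_B; D' = |D| / D_max; r^2 = D^2 / (p_A q_A p_B q_B).
    A monomorphic locus leaves LD undefined (flagged, nan measures).
    """
    counts = _genotype_pair_counts(np.asarray(codes_a), np.asarray(codes_b))
    n = counts.sum()
    if n == 0:
        raise ValueError("no individuals genotyped at both loci")
    # allele frequencies at each locus (rows/cols ordered 2, 1, 0)
    p_a = (2 * counts[0].sum() + counts[1].sum()) / (2 * n)
    p_b = (2 * counts[:, 0].sum() + counts[:, 1].sum()) / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LdPair(
            snp_a, snp_b, np.full(4, np.nan), np.nan, np.nan, np.nan, 0, undefined=True
        )

    hap = np.array(
        [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)], dtype=float
    )
    n_dh = counts[1, 1]  # double heterozygotes: the only phase-ambiguous class
    # phase-known haplotype pairs per genotype class (indices into AB, Ab, aB, ab)
    resolved = {
        (2, 2): (0, 0), (2, 1): (0, 1), (2, 0): (1, 1),
        (1, 2): (0, 2), (1, 0): (1, 3),
        (0, 2): (2, 2), (0, 1): (2, 3), (0, 0): (3, 3),
    }
    base = np.zeros(4)
    for i, ga in enumerate((2, 1, 0)):
        for j, gb in enumerate((2, 1, 0)):
            if (ga, gb) == (1, 1):
                continue
            c = counts[i, j]
            h1, h2 = resolved[(ga, gb)]
            base[h1] += c
            base[h2] += c
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split double heterozygotes between the two phase resolutions
        cis = hap[0] * hap[3]  # AB/ab
        trans = hap[1] * hap[2]  # Ab/aB
        w = 0.5 if cis + trans == 0 else cis / (cis + trans)
        counts_h = base.copy()
        counts_h += n_dh * np.array([w, 1 - w, 1 - w, w])
        new_hap = counts_h / (2 * n)
        if np.max(np.abs(new_hap - hap)) < tol:
            hap = new_hap
            break
        hap = new_hap
    p_A, p_B = hap[0] + hap[1], hap[0] + hap[2]
    D = hap[0] - p_A * p_B
    if D >= 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    d_prime = abs(D) / d_max if d_max > 0 else np.nan
    denom = p_A * (1 - p_A) * p_B * (1 - p_B)
    r2 = D * D / denom if denom > 0 else np.nan
    return LdPair(snp_a, snp_b, hap, float(D), float(d_prime), float(r2), it)


def qc_panel(
    genotypes: GenotypeMatrix,
    group_labels: np.ndarray,
    hwe_alpha: float = 0.05,
    power_alpha: float = 0.05,
) -> list[SnpQcResult]:
    """Full per-SNP QC over exactly two groups.

    A SNP is excluded iff its HWE p-value falls below ``hwe_alpha`` in either
    group; monomorphic SNPs are flagged but never excluded on HWE grounds.
    """
    group_labels = np.asarray(group_labels)
    groups = list(pd.unique(group_labels))
    if len(groups) != 2:
        raise ValueError("qc_panel expects exactly two groups")
    freq = allele_frequencies(genotypes, group_labels)
    results = []
    for snp_id in genotypes.snp_ids:
        col = genotypes.column(snp_id)
        freqs, chi2s, ps, mono = {}, {}, {}, {}
        counts_by_group = {}
        for g in groups:
            codes = col[group_labels == g]
            n2, n1, n0 = genotype_counts(codes)
            chi2, p = hwe_chisq(n2, n1, n0)
            f = freq.query("group == @g and snp_id == @snp_id")["effect_allele_freq"].iloc[0]
            freqs[g], chi2s[g], ps[g] = float(f), chi2, p
            mono[g] = bool(np.isnan(chi2))
            counts_by_group[g] = (2 * n2 + n1, 2 * n0 + n1)
        excluded = any(
            (not mono[g]) and ps[g] < hwe_alpha for g in groups
        )
        reason = "hwe_deviation" if excluded else ""
        fd_chi2, fd_p = compare_freqs(counts_by_group[groups[0]], counts_by_group[groups[1]])
        n_a = sum(counts_by_group[groups[0]]) // 2
        n_b = sum(counts_by_group[groups[1]]) // 2
        power = power_allele_diff(freqs[groups[0]], freqs[groups[1]], n_a, n_b, power_alpha)
        results.append(
            SnpQcResult(
                snp_id, freqs, chi2s, ps, mono, fd_chi2, fd_p, power, excluded, reason
            )
        )
    return results


def qc_report_frame(results: list[SnpQcResult]) -> pd.DataFrame:
    """Flatten QC results to the report table (one row per SNP)."""
    rows = []
    for r in results:
        row = {"snp_id": r.snp_id}
        for g in r.effect_allele_freq:
            row[f"freq_{g}"] = r.effect_allele_freq[g]
            row[f"hwe_chi2_{g}"] = r.hwe_chi2[g]
            row[f"hwe_p_{g}"] = r.hwe_p[g]
            row[f"monomorphic_{g}"] = r.monomorphic[g]
        row.update(
            freq_diff_chi2=r.freq_diff_chi2,
            freq_diff_p=r.freq_diff_p,
            power=r.power,
            excluded=r.excluded,
            reason=r.reason,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def ld_matrix(genotypes: GenotypeMatrix, r2_linkage_threshold: float = 0.8) -> pd.DataFrame:
    """All pairwise LD estimates; ``linked`` flags r^2 at or above the threshold."""
    ids = genotypes.snp_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pair = ld_em(genotypes.column(ids[i]), genotypes.column(ids[j]), ids[i], ids[j])
            rows.append(
                {
                    "snp_a": pair.snp_a,
                    "snp_b": pair.snp_b,
                    "D": pair.D,
                    "D_prime": pair.D_prime,
                    "r2": pair.r2,
                    "em_iterations": pair.em_iterations,
                    "undefined": pair.undefined,
                    "linked": (not pair.undefined) and pair.r2 >= r2_linkage_threshold,
                }
            )
    return pd.DataFrame(rows)
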