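"""Rank-based trend and comparison statistics for score-category analyses.

Implements the Jonckheere-Terpstra test for a monotone trend of a quantitative
outcome across ordered score categories (tie-corrected normal approximation,
with exact permutation enumeration on small samples), the Mann-Whitney U test,
Templeton's two-step rank-to-normal transform, the Bonferroni threshold used
for score analyses, and a thin Pearson chi-square wrapper for contingency
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

# exact-permutation guards: enumerate only when the sample is small enough
EXACT_MAX_N = 20
EXACT_MAX_ARRANGEMENTS = 250_000


@dataclass
class TrendResult:
    outcome_id: str
    group_labels: list
    group_n: list[int]
    group_means: list[float]
    group_ci_low: list[float]
    group_ci_high: list[float]
    jt_statistic: float
    z: float
    p: float
    exact: bool
    significant_after_correction: bool | None = None
    transformed: bool = False


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """Sum over ordered group pairs of Mann-Whitney counts, ties half-weighted."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            x, y = groups[i][:, None], groups[j][None, :]
            jt += float((x < y).sum()) + 0.5 * float((x == y).sum())
    return jt


def _jt_moments(group_sizes: np.ndarray, pooled: np.ndarray) -> tuple[float, float]:
    """Null mean and tie-corrected variance of the JT statistic."""
    n = group_sizes.sum()
    mean = (n * n - (group_sizes**2).sum()) / 4.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    g = group_sizes.astype(float)
    a = n * (n - 1) * (2 * n + 5) - (g * (g - 1) * (2 * g + 5)).sum() - (
        t * (t - 1) * (2 * t + 5)
    ).sum()
    var = a / 72.0
    if n > 2:
        var += ((g * (g - 1) * (g - 2)).sum() * (t * (t - 1) * (t - 2)).sum()) / (
            36.0 * n * (n - 1) * (n - 2)
        )
    var += ((g * (g - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * n * (n - 1))
    return float(mean), float(var)


def _n_arrangements(sizes: list[int]) -> int:
    total = sum(sizes)
    count = 1
    for s in sizes:
        count *= math.comb(total, s)
        total -= s
    return count


def _iter_group_assignments(indices: tuple[int, ...], sizes: list[int]):
    """Yield all distinct splits of ``indices`` into consecutive groups of ``sizes``."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for first in combinations(indices, sizes[0]):
        first_set = set(first)
        rest = tuple(i for i in indices if i not in first_set)
        for tail in _iter_group_assignments(rest, sizes[1:]):
            yield (first,) + tail


def _exact_jt_pvalues(groups: list[np.ndarray], observed: float) -> tuple[float, float]:
    """(one-sided upper, two-sided) exact permutation p-values of JT."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n_ge = 0
    n_le = 0
    total = 0
    idx = tuple(range(pooled.size))
    eps = 1e-12
    for assignment in _iter_group_assignments(idx, sizes):
        perm_groups = [pooled[list(ix)] for ix in assignment]
        jt = _jt_statistic(perm_groups)
        total += 1
        if jt >= observed - eps:
            n_ge += 1
        if jt <= observed + eps:
            n_le += 1
    p_upper = n_ge / total
    p_two = min(1.0, 2.0 * min(n_ge, n_le) / total)
    return p_upper, p_two


def jonckheere_terpstra(
    values: np.ndarray, group_labels: np.ndarray, ordered_groups: list, outcome_id: str = ""
) -> TrendResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    ``ordered_groups`` declares the group order (ascending alternative). The
    p-value is two-sided: exact by permutation enumeration when the pooled
    sample is small (n <= 20 and a bounded arrangement count), otherwise from
    the tie-corrected normal approximation.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if len(ordered_groups) < 2:
        raise ValueError("need at least two ordered groups")
    groups = []
    for g in ordered_groups:
        sel = values[group_labels == g]
        if sel.size == 0:
            raise ValueError(f"empty group {g!r}")
        groups.append(sel)
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    jt = _jt_statistic(groups)
    mean, var = _jt_moments(sizes, pooled)
    if var <= 0:  # all pooled values tied: no ordering information
        z = 0.0
        p = 1.0
        exact = False
    elif pooled.size <= EXACT_MAX_N and _n_arrangements(list(sizes)) <= EXACT_MAX_ARRANGEMENTS:
        _, p = _exact_jt_pvalues(groups, jt)
        z = (jt - mean) / math.sqrt(var)
        exact = True
    else:
        z = (jt - mean) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        exact = False
    means = [float(g.mean()) for g in groups]
    ci_low, ci_high = [], []
    for g in groups:
        se = float(g.std(ddof=1) / math.sqrt(g.size)) if g.size > 1 else 0.0
        means_g = float(g.mean())
        ci_low.append(means_g - 1.959963984540054 * se)
        ci_high.append(means_g + 1.959963984540054 * se)
    return TrendResult(
        outcome_id=outcome_id,
        group_labels=list(ordered_groups),
        group_n=[int(s) for s in sizes],
        group_means=means,
        group_ci_low=ci_low,
        group_ci_high=ci_high,
        jt_statistic=jt,
        z=float(z),
        p=float(p),
        exact=exact,
    )


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (count of x > y pairs, ties half-weighted), two-sided p.

    Exact enumeration over all C(n, n_x) group assignments when n_x + n_y <= 20,
    else the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = float((x[:, None] > y[None, :]).sum()) + 0.5 * float((x[:, None] == y[None, :]).sum())
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if n1 + n2 <= EXACT_MAX_N:
        eps = 1e-12
        n_ge = n_le = total = 0
        idx = tuple(range(n1 + n2))
        for first in combinations(idx, n1):
            first_set = set(first)
            xs = pooled[list(first)]
            ys = pooled[[i for i in idx if i not in first_set]]
            u_perm = float((xs[:, None] > ys[None, :]).sum()) + 0.5 * float(
                (xs[:, None] == ys[None, :]).sum()
            )
            total += 1
            if u_perm >= u - eps:
                n_ge += 1
            if u_perm <= u + eps:
                n_le += 1
        return u, min(1.0, 2.0 * min(n_ge, n_le) / total)
    mean = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    tie_term = ((t**3 - t).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (u - mean) / math.sqrt(var)
    return u, float(2.0 * stats.norm.sf(abs(z)))


def templeton_normalize(values: np.ndarray) -> np.ndarray:
    """Two-step rank-based transformation toward normality.

    Step 1: fractional ranks (ties share mid-ranks) mapped to open-interval
    percentiles rank/(n+1). Step 2: inverse standard-normal of the percentiles,
    linearly rescaled so the output keeps the input's mean and (ddof=1) SD.
    Strictly rank-preserving; constant input is an error.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(v) == 0.0:
        raise ValueError("constant input cannot be normalized")
    ranks = stats.rankdata(v, method="average")
    z = stats.norm.ppf(ranks / (v.size + 1))
    out = v.mean() + v.std(ddof=1) * (z - z.mean()) / z.std(ddof=1)
    return out


def shapiro_normal(values: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk gate: True when normality is *not* rejected at ``alpha``."""
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0.0:
        return False
    return bool(stats.shapiro(v).pvalue >= alpha)


@dataclass(frozen=True)
class BonferroniThreshold:
    threshold: float  # unrounded, used for flagging
    display: float  # rounded to 3 decimals for reporting

    def significant(self, p: float) -> bool:
        return p < self.threshold


def bonferroni_alpha(alpha: float, n_polymorphisms: int) -> BonferroniThreshold:
    """Corrected significance threshold alpha / n (n = SNPs retained in the score)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_polymorphisms < 1:
        raise ValueError("need at least one polymorphism")
    t = alpha / n_polymorphisms
    return BonferroniThreshold(t, round(t, 3))


def population_descriptives(table, outcomes=("general", "vigorous", "moderate", "walking")):
    """Descriptive comparison of the two populations, split by sex.

    Continuous variables (age, waist, BMI, MET-min/week) are summarised as mean
    with a normal-approximation 95% CI and compared by Mann-Whitney U;
    categorical variables (education, vehicle use, LTPA participation) as
    prevalence with a Wilson 95% CI and compared by Pearson chi-square.
    Returns a tidy table: one row per sex x variable x level x population.
    """
    import pandas as pd
    from statsmodels.stats.proportion import proportion_confint

    pops = list(pd.unique(table["population"]))
    if len(pops) != 2:
        raise ValueError("descriptives expect exactly two populations")
    rows = []
    for sex, sex_label in ((1, "men"), (0, "women")):
        sub = table[table["sex"] == sex]
        split = {p: sub[sub["population"] == p] for p in pops}

        continuous = [("age", "age"), ("waist", "waist"), ("bmi", "bmi")] + [
            (f"met_{o}", f"met_{o}") for o in outcomes
        ]
        for col, name in continuous:
            x, y = split[pops[0]][col].to_numpy(float), split[pops[1]][col].to_numpy(float)
            _, p = mann_whitney_u(x, y)
            for pop, v in ((pops[0], x), (pops[1], y)):
                se = v.std(ddof=1) / math.sqrt(v.size) if v.size > 1 else 0.0
                rows.append(
                    {
                        "sex": sex_label,
                        "variable": name,
                        "level": "",
                        "population": pop,
                        "n": v.size,
                        "estimate": v.mean(),
                        "ci95_low": v.mean() - 1.959963984540054 * se,
                        "ci95_high": v.mean() + 1.959963984540054 * se,
                        "p": p,
                    }
                )

        categorical = [("vehicle", [1])] + [(f"ltpa_{o}", [1]) for o in outcomes] + [
            ("education", [0, 1, 2])
        ]
        for col, levels in categorical:
            counts = np.array(
                [[int((split[p][col] == lv).sum()) for lv in levels]
                 + ([int((~split[p][col].isin(levels)).sum())] if len(levels) == 1 else [])
                 for p in pops]
            )
            try:
                _, _, p = chisq_contingency(counts)
            except ValueError:
                p = float("nan")
            for pop in pops:
                denom = len(split[pop])
                for lv in levels:
                    k = int((split[pop][col] == lv).sum())
                    lo, hi = proportion_confint(k, denom, method="wilson")
                    rows.append(
                        {
                            "sex": sex_label,
                            "variable": col,
                            "level": str(lv),
                            "population": pop,
                            "n": denom,
                            "estimate": k / denom,
                            "ci95_low": lo,
                            "ci95_high": hi,
                            "p": p,
                        }
                    )
    return pd.DataFrame(rows)


def chisq_contingency(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any() or table.sum() <= 0:
        raise ValueError("table must be non-negative with a positive total")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column marginal")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
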