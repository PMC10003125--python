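"""Unweighted count polygenic score, forward optimization, and categorization.

The score for an individual is the plain sum of effect-allele counts over a
SNP set (GRS = sum_i G_i), treating every allele as having the same direction
and size of effect. The optimization procedure ranks candidate SNPs by their
adjusted single-SNP association p-value and adds them to the score one at a
time, keeping a SNP only if it strictly decreases the score's association
p-value and strictly increases the Cox-Snell R-squared against the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .association import ADJUSTMENT_COVARIATES, AssociationResult, predictor_association
from .genotypes import MISSING, GenotypeMatrix


@dataclass
class TrajectoryStep:
    snp_id: str
    p_before: float
    p_after: float
    r2_before: float
    r2_after: float
    accepted: bool


@dataclass
class PGSModel:
    candidate_order: list[str]
    accepted: list[str]
    trajectory: list[TrajectoryStep]
    n_candidates: int  # panel size I, the upper index of the count-score sum
    final_association: AssociationResult | None = None


@dataclass
class ScoreVector:
    scores: np.ndarray  # per-individual integer score
    snp_set: tuple[str, ...]


def count_score(genotypes: GenotypeMatrix, snp_set: list[str]) -> ScoreVector:
    """Per-individual sum of effect-allele counts over ``snp_set``.

    Individuals with any missing genotype among the set must already have been
    excluded; encountering one here is an error (the exclusion rule lives
    upstream, before any score is computed).
    """
    if len(snp_set) == 0:
        raise ValueError("empty SNP set: a count score needs at least one SNP")
    sub = genotypes.subset_snps(list(snp_set))
    if (sub.codes == MISSING).any():
        raise ValueError(
            "missing genotypes encountered; individuals with any missing SNP "
            "must be excluded before scoring"
        )
    return ScoreVector(sub.codes.sum(axis=1).astype(np.int64), tuple(snp_set))


def rank_candidates(results: list[AssociationResult]) -> list[str]:
    """Ascending p-value; ties broken by larger |log OR|, then lexical id."""
    return [
        r.predictor_id
        for r in sorted(results, key=lambda r: (r.p_wald, -abs(np.log(r.odds_ratio)), r.predictor_id))
    ]


def optimize_pgs(
    genotypes: GenotypeMatrix,
    outcome: np.ndarray,
    covariates: np.ndarray,
    candidate_assoc: list[AssociationResult],
    covariate_names: tuple[str, ...] = ADJUSTMENT_COVARIATES,
) -> PGSModel:
    """Forward selection of score SNPs on the combined sample.

    Candidates are visited in ascending adjusted p-value order. The top-ranked
    SNP seeds the score unconditionally; each subsequent SNP is added to a
    trial score and retained only if the adjusted logistic fit of the outcome
    on the trial score shows a strictly smaller p-value AND a strictly larger
    Cox-Snell R-squared than the best score so far. Equality on either
    criterion rejects the SNP.
    """
    if len(candidate_assoc) == 0:
        raise ValueError("empty candidate list")
    order = rank_candidates(candidate_assoc)
    y = np.asarray(outcome, dtype=float)

    def score_fit(snp_set: list[str]) -> AssociationResult:
        vec = count_score(genotypes, snp_set)
        return predictor_association(
            vec.scores.astype(float),
            y,
            covariates,
            covariate_names,
            predictor_id="oPGS",
            outcome_id="general",
        )

    accepted = [order[0]]
    try:
        current = score_fit(accepted)
    except Exception as exc:
        raise RuntimeError(f"score fit failed at seed SNP {order[0]}: {exc}") from exc
    trajectory = [
        TrajectoryStep(order[0], np.nan, current.p_wald, np.nan, current.cox_snell_r2, True)
    ]
    for snp_id in order[1:]:
        trial_set = accepted + [snp_id]
        try:
            trial = score_fit(trial_set)
        except Exception as exc:
            raise RuntimeError(f"score fit failed when adding {snp_id}: {exc}") from exc
        improves = (trial.p_wald < current.p_wald) and (
            trial.cox_snell_r2 > current.cox_snell_r2
        )
        trajectory.append(
            TrajectoryStep(
                snp_id,
                current.p_wald,
                trial.p_wald,
                current.cox_snell_r2,
                trial.cox_snell_r2,
                improves,
            )
        )
        if improves:
            accepted = trial_set
            current = trial
    return PGSModel(order, accepted, trajectory, len(order), current)


def categorize_scores(
    scores: np.ndarray, n_groups: int = 4, min_group_frac: float = 0.10
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Bin integer scores into ordered genetic-predisposition categories.

    Starts from one bin per distinct integer value and repeatedly merges a bin
    at one extreme into its neighbour — choosing the end whose outermost bin is
    smaller (ties merge the low end first) — until there are at most
    ``n_groups`` bins and every bin holds at least ``min_group_frac`` of
    individuals. Returns (per-individual category index, list of inclusive
    (low, high) score bounds per category).
    """
    s = np.asarray(scores)
    if s.size < n_groups:
        raise ValueError("fewer individuals than requested groups")
    values, counts = np.unique(s, return_counts=True)
    if len(values) == 1:
        raise ValueError("constant scores: categories require score variation")
    if len(values) < n_groups:
        warnings.warn(
            f"only {len(values)} distinct score values; forming {len(values)} groups",
            stacklevel=2,
        )
        n_groups = len(values)
    bins = [[int(v)] for v in values]
    bin_counts = list(counts.astype(int))
    min_count = min_group_frac * s.size

    def merge(end: str) -> None:
        if end == "low":
            bins[1] = bins[0] + bins[1]
            bin_counts[1] += bin_counts[0]
            del bins[0], bin_counts[0]
        else:
            bins[-2] = bins[-2] + bins[-1]
            bin_counts[-2] += bin_counts[-1]
            del bins[-1], bin_counts[-1]

    while len(bins) > n_groups or min(bin_counts) < min_count:
        if len(bins) == 1:
            break
        low_small = bin_counts[0] < min_count
        high_small = bin_counts[-1] < min_count
        if low_small and not high_small:
            merge("low")
        elif high_small and not low_small:
            merge("high")
        elif bin_counts[-1] < bin_counts[0]:
            merge("high")
        else:
            merge("low")
    bounds = [(b[0], b[-1]) for b in bins]
    edges = [b[-1] for b in bins]
    labels = np.searchsorted(edges, s)
    return labels, bounds
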