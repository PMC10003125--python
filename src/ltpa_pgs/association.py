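"""Logistic association of genotypes and genetic scores with binary LTPA outcomes.

Per-predictor odds ratios with Wald 95% confidence intervals and p-values,
optionally adjusted for the fixed seven-covariate set (age, sex, ethnicity,
education, vehicle use, BMI, waist circumference), plus the Cox-Snell
pseudo-R-squared used by the score-optimization procedure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

ADJUSTMENT_COVARIATES: tuple[str, ...] = (
    "age",
    "sex",
    "ethnicity",
    "education",
    "vehicle",
    "bmi",
    "waist",
)


class SeparationError(RuntimeError):
    """Raised when a logistic fit is degenerate through (quasi-)complete separation."""


@dataclass
class AssociationResult:
    predictor_id: str
    outcome_id: str
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_wald: float
    loglik_full: float
    loglik_null: float
    cox_snell_r2: float
    n_used: int
    adjusted: bool
    covariate_set: tuple[str, ...]
    coef: float
    se: float


def fit_logistic(
    outcome: np.ndarray, design: np.ndarray, names: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Maximum-likelihood logistic fit.

    ``design`` must already contain the intercept column. Returns
    (coefficients, covariance, log-likelihood) where the covariance is the
    inverse observed information. Complete or quasi-complete separation and
    rank-deficient designs raise explicit errors naming the offending
    predictor where identifiable.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    n, k = X.shape
    if n <= k:
        raise ValueError("more parameters than observations")
    if y.min() == y.max():
        raise SeparationError("outcome is constant; model is degenerate")
    for j in range(1, k):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"constant non-intercept column: {names[j]}")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        warnings.simplefilter("error", RuntimeWarning)
        try:
            fit = sm.Logit(y, X).fit(method="newton", tol=1e-10, maxiter=100, disp=False)
        except (PerfectSeparationError, ConvergenceWarning, RuntimeWarning,
                np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"logistic fit failed (likely separation) for predictors {names[1:]}: {exc}"
            ) from exc
    mu = fit.predict()
    # explicit gradient check of the score equations at the returned optimum
    grad = X.T @ (y - mu)
    if np.linalg.norm(grad) > 1e-6 * max(1.0, n / 100):
        raise SeparationError(f"score equations not solved for predictors {names[1:]}")
    if np.isclose(mu, 0.0, atol=1e-10).any() or np.isclose(mu, 1.0, atol=1e-10).any():
        raise SeparationError(f"fitted probabilities at the boundary for {names[1:]}")
    return np.asarray(fit.params), np.asarray(fit.cov_params()), float(fit.llf)


def cox_snell_r2(loglik_null: float, loglik_full: float, n: int) -> float:
    """Cox-Snell pseudo R-squared: 1 - exp(2 (LL0 - LL1) / n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_full < loglik_null - 1e-9:
        raise ValueError("full model log-likelihood below null; models are not nested")
    return 1.0 - math.exp(2.0 * (loglik_null - loglik_full) / n)


def _null_loglik(y: np.ndarray) -> float:
    """Intercept-only Bernoulli log-likelihood in closed form."""
    n = y.size
    s = y.sum()
    if s == 0 or s == n:
        return 0.0
    p = s / n
    return float(s * math.log(p) + (n - s) * math.log(1 - p))


def predictor_association(
    predictor: np.ndarray,
    outcome: np.ndarray,
    covariates: "np.ndarray | None" = None,
    covariate_names: tuple[str, ...] = (),
    predictor_id: str = "predictor",
    outcome_id: str = "outcome",
) -> AssociationResult:
    """Association of one predictor (genotype dosage or score) with a binary outcome.

    OR per unit of the predictor with Wald 95% CI and p-value. The Cox-Snell
    R-squared compares the fitted model against the intercept-only null (the
    convention of mainstream statistical packages).
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError(f"{predictor_id}: predictor is constant (monomorphic)")
    cols = [np.ones_like(x), x]
    names = ["const", predictor_id]
    adjusted = covariates is not None and len(covariate_names) > 0
    if adjusted:
        cov = np.asarray(covariates, dtype=float)
        if cov.shape[0] != x.size or cov.shape[1] != len(covariate_names):
            raise ValueError("covariate matrix shape does not match names/outcome")
        cols.append(cov)
        names.extend(covariate_names)
        X = np.column_stack(cols[:2] + [cov])
    else:
        X = np.column_stack(cols)
    params, covm, llf = fit_logistic(y, X, names)
    beta, se = float(params[1]), float(math.sqrt(covm[1, 1]))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    ll0 = _null_loglik(y)
    return AssociationResult(
        predictor_id=predictor_id,
        outcome_id=outcome_id,
        odds_ratio=math.exp(beta),
        ci95_low=math.exp(beta - 1.959963984540054 * se),
        ci95_high=math.exp(beta + 1.959963984540054 * se),
        p_wald=float(p),
        loglik_full=llf,
        loglik_null=ll0,
        cox_snell_r2=cox_snell_r2(ll0, llf, y.size),
        n_used=int(y.size),
        adjusted=adjusted,
        covariate_set=tuple(covariate_names) if adjusted else (),
        coef=beta,
        se=se,
    )


def snp_association(
    genotype_column: np.ndarray,
    outcome: np.ndarray,
    covariates: "np.ndarray | None",
    adjusted: bool,
    snp_id: str = "snp",
    outcome_id: str = "outcome",
    covariate_names: tuple[str, ...] = ADJUSTMENT_COVARIATES,
) -> AssociationResult:
    """Additive (per effect-allele) single-SNP logistic association.

    Genotypes must be complete 0/1/2 dosages; individuals with missing
    genotypes are excluded before this point. When ``adjusted``, the covariate
    set is exactly the configured seven-variable set.
    """
    g = np.asarray(genotype_column, dtype=float)
    if np.isin(g, (0.0, 1.0, 2.0)).sum() != g.size:
        raise ValueError(f"{snp_id}: genotype dosages must be in {{0,1,2}} with no missing")
    if adjusted:
        if covariates is None:
            raise ValueError("adjusted association requires a covariate matrix")
        return predictor_association(
            g, outcome, covariates, covariate_names, predictor_id=snp_id, outcome_id=outcome_id
        )
    return predictor_association(g, outcome, predictor_id=snp_id, outcome_id=outcome_id)
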