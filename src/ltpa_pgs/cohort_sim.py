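"""Two-population synthetic cohort generator.

Emulates the statistical structure of a cross-sectional genotype/phenotype
survey of two adult populations (ages 20-64): a small candidate-SNP panel with
population-specific effect-allele frequencies in Hardy-Weinberg equilibrium
within each population, demographic/anthropometric covariates, binary
leisure-time physical activity (LTPA) outcomes driven by a logistic model with
small per-allele effects, and zero-inflated MET-min/week activity volumes.

Randomness policy: one master seed; every stage draws from a child stream
derived with :class:`numpy.random.SeedSequence` using a fixed
``(stage, population)`` spawn key, so each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, PanelMetadata, SnpInfo

OUTCOMES: tuple[str, ...] = ("general", "vigorous", "moderate", "walking")
COVARIATES: tuple[str, ...] = ("age", "sex", "education", "vehicle", "bmi", "waist", "ethnicity")

# truncation bounds for covariate draws (adult survey population, 20-64 years)
AGE_BOUNDS = (20.0, 64.0)
BMI_BOUNDS = (15.0, 60.0)
WAIST_BOUNDS = (50.0, 200.0)

# spawn-key stage identifiers (fixed; part of the reproducibility contract)
_STAGE_GENOTYPES = 0
_STAGE_COVARIATES = 1
_STAGE_PHENOTYPES = 2


def _child_rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage, index)))


@dataclass(frozen=True)
class SnpSpec:
    """One panel SNP with per-population effect-allele frequencies.

    ``inbreeding`` is a per-population fixation-style coefficient F; the default
    0 produces Hardy-Weinberg genotype proportions, F > 0 inflates homozygosity
    (used to exercise the HWE-exclusion path).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    effect_allele_freq: tuple[float, ...]
    inbreeding: tuple[float, ...] = None

    def __post_init__(self) -> None:
        SnpInfo(self.snp_id, self.chrom, self.pos, self.effect_allele, self.other_allele)
        for f in self.effect_allele_freq:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.snp_id}: frequency {f} outside [0, 1]")
        if self.inbreeding is None:
            object.__setattr__(self, "inbreeding", tuple(0.0 for _ in self.effect_allele_freq))
        elif len(self.inbreeding) != len(self.effect_allele_freq):
            raise ValueError(f"{self.snp_id}: inbreeding needs one value per population")

    def info(self) -> SnpInfo:
        return SnpInfo(self.snp_id, self.chrom, self.pos, self.effect_allele, self.other_allele)


@dataclass(frozen=True)
class CovariateParams:
    """Per-population covariate distribution parameters."""

    age_mean: float
    age_sd: float
    sex_male_prop: float
    education_probs: tuple[float, float, float]  # primary / secondary / higher
    vehicle_prop: float
    bmi_mean: float
    bmi_sd: float
    waist_mean: float
    waist_sd: float

    def __post_init__(self) -> None:
        for name in ("age_sd", "bmi_sd", "waist_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sex_male_prop", "vehicle_prop"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if any(p < 0 for p in self.education_probs) or not math.isclose(
            sum(self.education_probs), 1.0, abs_tol=1e-9
        ):
            raise ValueError("education_probs must be non-negative and sum to 1")


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model generating one binary LTPA outcome.

    ``snp_log_or`` maps SNP id -> per-effect-allele log odds ratio;
    ``covariate_coefs`` maps covariate name -> coefficient on the raw scale.
    """

    intercept: float
    snp_log_or: dict[str, float] = field(default_factory=dict)
    covariate_coefs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.covariate_coefs) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in outcome model: {sorted(unknown)}")


@dataclass(frozen=True)
class MetModel:
    """Log-normal MET-min/week model given participation (right-skewed support)."""

    meanlog: float
    sdlog: float

    def __post_init__(self) -> None:
        if self.sdlog <= 0:
            raise ValueError("sdlog must be positive")


@dataclass(frozen=True)
class DaysModel:
    """Days/week given participation: Binomial(7, p)."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("days probability outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    population_labels: tuple[str, ...]
    n_per_population: tuple[int, ...]
    snps: tuple[SnpSpec, ...]
    covariates: tuple[CovariateParams, ...]
    outcome_models: dict[str, OutcomeModel]
    met_models: dict[str, MetModel]
    days_models: dict[str, DaysModel]
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.population_labels)
        if k < 1:
            raise ValueError("at least one population required")
        if len(self.n_per_population) != k or len(self.covariates) != k:
            raise ValueError("per-population fields must have one entry per population")
        if any(n < 1 for n in self.n_per_population):
            raise ValueError("population sizes must be >= 1")
        for spec in self.snps:
            if len(spec.effect_allele_freq) != k:
                raise ValueError(f"{spec.snp_id}: needs one frequency per population")
        for name in OUTCOMES:
            if name not in self.outcome_models:
                raise ValueError(f"missing outcome model for {name!r}")
            if name not in self.met_models or name not in self.days_models:
                raise ValueError(f"missing MET/days model for {name!r}")
        snp_ids = {s.snp_id for s in self.snps}
        for name, model in self.outcome_models.items():
            orphan = set(model.snp_log_or) - snp_ids
            if orphan:
                raise ValueError(f"outcome {name!r} references absent SNPs: {sorted(orphan)}")

    @property
    def panel(self) -> PanelMetadata:
        return PanelMetadata(tuple(s.info() for s in self.snps))

    def population_index(self, label: str) -> int:
        return self.population_labels.index(label)


@dataclass
class Cohort:
    """Simulated genotypes plus the per-individual phenotype/covariate table."""

    genotypes: GenotypeMatrix
    table: pd.DataFrame


def _check_population(config: SimulationConfig, population_index: int) -> None:
    if not 0 <= population_index < len(config.population_labels):
        raise ValueError(f"unknown population index {population_index}")


def simulate_genotypes(config: SimulationConfig, population_index: int) -> GenotypeMatrix:
    """Draw the SNP panel for one population.

    Each SNP is sampled independently; a genotype is the sum of two Bernoulli
    draws at the population's effect-allele frequency, i.e. Binomial(2, f),
    which is Hardy-Weinberg consistent. A positive per-SNP inbreeding
    coefficient correlates the two draws, inflating homozygosity.
    """
    _check_population(config, population_index)
    rng = _child_rng(config.seed, _STAGE_GENOTYPES, population_index)
    n = config.n_per_population[population_index]
    label = config.population_labels[population_index]
    codes = np.empty((n, len(config.snps)), dtype=np.int8)
    for j, spec in enumerate(config.snps):
        f = spec.effect_allele_freq[population_index]
        F = spec.inbreeding[population_index]
        if F == 0.0:
            codes[:, j] = rng.binomial(2, f, size=n)
        else:
            # genotype distribution with fixation coefficient F:
            # P(2) = f^2 + F f(1-f), P(1) = 2 f (1-f) (1-F), P(0) = rest
            p2 = f * f + F * f * (1 - f)
            p1 = 2 * f * (1 - f) * (1 - F)
            u = rng.random(n)
            codes[:, j] = np.where(u < p2, 2, np.where(u < p2 + p1, 1, 0)).astype(np.int8)
    sample_ids = [f"{label}_{i:04d}" for i in range(n)]
    population = np.full(n, population_index, dtype=np.int64)
    return GenotypeMatrix(codes, sample_ids, config.panel, population)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], n: int
) -> np.ndarray:
    lo, hi = bounds
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_covariates(config: SimulationConfig, population_index: int) -> pd.DataFrame:
    """Draw covariates for one population.

    Age, BMI and waist circumference are truncated normals (age 20-64; BMI
    15-60; waist 50-200). Sex (1 = male) and vehicle use are Bernoulli;
    education is a 3-level multinomial coded ordinally 0/1/2
    (primary/secondary/higher). Ethnicity carries the population index.
    """
    _check_population(config, population_index)
    rng = _child_rng(config.seed, _STAGE_COVARIATES, population_index)
    n = config.n_per_population[population_index]
    params = config.covariates[population_index]
    label = config.population_labels[population_index]
    age = _truncated_normal(rng, params.age_mean, params.age_sd, AGE_BOUNDS, n)
    sex = rng.binomial(1, params.sex_male_prop, size=n)
    education = rng.choice(3, size=n, p=params.education_probs)
    vehicle = rng.binomial(1, params.vehicle_prop, size=n)
    bmi = _truncated_normal(rng, params.bmi_mean, params.bmi_sd, BMI_BOUNDS, n)
    waist = _truncated_normal(rng, params.waist_mean, params.waist_sd, WAIST_BOUNDS, n)
    return pd.DataFrame(
        {
            "sample_id": [f"{label}_{i:04d}" for i in range(n)],
            "population": label,
            "ethnicity": population_index,
            "age": age,
            "sex": sex,
            "education": education,
            "vehicle": vehicle,
            "bmi": bmi,
            "waist": waist,
        }
    )


def simulate_phenotypes(
    genotypes: GenotypeMatrix, covariates: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Draw the four binary LTPA outcomes plus MET-min/week and days/week.

    Binary outcome ~ Bernoulli(expit(linear predictor)); given participation,
    MET-min/week is log-normal and days/week is Binomial(7, p); both are
    exactly zero for non-participants.
    """
    if len(covariates) != genotypes.n_individuals:
        raise ValueError("covariate table and genotype matrix disagree on n")
    rng = _child_rng(config.seed, _STAGE_PHENOTYPES)
    out = covariates.copy()
    n = len(out)
    for name in OUTCOMES:
        model = config.outcome_models[name]
        lp = np.full(n, model.intercept, dtype=float)
        for snp_id, beta in model.snp_log_or.items():
            g = genotypes.column(snp_id).astype(float)
            if (g < 0).any():
                raise ValueError(f"missing genotypes for {snp_id} in phenotype simulation")
            lp += beta * g
        for cov, coef in model.covariate_coefs.items():
            lp += coef * out[cov].to_numpy(dtype=float)
        prob = 1.0 / (1.0 + np.exp(-lp))
        y = rng.binomial(1, prob)
        met_m = config.met_models[name]
        met = np.where(y == 1, rng.lognormal(met_m.meanlog, met_m.sdlog, size=n), 0.0)
        days = np.where(y == 1, rng.binomial(7, config.days_models[name].p, size=n), 0)
        out[f"ltpa_{name}"] = y
        out[f"met_{name}"] = met
        out[f"days_{name}"] = days
    return out


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate all populations and concatenate into one cohort."""
    geno_parts = [simulate_genotypes(config, k) for k in range(len(config.population_labels))]
    codes = np.vstack([g.codes for g in geno_parts])
    sample_ids = [sid for g in geno_parts for sid in g.sample_ids]
    population = np.concatenate([g.population for g in geno_parts])
    genotypes = GenotypeMatrix(codes, sample_ids, config.panel, population)
    covariates = pd.concat(
        [simulate_covariates(config, k) for k in range(len(config.population_labels))],
        ignore_index=True,
    )
    table = simulate_phenotypes(genotypes, covariates, config)
    return Cohort(genotypes, table)


def simulate_phased_genotype_pair(
    freq_a: float, freq_b: float, d: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate two linked loci from phased haplotypes, collapsed to genotypes.

    Haplotype frequencies are (p_AB, p_Ab, p_aB, p_ab) with disequilibrium
    ``d`` = p_AB - freq_a * freq_b. Returns (codes_a, codes_b, haplotype freqs).
    Used to validate the EM haplotype-frequency estimator against truth.
    """
    hap = np.array(
        [
            freq_a * freq_b + d,
            freq_a * (1 - freq_b) - d,
            (1 - freq_a) * freq_b - d,
            (1 - freq_a) * (1 - freq_b) + d,
        ]
    )
    if (hap < -1e-12).any():
        raise ValueError("disequilibrium d incompatible with allele frequencies")
    hap = np.clip(hap, 0.0, None)
    hap = hap / hap.sum()
    draws = rng.choice(4, size=(n, 2), p=hap)  # two haplotypes per individual
    carries_a = (draws <= 1).sum(axis=1).astype(np.int8)  # haplotypes 0,1 carry allele A
    carries_b = ((draws == 0) | (draws == 2)).sum(axis=1).astype(np.int8)
    return carries_a, carries_b, hap


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Default two-population study configuration.

    Emulates a survey of 330 + 314 adults (a majority-population sample and a
    Roma sample) genotyped for seven LTPA-candidate SNPs. Allele frequencies
    are chosen so that four SNPs differ markedly between populations and three
    do not; per-allele effects on LTPA outcomes are small (OR about 1.05-1.5)
    with the strongest signal on rs10887741 for LTPA in general. Covariate
    distributions mirror the published descriptive structure (education and
    vehicle use differing strongly between populations; age/BMI/waist similar).
    """
    snps = (
        SnpSpec("rs10252228", "7", 34900427, "G", "A", (0.45, 0.30)),
        SnpSpec("rs12612420", "2", 200293399, "G", "A", (0.40, 0.55)),
        SnpSpec("rs7023003", "9", 105118389, "G", "A", (0.15, 0.12)),
        SnpSpec("rs459465", "20", 54806483, "G", "A", (0.35, 0.20)),
        SnpSpec("rs6022999", "20", 54171474, "A", "G", (0.30, 0.28)),
        SnpSpec("rs10887741", "10", 87683553, "C", "T", (0.55, 0.40)),
        SnpSpec("rs8097348", "18", 1595020, "A", "G", (0.25, 0.27)),
    )
    covariates = (
        CovariateParams(44.1, 11.5, 0.44, (0.20, 0.61, 0.19), 0.74, 27.3, 4.8, 96.2, 12.5),
        CovariateParams(42.7, 11.8, 0.25, (0.87, 0.12, 0.01), 0.25, 27.5, 5.2, 94.5, 13.0),
    )
    outcome_models = {
        "general": OutcomeModel(
            intercept=1.35,
            snp_log_or={
                "rs10887741": math.log(1.48),
                "rs6022999": math.log(1.29),
                "rs7023003": math.log(1.25),
                "rs10252228": math.log(1.09),
                "rs12612420": math.log(1.09),
                "rs8097348": math.log(1.06),
                "rs459465": math.log(1.01),
            },
            covariate_coefs={
                "age": -0.010,
                "sex": 0.10,
                "education": 0.25,
                "vehicle": 0.15,
                "bmi": -0.020,
                "waist": -0.002,
                "ethnicity": -0.10,
            },
        ),
        "vigorous": OutcomeModel(
            intercept=-0.15,
            snp_log_or={"rs10887741": math.log(1.25), "rs7023003": math.log(1.15)},
            covariate_coefs={
                "age": -0.020,
                "sex": 0.30,
                "education": 0.45,
                "vehicle": 0.35,
                "bmi": -0.030,
                "ethnicity": -0.60,
            },
        ),
        "moderate": OutcomeModel(
            intercept=0.35,
            snp_log_or={"rs10887741": math.log(1.23), "rs10252228": math.log(1.15)},
            covariate_coefs={
                "age": -0.012,
                "sex": 0.05,
                "education": 0.35,
                "vehicle": 0.20,
                "bmi": -0.020,
                "ethnicity": -0.45,
            },
        ),
        "walking": OutcomeModel(
            intercept=0.35,
            snp_log_or={"rs10887741": math.log(1.15), "rs6022999": math.log(1.20)},
            covariate_coefs={
                "age": 0.000,
                "sex": -0.15,
                "education": 0.10,
                "vehicle": -0.05,
                "bmi": -0.005,
                "ethnicity": -0.05,
            },
        ),
    }
    met_models = {
        "general": MetModel(7.00, 0.90),
        "vigorous": MetModel(6.40, 0.90),
        "moderate": MetModel(6.10, 0.90),
        "walking": MetModel(5.70, 0.80),
    }
    days_models = {
        "general": DaysModel(0.50),
        "vigorous": DaysModel(0.35),
        "moderate": DaysModel(0.40),
        "walking": DaysModel(0.50),
    }
    return SimulationConfig(
        population_labels=("general", "roma"),
        n_per_population=(330, 314),
        snps=snps,
        covariates=covariates,
        outcome_models=outcome_models,
        met_models=met_models,
        days_models=days_models,
        seed=seed,
    )
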