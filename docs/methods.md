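# Methods

This package reimplements, as a tested pipeline, a candidate-gene analysis of
leisure-time physical activity (LTPA) in two adult populations: a small SNP
panel goes through Hardy-Weinberg and linkage-disequilibrium QC, each SNP is
tested for association with four binary LTPA outcomes by covariate-adjusted
logistic regression, an unweighted count polygenic score is optimized by
forward selection, and activity volume is tested for a monotone trend across
score categories. Because the individual-level data of the motivating study
design are not publicly deposited, the package ships a synthetic cohort
generator that reproduces the *statistical structure* of such a survey; all
tests and the acceptance script run against synthetic data.

## The synthetic cohort

Two populations (labelled `general` and `roma`, default sizes 330 and 314) of
adults aged 20-64. Per population and SNP, genotypes are drawn as
Binomial(2, f) effect-allele counts — i.e. two independent allele draws — so
each population is in Hardy-Weinberg equilibrium by construction. An optional
per-SNP fixation-style coefficient F > 0 correlates the two draws
(P(hom) = f² + Ffq), which is used only to exercise the HWE-exclusion path.
No between-locus linkage is simulated by default (the panel is expected to be
LD-free); a separate phased two-locus simulator with explicit disequilibrium D
exists solely to validate the EM estimator.

Covariates: age, BMI and waist circumference are truncated normals (age
20-64, BMI 15-60, waist 50-200 — bounds are documented constants matching an
adult survey population); sex and vehicle use are Bernoulli; education is a
3-level multinomial coded ordinally 0/1/2 (primary/secondary/higher).
Covariates are drawn independently; real anthropometrics are correlated
(BMI-waist in particular), so passing tests say nothing about collinearity
behaviour on real data.

Each binary LTPA outcome (general, vigorous, moderate, walking) follows a
logistic model: per-allele log-odds-ratios per SNP plus covariate
coefficients. Default effect sizes are small (OR about 1.05-1.5 per allele,
strongest on rs10887741 for LTPA in general) and default intercepts give
participation prevalences of roughly 0.75 (general), 0.2 (vigorous), 0.4
(moderate) and 0.6 (walking). Given participation, MET-min/week is log-normal
(right-skewed, so the normality gate is exercised) and days/week is
Binomial(7, p); both are exactly zero for non-participants. Allele
frequencies default to values under which four of the seven SNPs differ
clearly between populations and three do not.

The generator does **not** simulate questionnaire items, household/colony
sampling design, ancestry structure beyond per-population allele frequencies,
genotyping error, or covariate correlation — results on synthetic data
therefore validate the statistical machinery, not survey-specific biases.

Randomness: one master seed; every stage (genotypes per population,
covariates per population, phenotypes) draws from a child stream derived via
`numpy.random.SeedSequence(seed, spawn_key=(stage, population))`, so any stage
is reproducible in isolation and whole runs are byte-identical under a fixed
seed.

## QC statistics

* **Allele frequency**: effect-allele count over 2 x (non-missing n), per
  population.
* **HWE**: 1-df Pearson chi-square of observed genotype counts against
  n(p², 2pq, q²) with p estimated from the sample. A SNP is excluded when the
  HWE p-value falls below alpha (default 0.05) in either population.
  Monomorphic SNPs have no testable departure: they are flagged, never
  excluded on HWE grounds. An exact HWE test is deliberately not offered; the
  chi-square matches the analysis convention this pipeline reproduces.
* **LD**: two-locus haplotype frequencies by EM on unphased genotypes. Only
  the double heterozygote is phase-ambiguous; the E-step splits it between
  cis (AB/ab) and trans (Ab/aB) resolutions in proportion to current
  haplotype frequency products. EM starts at linkage-equilibrium frequencies
  (tolerance 1e-8 on the max frequency change, max 1000 iterations), so a
  degenerate all-ambiguous sample stays at the equilibrium solution — the
  documented tie-break. D' and r² follow the standard definitions; a pair is
  flagged "linked" at r² >= 0.8 (configurable; the threshold is a package
  convention, chosen because the analysis only needs a qualitative no-linkage
  statement).
* **Between-population frequency test**: Pearson chi-square on the 2x2
  allele-count table (2n alleles per group), no continuity correction.
* **Power**: two-sided normal approximation for the difference of two
  proportions with unpooled variance on allele counts. Chosen because the
  original online calculator's internals are undocumented; the approximation
  is validated against a 10,000-replicate Monte-Carlo of the chi-square test
  (agreement within 0.02 at the panel's typical frequencies).

## Association model

Additive coding: 0/1/2 effect alleles, where the effect allele is declared a
priori as the LTPA-promoting allele and fixed in panel metadata (a warning
fires if a declared effect allele fits with OR < 1). Logistic fits use
Newton-Raphson maximum likelihood (statsmodels backend) with the covariance
taken as the inverse observed information; Wald 95% CIs and p-values match the
conventions of mainstream statistical packages. The adjusted model uses
exactly seven covariates: age, sex, ethnicity, education (ordinal 0/1/2),
vehicle use, BMI, waist circumference. Education's ordinal coding and the
untransformed continuous covariates are package conventions (the motivating
design names the covariates but not their encodings).

Separation and rank deficiency raise explicit errors naming the predictor
rather than returning a penalized fit: with a small common-variant panel,
separation indicates a data pathology worth surfacing. Individuals with any
missing genotype on the panel are excluded once, upstream of all association
and scoring stages; every stage reports its n.

Cox-Snell pseudo-R²: `1 - exp(2(LL0 - LL1)/n)` with LL0 the intercept-only
null — the convention used by the statistical package the original analysis
relied on, and the quantity the optimization criterion compares.

## Score optimization

The score is the plain sum of effect-allele counts over a SNP set (all alleles
equal in direction and size). Candidates are ranked by ascending adjusted
single-SNP p-value on the combined two-population sample (ties: larger
|log OR| first, then lexical id). The top SNP seeds the score unconditionally.
Each subsequent candidate joins a trial score; the adjusted logistic fit of
LTPA-in-general on the trial score must show a *strictly* smaller Wald p and
a *strictly* larger Cox-Snell R² than the best score so far, else the SNP is
rejected (equality rejects). Comparison is against the best-so-far model, not
the immediately preceding trial. The full trajectory (p and R² before/after,
decision) is recorded.

Categories: distinct integer score values are merged from the extremes inward
— the end with the smaller outermost bin merges first, ties merge the low end
— until at most `n_groups` (default 4) bins remain and every bin holds at
least `min_group_frac` (default 10%) of individuals. The integer-merge rule
reproduces groupings of the form 0-1 / 2 / 3 / 4-5 on roughly symmetric score
distributions; quartile cuts were rejected because integer scores make exact
quartiles unattainable.

## Trend and comparison statistics

Jonckheere-Terpstra: the sum over ordered group pairs of Mann-Whitney counts
(ties half-weighted). For pooled n <= 20 *and* at most 250,000 distinct group
assignments, the two-sided p is exact by full enumeration using the
conservative doubling convention min(1, 2 min(P(JT<=obs), P(JT>=obs)));
otherwise the tie-corrected normal approximation is used. The enumeration
guard exists because multi-group layouts near n = 20 can exceed 10⁹
assignments. The normal approximation should not be trusted below n of about
10-12: the permutation distribution is discrete with atoms as large as 1/3 at
n = 4, so no continuous approximation tracks the exact p closely there — which
is exactly why the exact path covers those sizes. A Monte-Carlo check at
n = 120 shows approximation error under 0.02 where the normal path is used.

Mann-Whitney U follows the same exact-below-20 / tie-corrected-normal-above
scheme. Templeton's two-step transform maps values to mid-rank percentiles
rank/(n+1) (the open-interval form avoids infinite normal quantiles at the
extremes), applies the inverse standard normal, and rescales to the input
mean and ddof-1 SD; it is strictly rank-preserving and errors on constant
input. A Shapiro-Wilk gate at alpha 0.05 decides whether the transform is
applied before mean/CI reporting; the trend tests themselves are rank-based
and skip the gate. Group-mean 95% CIs are normal-approximation (mean +/-
1.96 SE) on the analyzed scale.

Bonferroni: the score-analysis threshold is alpha divided by the number of
SNPs retained in the optimized score (display rounded to 3 decimals, e.g.
0.017 for three SNPs; flagging uses the unrounded value).

Trend tables are computed both including zeros for non-participants (the
default summary, since category sizes then add up to the full genotyped
sample) and restricted to participants.

## Pipeline and formats

Genotypes travel as a minimal VCF (biallelic SNVs, GT only; REF = other
allele, ALT = effect allele on write; on read, dosages are re-oriented to
effect-allele counts, so swapping effect/other in the panel maps g to 2 - g)
or as a 0/1/2 dosage CSV; missing is `./.` or an empty/`NA` cell. Phenotypes
are a documented CSV; rows violating the zero-inflation contract (activity
volume reported without participation) are hard errors, rows missing required
covariates are excluded with a logged count. The YAML run configuration is
versioned and fail-fast on unknown keys; the run summary embeds a hash of the
analytic configuration (output location excluded). All outputs are plain TSV/
CSV/JSON written with fixed float formatting, so repeat runs under the same
seed are byte-identical.

## Problem sizes used in the test suite

Oracle-equivalence suites use 1000 random instances each; null-calibration
suites use 2000 replicates at n = 500; parameter recovery uses a single
n = 20,000 cohort plus 1000 coverage replicates at n = 2000; the optimization
sensitivity check uses 200 replicates at n = 2000 with one causal SNP (OR
1.5) among six nulls. These sizes keep every Monte-Carlo band at least three
standard errors wide.

## Known limitations

* Wald inference only; no profile-likelihood or Firth fallback, so heavily
  imbalanced outcomes with rare alleles can abort with a separation error.
* The forward-selection score inherits the instability of stepwise methods;
  on null panels it occasionally admits a noise SNP (the joint p-and-R²
  criterion keeps this rare, and the behaviour is regression-tested).
* The EM LD estimator assumes Hardy-Weinberg within the sample used; applying
  it across pooled divergent populations can manufacture spurious LD.
* Descriptive tables compare populations with unweighted tests; no survey
  weights or age standardization.
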