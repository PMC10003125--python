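# ltpa-pgs

Candidate-SNP quality control, association testing and optimized polygenic
score construction for **leisure-time physical activity (LTPA)** in a
two-population cohort, with a synthetic cohort generator so the entire
analysis is reproducible without access to individual-level survey data.

The package is aimed at genetic-epidemiology analyses of the following shape:
a small panel of candidate SNPs genotyped in two populations, four binary
activity outcomes (any LTPA, plus vigorous / moderate / walking intensity),
IPAQ-style activity volumes (MET-min/week, days/week), and a fixed covariate
set (age, sex, ethnicity, education, vehicle use, BMI, waist circumference).

## The statistics at its core

* **Panel QC** — per-population effect-allele frequencies; 1-df Pearson
  χ² test of Hardy–Weinberg equilibrium with exclusion at α = 0.05 in either
  population; pairwise linkage disequilibrium (D′, r²) from EM-estimated
  two-locus haplotype frequencies on unphased genotypes; 2×2 allele-count χ²
  between populations with a normal-approximation power calculation.
* **Association** — additive (per effect-allele) logistic regression of each
  outcome, univariate and adjusted for the seven covariates, reporting
  OR with Wald 95% CI and p, and the Cox–Snell pseudo-R²
  `R² = 1 − exp(2(LL₀ − LL₁)/n)`.
* **Optimized polygenic score (oPGS)** — the unweighted count score
  `GRS = Σᵢ Gᵢ` (Gᵢ ∈ {0,1,2} effect-allele counts), built by forward
  selection: candidates enter in ascending adjusted p-value order and are
  kept only if they strictly decrease the score's association p *and*
  strictly increase its Cox–Snell R².
* **Trend analysis** — genetic-predisposition categories formed by merging
  integer score values from the extremes (each category ≥ 10% of the sample),
  then the Jonckheere–Terpstra test (exact permutation p on small samples,
  tie-corrected normal otherwise) for a monotone trend of MET-min/week and
  days/week across categories, with a Bonferroni threshold of α divided by
  the number of SNPs in the score.

## Worked example

The analysis is organised as numbered drivers over the library:

```sh
python analysis/01_simulate_cohort.py --seed 1   # cohort -> results/data/
python analysis/02_genotype_qc.py     --seed 1   # QC     -> results/qc/
python analysis/03_snp_association.py --seed 1   # per-SNP -> results/association/
python analysis/04_optimize_score.py  --seed 1   # oPGS   -> results/pgs/
python analysis/05_trend_analysis.py  --seed 1   # trends -> results/trend/
```

With seed 1 the run prints, abridged:

```
simulated 644 individuals (330 general, 314 roma), 7 SNPs
7 SNPs tested; excluded for HWE deviation: ['rs10252228']
significant between-population frequency difference: ['rs10252228', 'rs12612420', 'rs459465', 'rs10887741']
adjusted per-allele associations with LTPA in general (ascending p):
  rs6022999: OR 1.79 (1.31-2.44), p = 0.000
  rs10887741: OR 1.37 (1.05-1.79), p = 0.021
  ...
accepted into the optimized score: ['rs6022999', 'rs10887741']
oPGS vs LTPA in general, adjusted: OR 1.52 (1.25-1.86), p = 3.8e-05 (Bonferroni threshold 0.025)
predisposition categories (score ranges): ['0', '1', '2', '3-4']
  MET-min/week, general: p = 9.033e-05 *
oPGS general: 1.61 +/- 0.96 vs roma: 1.46 +/- 0.99 (Mann-Whitney p = 0.0391)
```

Reading this: one SNP fell at the Hardy–Weinberg gate (at α = 0.05 per
population, occasional false exclusions are expected); four SNPs differ in
allele frequency between the populations by construction of the generator;
forward selection kept two SNPs whose combined count score associates with
LTPA far more strongly (p ≈ 4×10⁻⁵) than any single SNP; activity volume
rises monotonically across the four score categories; and the
majority-population sample carries a higher mean score than the Roma sample,
mirroring its higher configured frequencies of the activity-promoting
alleles.

The same pipeline runs on real data from a minimal VCF plus phenotype CSV via
the YAML configuration (`inputs:` block instead of `simulation:`), or from
the command line: `ltpa-pgs run --config config.yaml` (subcommands:
`simulate`, `qc`, `assoc`, `optimize`, `trend`, `run`).

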