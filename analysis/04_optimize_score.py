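"""Forward optimization of the unweighted count polygenic score.

Ranks QC-passing SNPs by their adjusted association p-value with LTPA in
general, seeds the score with the top SNP, and adds the remaining candidates
one at a time, keeping each only if it strictly lowers the score's p-value and
strictly raises the Cox-Snell R². Writes the acceptance trajectory, the final
score's association with each outcome (univariate and adjusted), and the
genetic-predisposition categories.
"""

import argparse
from pathlib import Path

import pandas as pd

from ltpa_pgs import association, cohort_sim, genotype_qc, io_cli, pgs, trend_stats

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/pgs"))
args = parser.parse_args()

config = cohort_sim.default_study_config(seed=args.seed)
genotypes = io_cli.read_genotypes(args.data / "genotypes.vcf", config.panel)
table = io_cli.read_phenotypes(args.data / "phenotypes.csv")
qc = genotype_qc.qc_panel(genotypes, table["population"].to_numpy())
genotypes = genotypes.subset_snps([r.snp_id for r in qc if not r.excluded])

covariates = table.loc[:, list(association.ADJUSTMENT_COVARIATES)].to_numpy(float)
y = table["ltpa_general"].to_numpy(float)
assocs = [
    association.snp_association(
        genotypes.column(s).astype(float), y, covariates, adjusted=True, snp_id=s
    )
    for s in genotypes.snp_ids
]
model = pgs.optimize_pgs(genotypes, y, covariates, assocs)

args.out.mkdir(parents=True, exist_ok=True)
traj = pd.DataFrame([vars(t) for t in model.trajectory])
traj.to_csv(args.out / "trajectory.tsv", sep="\t", index=False, float_format="%.10g")

score = pgs.count_score(genotypes, model.accepted)
bonf = trend_stats.bonferroni_alpha(0.05, len(model.accepted))
rows = []
for outcome in cohort_sim.OUTCOMES:
    yy = table[f"ltpa_{outcome}"].to_numpy(float)
    for kind, cov, names in (
        ("univariate", None, ()),
        ("multivariate", covariates, association.ADJUSTMENT_COVARIATES),
    ):
        res = association.predictor_association(
            score.scores.astype(float), yy, cov, names, predictor_id="oPGS",
            outcome_id=outcome,
        )
        rows.append({
            "outcome": outcome, "model": kind, "odds_ratio": res.odds_ratio,
            "ci95_low": res.ci95_low, "ci95_high": res.ci95_high, "p": res.p_wald,
            "significant_after_correction": bonf.significant(res.p_wald),
        })
score_assoc = pd.DataFrame(rows)
score_assoc.to_csv(args.out / "score_association.tsv", sep="\t", index=False,
                   float_format="%.10g")

labels, bounds = pgs.categorize_scores(score.scores)
out_table = table.copy()
out_table["oPGS"] = score.scores
out_table["oPGS_category"] = labels
io_cli.write_phenotypes(out_table, args.out / "phenotypes_with_score.csv")

print(f"candidate order (ascending adjusted p): {model.candidate_order}")
print(f"accepted into the optimized score: {model.accepted}")
adj = score_assoc.query("outcome == 'general' and model == 'multivariate'").iloc[0]
print(f"oPGS vs LTPA in general, adjusted: OR {adj.odds_ratio:.2f} "
      f"({adj.ci95_low:.2f}-{adj.ci95_high:.2f}), p = {adj.p:.2g} "
      f"(Bonferroni threshold {bonf.display})")
print(f"predisposition categories (score ranges): "
      f"{['-'.join(map(str, b)) if b[0] != b[1] else str(b[0]) for b in bounds]}")
print(f"wrote {args.out}/trajectory.tsv, score_association.tsv, phenotypes_with_score.csv")
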