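"""Trichotomized robust scores, sum scores and lineage concordance.

For each effect (3D-2D medium shift; hypoxia-normoxia treatment shift):
computes the adjusted per-(cell line, replicate) effect residuals,
trichotomizes them against the pooled quartiles (+1 top 25%, -1 bottom
25%), sums scores by column / condition / protein, calls per-lineage
concordance under the strict >50% rule (6/10 glioma, 7/12 adenocarcinoma
columns), and writes the figure-style report tables sorted by fold
change.

Reads:  results/sheet.tsv, results/matrix_centered.tsv, results/anova.tsv
Writes: results/scores_<effect>.tsv, results/calls_<effect>.tsv,
        results/report_<effect>.tsv
"""

import argparse
from pathlib import Path

import pandas as pd

from rppa_triscore import read_sample_sheet
from rppa_triscore.anova import effect_residuals
from rppa_triscore.scoring import figure_table, score_effect

ap = argparse.ArgumentParser()
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

sheet = read_sample_sheet(args.outdir / "sheet.tsv")
matrix = pd.read_csv(args.outdir / "matrix_centered.tsv", sep="\t", index_col=0)
anova = pd.read_csv(args.outdir / "anova.tsv", sep="\t", index_col=0)

for effect in ("medium", "treatment"):
    col_res, cond_res = effect_residuals(matrix, sheet, effect)
    ss, calls = score_effect(col_res, cond_res, sheet, effect)
    groups = calls["grouping"].value_counts().to_dict()
    print(f"{effect}: groupings {groups}")
    worst = ss.averaged_sums.idxmin()
    best = ss.averaged_sums.idxmax()
    print(f"  most down-regulated line: {worst} (averaged sum {ss.averaged_sums[worst]:.1f}); "
          f"most up-regulated: {best} ({ss.averaged_sums[best]:.1f})")

    sc = ss.scores.copy()
    sc.columns = [f"{l}_r{r}" for l, r in sc.columns]
    sc.to_csv(args.outdir / f"scores_{effect}.tsv", sep="\t", float_format="%.0f")
    calls.to_csv(args.outdir / f"calls_{effect}.tsv", sep="\t")
    figure_table(anova, ss, calls, effect).to_csv(
        args.outdir / f"report_{effect}.tsv", sep="\t", float_format="%.6g")

print(f"-> {args.outdir}/scores_*.tsv, calls_*.tsv, report_*.tsv")
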