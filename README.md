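# rppa-triscore

Reverse-phase protein arrays (RPPA) probe cell lysates spotted in serial
dilution series on slides, one antibody per slide, to measure relative
protein and phosphoprotein abundance across many samples at once.  This
package implements a complete, tested analysis pipeline for a factorial
RPPA experiment contrasting tumor cell lines (glioma vs adenocarcinoma
lineages) grown in monolayer (2D) vs spheroid (3D) culture under normoxia
vs hypoxia — and a synthetic slide generator that emulates that design so
every stage can be validated against known ground truth.

## The method

1. **Quantification.** Each slide carries, per sample, five serial 1:2
   dilutions spotted in triplicate (the middle series in normal
   orientation, the flanking two mirrored) plus pooled positive and buffer
   negative controls.  After a linear spatial-trend correction, one joint
   four-parameter logistic response curve is fit per antibody,

   *y* = *L* + (*U* − *L*) / (1 + exp(−η(*x*ₛ − *k*))),

   jointly over the shared curve (*L*, *U*, η; center fixed at 0) and one
   log2 concentration *x*ₛ per sample, with dilution step *k* entering as
   an exact −1 shift per step on the log2 axis.

2. **QC and normalization.** Antibodies must pass a control-based
   signal-to-noise filter (SNR ≥ 2) and a replicate-correlation filter
   (Pearson r > 0.5 between replicate-1 and replicate-2 values across
   design cells); sample rows are median-centered to remove loading
   differences; a label-swap scan flags sample pairs whose relabelling
   would raise both replicate correlations; technical and effect variance
   components are estimated from exact replicate pairs.

3. **Inference.** Per protein, a three-way fixed-effects ANOVA
   value ~ cellline + medium + treatment + medium:treatment (sum-to-zero
   contrasts, Type II tests) yields term p-values and marginal effect
   estimates, reported as signed fold changes (2^δ for δ ≥ 0, −2^(−δ)
   otherwise).  Each term's p-value distribution is modelled as a
   beta-uniform mixture f(p) = λ + (1 − λ)·a·p^(a−1); cutoffs targeting
   5% and 1% FDR come from the conservative estimate
   FDR(τ) = π·τ / (λτ + (1 − λ)τ^a) with π = λ + (1 − λ)a.

4. **Robust scoring.** For each effect, per-(cell line, replicate)
   adjusted residuals (e.g. the 3D − 2D difference averaged over
   treatments after removing fitted treatment and interaction terms) are
   trichotomized against the pooled quartiles: +1 (top 25%), −1 (bottom
   25%), 0 otherwise.  Scores are summed by column, condition and
   protein; a protein is called up/down/neutral per lineage when a strict
   majority (>50%: 6 of 10 glioma, 7 of 12 adenocarcinoma columns) of
   that lineage's columns agree, and the pair of calls maps to one of six
   groupings (both-up, both-down, both-neutral, GL-specific, AC-specific,
   ill-defined).

The synthetic generator plants known cell-line, medium, treatment and
lineage-specific effects at the experiment's variance scales (replicate
variance 0.0053, design-cell variance 0.4615 on the log2 scale) so the
whole chain can be checked end to end.

## Worked example

Run the numbered analysis drivers from the repository root:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_quantify.py
python analysis/03_preprocess.py
python analysis/04_anova_bum.py
python analysis/05_score.py
```

which prints (seed 1):

```
design: 85 samples (11 lines, 88 before drops)
panel: 40 antibodies; planted medium signal in 22, treatment signal in 12
rendered 57800 spots across 40 slides -> results/spots.tsv
spatial correction: mean fitted slopes d_row=3.07, d_col=1.58 intensity/grid-unit
quantified 85 samples x 40 antibodies; 0 sample flags; all converged: True
truth recovery: median rms error 0.176 log2 units (replicate + loading noise scale)
signal-to-noise filter: 40/40 antibodies pass (median SNR 212)
replicate-correlation filter: 40/40 retained (median r 0.985)
label-swap scan: 0 candidate pair(s)
variance components: technical 0.0065 (target 0.0053), effect 0.4862 (target 0.4615)
ANOVA: 40 proteins; p<0.05 counts — medium: 30, treatment: 14, interaction: 0
BUM medium: lam=0.00 a=0.06 pi_ub=0.06; 40 proteins at 5% FDR
BUM treatment: lam=0.62 a=0.05 pi_ub=0.63; 13 proteins at 5% FDR
BUM interaction: lam=1.00 a=1.00 pi_ub=1.00; 0 proteins at 5% FDR
medium: groupings {'both-neutral': 18, 'both-up': 8, 'both-down': 8,
                   'GL-specific': 3, 'AC-specific': 3}
```

Reading the output: the full factorial design would hold 88 samples, three
replicates failed, leaving 85.  Quantified concentrations track the
simulated truth to 0.176 log2 units rms — the replicate plus loading noise
floor.  The variance components recover the generator's scales (replicate
pairs agree ~90x more tightly than conditions differ), the interaction
BUM fit is flat (no planted interaction; uniform p-values, π = 1, no
5%-FDR calls), and the six-way concordance grouping recovers the planted
classes exactly: 8 both-up, 8 both-down, 3 glioma-specific, 3
adenocarcinoma-specific, 18 neutral.

The same chain is available as a single command (`rppa-triscore run
--out results/run`) or per stage (`rppa-triscore simulate|quantify|
preprocess|anova|bum|score`), and as a library (`rppa_triscore.run_pipeline`).

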