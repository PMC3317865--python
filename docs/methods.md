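# Methods

## Scope and data model

The pipeline analyses a factorial RPPA experiment: 11 cell lines (5
high-grade glioma: U87, U251, SNB19, LNZ308, LN229; 6 adenocarcinoma:
MCF7, MDA231, MDA468, MiaPaCa, OVCAR5, SKOV3) crossed with culture medium
(2D monolayer vs 3D spheroid), oxygen treatment (normoxia 21% O2 vs
relative hypoxia 1% O2) and biological replicate (2).  The full crossing
is 88 samples; three replicates are dropped by default (LNZ308 3D under
both treatments, U87 3D normoxia — each replicate 2), leaving 85 samples
and 41 intact replicate pairs.  Sample identifiers are synthesized as
`<line>_<medium>_<treatment>_r<rep>`.

Data flow: spot-level intensity tables (antibody × sample × dilution step
× series × grid position × role) → per-antibody joint logistic fits → an
85 × A log2 concentration matrix → QC/normalization → per-protein ANOVA →
BUM-FDR → trichotomized scores and concordance calls.

## Synthetic slide generator

Truth follows the additive factorial model the downstream ANOVA assumes:

    x[s,p] = grand_mean + cellline(line(s), p) + medium_p + treatment_p
             + interaction_p

on the log2 scale.  Design choices:

- **Replicate noise.** Exact replicates share a truth value; all
  replicate-to-replicate variation is a single per-(antibody, sample)
  perturbation on the log2 axis, applied at render time before the curve
  mapping, with variance `technical_sd**2 = 0.0053`.  This is precisely
  the quantity a paired-replicate estimator measures, and it makes the
  three-way model correctly specified (iid observation noise), so null
  p-values are exactly uniform.  The generator deliberately does not
  separate culture-to-culture biology from assay noise — the pair
  variance is what is observable.
- **Variance budget.** Per-protein cell-line effects are drawn
  N(0, s_p²) and centered, with s_p² set so that the expected ddof-1
  variance of the 44 design-cell means equals `effect_sd**2 = 0.4615`
  after accounting for the variance contributed by planted effects
  (including the finite-sample correction for line effects repeating
  across the 4 conditions).  Every protein therefore carries the same
  design-cell variance scale whether or not it bears signal, and the
  implied replicate correlation is 0.4615/(0.4615 + 0.0053) ≈ 0.989.
- **Planted classes.** The default panel assigns, by position: ~21% of
  proteins a common (both-lineage) 3D−2D increase of +0.8 log2 units,
  ~21% a decrease, ~8% a glioma-only and ~8% an adenocarcinoma-only
  increase; treatment effects (±0.6) go to ~4% common up, ~13% common
  down, ~13% glioma-only up; no interaction is planted.  The asymmetry
  (many medium changes, fewer treatment changes, glioma-specific hypoxia
  increases, a flat interaction) mirrors the experimental setting the
  generator emulates.  Effect sizes sit far above the replicate noise
  (0.8 vs sd 0.073) — recovery at these settings demonstrates the
  machinery, not statistical power at marginal effect sizes.
- **Rendering.** Intensities follow y = L + (U−L)/(1+exp(−η(x−k−m))) with
  defaults L = 1000, U = 50000, η = 1, m = 0, per-spot Gaussian intensity
  noise (sd 150), a linear spatial gradient in grid coordinates (default
  (3.0, 1.5) intensity per grid unit in the full pipeline), and a
  per-sample loading offset on the log2 axis (sd 0.15) shared across
  antibodies, which row median-centering later removes.  Grid layout: one
  sample per row; the triplicate series occupy three column blocks with
  the flanking blocks printed in reversed step order; pooled positive
  (equal-weight mixture of all simulated samples) and buffer negative
  controls terminate each sample row.
- Not modelled: antibody staining chemistry, colorimetric saturation
  artifacts, slide-to-slide batch structure, per-protein differences in
  curve shape.  Passing tests therefore validate the statistical chain
  under idealized logistic responses, not robustness to curve
  misspecification.

## Quantification

One shared curve per antibody is fit jointly with one concentration per
sample by trust-region nonlinear least squares over
(L, log(U−L), log η, x₁..xₙ) with an analytic Jacobian, bounds
(η ∈ [0.05, 20], x ∈ [−12, 12], gap within e^±5 of its start) and
convergence at relative cost change < 1e−8 (cap 500 evaluations).  The
curve center m is fixed at 0: concentrations are relative, which is
immaterial after row median-centering.  Initialization is deterministic:
L from the 5th intensity percentile, U just above the brightest spot, η =
1, and each x from a 1-D grid search against that initial curve — the
grid keeps saturating samples off the sigmoid's flat tails, where a
naive inversion start strands the optimizer in a degenerate basin.  A
sample needs ≥ 3 distinct dilution steps to be quantified; samples whose
spots all sit within max(3σ, 2% of the dynamic range) of an asymptote are
flagged saturated and left missing in the matrix; per-sample mean squared
error > 25× the slide average flags poor-fit (value retained).

Spatial correction estimates one linear trend per slide from two
complementary anchors, each clean for one coordinate: the row slope from
the control grid (controls share a column within each role, so per-role
demeaning isolates row) and the column slope from the mirrored triplicate
series (within a (sample, step) group the row is fixed and the three
series sit in well-separated columns).  The subtracted plane is centered
to have exactly zero mean over the slide.

## QC and normalization

- SNR(antibody) = (mean positive − mean negative control) / sd(negative),
  retained at SNR ≥ 2 (threshold configurable; antibodies without
  controls are retained unevaluated, with a warning).
- Rows are median-centered (idempotent; preserves within-row differences)
  **before** the replicate-correlation filter, so loading offsets do not
  depress correlations; the filter then keeps antibodies with Pearson
  r > 0.5 (strict) between replicate-1 and replicate-2 values across
  design cells with both replicates, computed on quantified values (not
  raw spot intensities).  Fewer than 3 matched pairs leaves the
  correlation undefined and the antibody retained with a warning.
- Variance components from the 41 replicate pairs: technical =
  mean(diff²)/2 over pairs and antibodies; effect = mean over antibodies
  of the ddof-1 variance of design-cell means minus
  technical × mean(1/n_reps per cell) — the method-of-moments correction
  that removes the replicate-averaging contribution (~0.6% at these
  scales).  At the full-pipeline level both components also absorb
  curve-inversion noise (technical ≈ 0.0065 rather than 0.0053); the
  matrix-level generator shortcut recovers the nominal scales.
- Label-swap scan: pair (i, j) is flagged when relabelling strictly
  improves both within-pair replicate correlations by > 0.1.  Swaps
  between replicates of the same design cell are indistinguishable by
  construction and are not flagged.  Detection is a report; relabelling
  requires the explicit `apply_label_swaps` config directive.

## ANOVA

Per protein: value ~ μ + cellline + medium + treatment +
medium:treatment with sum-to-zero contrasts; term tests use Type II sums
of squares (marginality-respecting model comparisons, full-model residual
mean square as denominator), appropriate for the mildly unbalanced
85-sample design and identical to Type III on balanced data.  The engine
precomputes QR factorizations of the five needed submodels from one patsy
design matrix and evaluates whole panels vectorized; proteins with
missing cells are refit on their complete rows.  Effect estimates δ are
marginal level differences from predictions on the balanced line × medium
× treatment grid (equal to raw level mean differences on balanced data);
fold change is 2^δ for δ ≥ 0, else −2^(−δ).  Replicates enter as
observations; replicate is not a model term.

Effect residuals for scoring: for the medium effect, each (cell line,
replicate) column receives the 3D − 2D difference averaged over treatment
levels after subtracting the fitted treatment and interaction
contributions (symmetrically for treatment).  Columns lacking any
complete pair (e.g. LNZ308 replicate 2, which has no 3D samples) are
missing.  Per-(column, condition) differences are kept alongside for
condition-level sum scores.

## BUM multiplicity control

f(p) = λ + (1−λ)·a·p^(a−1) on (0, 1], a ∈ (0, 1) (alternatives enriched
near zero).  Maximum likelihood by L-BFGS-B from a 5 × 5 start grid
(λ, a ∈ {0.1..0.9} × {0.05..0.95}); p-values are clamped at 1e−12 inside
the likelihood only.  The conservative null-proportion bound
π = λ + (1−λ)a (the density at p = 1) enters
FDR(τ) = π·τ / (λτ + (1−λ)τ^a), nondecreasing in τ, and the cutoff for a
target is the largest τ with FDR(τ) ≤ target, found by bisection; it is
absent when even the smallest τ exceeds the target (pure-null fits).
When most proteins carry strong signal the fitted λ approaches 0 and the
cutoff can be large — faithful BUM behavior, since the estimated null
fraction is then tiny.

## Scoring and concordance

Trichotomization thresholds are the 25%/75% linear-interpolation
quantiles of the pooled non-missing residuals of the whole
protein × column matrix per effect — pooled, not per protein, so
strongly-moving proteins dominate the tails and a protein's row can be
uniformly colored; values exactly at a threshold score 0 (strict
inequalities).  Sum scores: per column; per cell line within each level
of the other factor (condition sums, aggregating replicate columns);
averaged per line across the two condition sums; per protein.  Missing
scores contribute 0.  The majority threshold is the smallest integer
strictly greater than rule × n_available columns (6/10 glioma, 7/12
adenocarcinoma at rule 0.5; missing columns shrink the denominator).  A
lineage call requires that many columns to share a score (+1 → up, −1 →
down, 0 → neutral — neutral needs an explicit majority of zeros), else
ill-defined; the grouping map is (up,up) → both-up, (down,down) →
both-down, (neutral,neutral) → both-neutral, then a definite (up/down)
glioma call with a non-matching adenocarcinoma call → GL-specific, the
converse → AC-specific, otherwise ill-defined.  Scoring is fully
deterministic given the residual matrix.

## Reproducibility and problem sizes

The pipeline is deterministic given (config, seed); the single seed is
expanded into per-stage seeds by a fixed affine counter so stages can be
re-run in isolation.  Default problem sizes are desk-scale by design: a
40-antibody panel (the study-scale 124-label/121-target panel builder
exists for bookkeeping), 85 samples × 17 spots per slide, 8-seed
Monte-Carlo loops for variance recovery and 20-seed loops of 10,000
p-values for FDR calibration; the full chain runs in a few seconds.

## Known limitations

- The joint fit assumes a common curve across all samples of a slide;
  antibody-specific nonlinearity or saturation bias is neither simulated
  nor corrected.
- BUM's null-proportion bound is conservative under the mixture model but
  can be anti-conservative if the alternative p-value density is not
  decreasing (non-Beta alternatives).
- Lineage-specific effects are planted as lineage-restricted mean shifts;
  the ANOVA has no cellline × medium or cellline × treatment interaction
  terms, so such effects appear as attenuated main effects plus residual
  variance — intentional, as the scoring stage, not the ANOVA, is the
  instrument for lineage specificity.
- With ≤ 2 replicates per design cell, the swap scan can only flag swaps
  across design cells, and its evidence margin (0.1) trades sensitivity
  against false alarms at the 0.989 replicate-correlation operating
  point.
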