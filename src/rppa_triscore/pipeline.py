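"""End-to-end orchestration of the synthetic RPPA experiment.

simulate -> spatial correction -> joint logistic quantification -> QC /
normalization -> per-protein three-way ANOVA -> BUM multiplicity control
-> trichotomized scoring and lineage concordance -> figure-style reports.

The single pipeline seed is expanded into per-stage seeds through a
deterministic counter so individual stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anova as anova_mod
from . import bum as bum_mod
from . import preprocess as prep
from . import quantify as quant
from . import scoring as scoring_mod
from . import synth
from .config import PipelineConfig
from .design import DEFAULT_DROPPED, build_design

log = logging.getLogger("rppa_triscore")

_STAGE_OFFSETS = {"truth": 1, "render": 2}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (seed * 1009 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)
    versions: dict = field(default_factory=dict)

    def record(self, stage: str, **counts) -> None:
        log.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in counts.items()))
        self.stages.append({"stage": stage, **counts})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


@dataclass
class PipelineResult:
    manifest: RunManifest
    sheet: pd.DataFrame
    truth: synth.TruthMatrix
    spots: pd.DataFrame
    matrix: pd.DataFrame          # centered, filtered
    qc: prep.QcReport
    anova: pd.DataFrame
    bum_fits: dict[str, bum_mod.BumFit]
    scores: dict[str, scoring_mod.ScoreSet]
    calls: dict[str, pd.DataFrame]
    reports: dict[str, pd.DataFrame]


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    effect_config: synth.EffectConfig | None = None,
    curve: synth.CurveConfig | None = None,
) -> PipelineResult:
    """Run the full synthetic experiment; deterministic given (config, seed)."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    manifest = RunManifest(config=dataclasses.asdict(config), seed=seed,
                           versions={"numpy": np.__version__, "pandas": pd.__version__})
    t0 = time.time()

    sheet = build_design(5, 6, 2, DEFAULT_DROPPED)
    manifest.record("design", samples=len(sheet))

    if effect_config is not None and effect_config.protein_effects:
        eff = effect_config
        proteins = list(effect_config.protein_effects)
    else:
        proteins = [f"AB{i:03d}" for i in range(1, config.n_proteins + 1)]
        eff = effect_config or synth.default_effect_config(proteins)
    truth = synth.simulate_truth(sheet, proteins, eff, seed=stage_seed(seed, "truth"))
    manifest.record("simulate_truth", samples=len(sheet), proteins=len(proteins))

    curve = curve or synth.CurveConfig(spatial_gradient=(3.0, 1.5))
    spots = synth.render_slides(truth, curve, seed=stage_seed(seed, "render"))
    manifest.record("render", spots=len(spots))

    spots_adj, spatial = quant.correct_spatial_trend(spots)
    manifest.record("spatial_correction", slides=len(spatial))

    retained_snr, qc_snr = prep.snr_filter(spots_adj, config.snr_min)
    manifest.record("snr_filter", antibodies_in=len(proteins), antibodies_out=len(retained_snr))

    fits = {}
    for ab in retained_snr:
        fits[ab] = quant.fit_joint_logistic(spots_adj[spots_adj["antibody"] == ab])
    matrix = quant.assemble_matrix(fits, sheet)
    manifest.record("quantify", antibodies=len(fits),
                    flagged=sum(len(f.flags) for f in fits.values()))

    # center first: row medians absorb per-sample loading, which would
    # otherwise depress replicate correlations
    centered = prep.median_center_rows(matrix)
    retained_corr, qc_corr = prep.replicate_correlation_filter(centered, sheet, config.replicate_corr_min)
    centered = centered[retained_corr]
    manifest.record("replicate_filter", antibodies_out=len(retained_corr))

    swaps = prep.detect_label_swaps(centered, sheet, config.swap_margin)
    if config.apply_label_swaps:
        for a, b, _ in swaps:
            centered = prep.apply_label_swap(centered, a, b)
    tech_var, eff_var = prep.estimate_variance_components(centered, sheet)
    qc = prep.QcReport(
        antibodies_in=list(qc_snr.snr), antibodies_out=retained_corr,
        snr=qc_snr.snr, replicate_correlation=qc_corr.replicate_correlation,
        swap_candidates=swaps, technical_variance=tech_var, effect_variance=eff_var,
        notes=qc_snr.notes + qc_corr.notes,
    )
    manifest.record("preprocess", technical_variance=round(tech_var, 5),
                    effect_variance=round(eff_var, 4), swap_candidates=len(swaps))

    engine = anova_mod.AnovaEngine(sheet)
    table = engine.fit(centered)
    manifest.record("anova", proteins=len(table))

    bum_fits = {}
    for term in ("medium", "treatment", "interaction"):
        bum_fits[term] = bum_mod.fit_bum(table[f"p_{term}"].to_numpy(), config.fdr_targets)
    manifest.record("bum", terms=len(bum_fits))

    scores, calls, reports = {}, {}, {}
    for effect in ("medium", "treatment"):
        col_res, cond_res = anova_mod.effect_residuals(centered, sheet, effect)
        ss, call_df = scoring_mod.score_effect(
            col_res, cond_res, sheet, effect,
            quartiles=(config.quartile_lo, config.quartile_hi), rule=config.majority_rule,
        )
        scores[effect] = ss
        calls[effect] = call_df
        reports[effect] = scoring_mod.figure_table(table, ss, call_df, effect)
    manifest.record("scoring", effects=len(scores))
    manifest.record("done", wall_s=round(time.time() - t0, 2))

    result = PipelineResult(
        manifest=manifest, sheet=sheet, truth=truth, spots=spots_adj,
        matrix=centered, qc=qc, anova=table, bum_fits=bum_fits,
        scores=scores, calls=calls, reports=reports,
    )
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    """Write all stage outputs as TSV/JSON under ``outdir``."""
    outdir.mkdir(parents=True, exist_ok=True)
    result.sheet.to_csv(outdir / "sheet.tsv", sep="\t", index=False)
    result.matrix.to_csv(outdir / "matrix_centered.tsv", sep="\t", float_format="%.10g")
    result.anova.to_csv(outdir / "anova.tsv", sep="\t", float_format="%.10g")
    bums = {
        term: {"lam": f.lam, "a": f.a, "loglik": f.loglik, "n": f.n,
               "pi_ub": f.pi_ub, "cutoffs": {str(k): v for k, v in f.cutoffs.items()}}
        for term, f in result.bum_fits.items()
    }
    with open(outdir / "bum.json", "w") as fh:
        json.dump(bums, fh, indent=1)
    qc = result.qc
    with open(outdir / "qc.json", "w") as fh:
        json.dump({
            "snr": qc.snr, "replicate_correlation": qc.replicate_correlation,
            "swap_candidates": qc.swap_candidates,
            "technical_variance": qc.technical_variance,
            "effect_variance": qc.effect_variance,
            "notes": qc.notes,
        }, fh, indent=1, default=str)
    for effect in result.scores:
        sc = result.scores[effect].scores.copy()
        sc.columns = [f"{l}_r{r}" for l, r in sc.columns]
        sc.to_csv(outdir / f"scores_{effect}.tsv", sep="\t", float_format="%.0f")
        result.calls[effect].to_csv(outdir / f"calls_{effect}.tsv", sep="\t")
        result.reports[effect].to_csv(outdir / f"report_{effect}.tsv", sep="\t", float_format="%.6g")
    result.manifest.to_json(outdir / "manifest.json")
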