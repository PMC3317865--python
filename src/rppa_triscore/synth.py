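"""Synthetic slide generator.

Ground truth follows the additive factorial model the analysis assumes:

    x[s, p] = grand_mean + cellline(line(s), p)
              + medium_p(medium(s)) + treatment_p(treatment(s))
              + interaction_p(medium(s), treatment(s))

on the log2 concentration scale.  Exact replicates share the same design
cell and therefore the same truth value; replicate-to-replicate variation
enters only at render time as a per-(antibody, sample) perturbation on the
log2 axis with variance ``technical_sd**2`` (default 0.0053), the scale a
paired-replicate estimator recovers.  Per-protein cell-line effects are
drawn with a variance budget chosen so that the expected variance of the
44 design-cell means equals ``effect_sd**2`` (default 0.4615) for every
protein, whatever signal is planted on top.

Rendering maps truth through a shared four-parameter logistic response
curve per antibody into five 1:2 dilution steps spotted in triplicate
(middle series in normal orientation, the two flanking series reversed),
adds a linear spatial trend in grid coordinates, sample-level loading
offsets, and pooled positive / buffer negative control spots at the end of
each sample row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import LINEAGES, MEDIA, TREATMENTS
from .spots import SPOT_COLUMNS, normalize_spot_order

TECHNICAL_VARIANCE = 0.0053   # replicate-pair variance, log2 scale
EFFECT_VARIANCE = 0.4615      # design-cell-mean variance, log2 scale

POSITIVE_CONTROL_ID = "POOLED_CONTROL"
NEGATIVE_CONTROL_ID = "BUFFER"


@dataclass
class ProteinEffect:
    """Planted signal for one protein.

    ``medium`` / ``treatment`` / ``interaction`` are signed effect sizes in
    log2 units (difference between the two levels; 0 = null).  The
    ``*_lineage`` fields restrict an effect to one lineage (None = both).
    """

    medium: float = 0.0
    medium_lineage: str | None = None
    treatment: float = 0.0
    treatment_lineage: str | None = None
    interaction: float = 0.0

    def __post_init__(self) -> None:
        for lin in (self.medium_lineage, self.treatment_lineage):
            if lin is not None and lin not in LINEAGES:
                raise ValueError(f"unknown lineage {lin!r}")


@dataclass
class EffectConfig:
    """Effect structure and variance scales of the generator."""

    grand_mean: float = 1.0
    effect_sd: float = float(np.sqrt(EFFECT_VARIANCE))
    technical_sd: float = float(np.sqrt(TECHNICAL_VARIANCE))
    #: sample-level loading offset sd (log2), removed by row median-centering
    loading_sd: float = 0.15
    #: sum-to-zero level patterns scaled by each protein's effect size
    medium_effects: Mapping[str, float] = field(default_factory=lambda: {"2D": -0.5, "3D": +0.5})
    treatment_effects: Mapping[str, float] = field(
        default_factory=lambda: {"normoxia": -0.5, "hypoxia": +0.5}
    )
    interaction_effects: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("2D", "normoxia"): +0.25, ("2D", "hypoxia"): -0.25,
            ("3D", "normoxia"): -0.25, ("3D", "hypoxia"): +0.25,
        }
    )
    protein_effects: dict[str, ProteinEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.effect_sd < 0 or self.technical_sd < 0 or self.loading_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for name, pattern in (("medium_effects", self.medium_effects),
                              ("treatment_effects", self.treatment_effects),
                              ("interaction_effects", self.interaction_effects)):
            if abs(sum(pattern.values())) > 1e-9:
                raise ValueError(f"{name} must sum to zero")


@dataclass
class CurveConfig:
    """Shared logistic response curve of a slide.

    y = L + (U - L) / (1 + exp(-eta * (x - k - m))) at dilution step k.
    """

    L: float = 1000.0
    U: float = 50000.0
    eta: float = 1.0
    m: float = 0.0
    noise_sd: float = 150.0
    spatial_gradient: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.U <= self.L:
            raise ValueError("require U > L")
        if self.eta <= 0:
            raise ValueError("require eta > 0")
        if self.noise_sd < 0:
            raise ValueError("require noise_sd >= 0")


@dataclass
class TruthMatrix:
    """Samples x proteins true log2 concentrations plus provenance."""

    values: pd.DataFrame            # index sample_id, columns proteins
    sheet: pd.DataFrame
    config: EffectConfig
    cell_line_effects: pd.DataFrame  # index cell_line, columns proteins


def default_effect_config(
    proteins: Sequence[str],
    medium_size: float = 0.8,
    treatment_size: float = 0.6,
    **kwargs,
) -> EffectConfig:
    """Assign planted effect classes across a protein panel.

    Medium (3D-2D) classes, by panel position: ~21% common up, ~21% common
    down, ~8% glioma-only up, ~8% adenocarcinoma-only up, rest null.
    Treatment (hypoxia-normoxia) classes are assigned from the other end of
    the panel so the two overlays are roughly independent: ~4% common up,
    ~13% common down, ~13% glioma-only up, rest null — echoing the study's
    asymmetry (many 3D changes, fewer hypoxia changes, glioma-specific
    hypoxia increases).
    """
    n = len(proteins)
    effects = {p: ProteinEffect() for p in proteins}

    def take(fraction: float) -> int:
        return max(1, round(fraction * n)) if n else 0

    i = 0
    for count, kv in [
        (take(0.21), {"medium": +medium_size}),
        (take(0.21), {"medium": -medium_size}),
        (take(0.08), {"medium": +medium_size, "medium_lineage": "glioma"}),
        (take(0.08), {"medium": +medium_size, "medium_lineage": "adenocarcinoma"}),
    ]:
        for p in proteins[i:i + count]:
            for k, v in kv.items():
                setattr(effects[p], k, v)
        i += count

    j = n
    for count, kv in [
        (take(0.04), {"treatment": +treatment_size}),
        (take(0.13), {"treatment": -treatment_size}),
        (take(0.13), {"treatment": +treatment_size, "treatment_lineage": "glioma"}),
    ]:
        for p in proteins[max(0, j - count):j]:
            for k, v in kv.items():
                setattr(effects[p], k, v)
        j -= count

    return EffectConfig(protein_effects=effects, **kwargs)


def _structured_cells(sheet: pd.DataFrame, proteins: Sequence[str], cfg: EffectConfig) -> pd.DataFrame:
    """Deterministic (non-cell-line) truth per design cell, grand mean excluded."""
    lines = sheet[["cell_line", "lineage"]].drop_duplicates()
    cells = (
        lines.merge(pd.DataFrame({"medium": MEDIA}), how="cross")
        .merge(pd.DataFrame({"treatment": TREATMENTS}), how="cross")
    )
    unknown = set(cfg.protein_effects) - set(proteins)
    if unknown:
        raise KeyError(f"protein_effects refer to proteins not in the panel: {sorted(unknown)}")
    out = pd.DataFrame(0.0, index=cells.index, columns=list(proteins))
    for p in proteins:
        eff = cfg.protein_effects.get(p, ProteinEffect())
        v = np.zeros(len(cells))
        if eff.medium:
            mask = np.ones(len(cells), bool) if eff.medium_lineage is None else (
                cells["lineage"].to_numpy() == eff.medium_lineage
            )
            v += eff.medium * cells["medium"].map(cfg.medium_effects).to_numpy() * mask
        if eff.treatment:
            mask = np.ones(len(cells), bool) if eff.treatment_lineage is None else (
                cells["lineage"].to_numpy() == eff.treatment_lineage
            )
            v += eff.treatment * cells["treatment"].map(cfg.treatment_effects).to_numpy() * mask
        if eff.interaction:
            keys = list(zip(cells["medium"], cells["treatment"]))
            v += eff.interaction * np.array([cfg.interaction_effects[k] for k in keys])
        out[p] = v
    return pd.concat([cells.reset_index(drop=True), out.reset_index(drop=True)], axis=1)


def simulate_truth(
    sheet: pd.DataFrame,
    proteins: Sequence[str],
    cfg: EffectConfig | None = None,
    seed: int = 0,
) -> TruthMatrix:
    """Simulate true log2 concentrations under the factorial model.

    Exact replicates receive identical values; replicate variation is
    added at render time.  Per-protein cell-line effects are drawn
    N(0, s_p^2), centered, with s_p^2 set so the expected design-cell-mean
    variance equals ``cfg.effect_sd**2`` after accounting for planted
    signal (clamped at zero if the planted signal alone exceeds the
    budget).
    """
    if cfg is None:
        cfg = EffectConfig(protein_effects={p: ProteinEffect() for p in proteins})
    rng = np.random.default_rng(seed)
    cells = _structured_cells(sheet, list(proteins), cfg)
    lines = cells["cell_line"].drop_duplicates().tolist()
    n_lines = len(lines)
    n_cells = len(cells)

    struct = cells[list(proteins)].to_numpy()
    # ddof=1 variance of the structured part over design cells
    v_struct = struct.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(len(proteins))
    # line effects repeat over the 4 conditions: E[cell-mean sample variance]
    # of iid N(0, s^2) line draws is cf * s^2 with
    cf = (n_cells / max(n_cells - 1, 1)) * (1 - 1 / n_lines) if n_lines > 0 else 1.0
    budget = np.maximum(cfg.effect_sd**2 - v_struct, 0.0)
    s_line = np.sqrt(budget / cf) if cf > 0 else np.zeros_like(budget)

    cl = rng.normal(0.0, 1.0, size=(n_lines, len(proteins))) * s_line
    cl -= cl.mean(axis=0, keepdims=True)  # identifiable: sum to zero per protein
    cl_df = pd.DataFrame(cl, index=lines, columns=list(proteins))

    cell_vals = cfg.grand_mean + struct + cl_df.loc[cells["cell_line"]].to_numpy()
    cell_key = cells[["cell_line", "medium", "treatment"]]
    cell_lookup = {tuple(k): i for i, k in enumerate(cell_key.itertuples(index=False, name=None))}
    idx = [cell_lookup[(r.cell_line, r.medium, r.treatment)] for r in sheet.itertuples()]
    values = pd.DataFrame(cell_vals[idx], index=sheet["sample_id"].to_numpy(), columns=list(proteins))
    values.index.name = "sample_id"
    return TruthMatrix(values=values, sheet=sheet.reset_index(drop=True), config=cfg, cell_line_effects=cl_df)


def sample_matrix(truth: TruthMatrix, seed: int = 0) -> pd.DataFrame:
    """Matrix-level shortcut: truth plus per-(sample, protein) replicate noise.

    Equivalent in distribution to render + perfect quantification; used
    for matrix-level studies where the dilution-curve machinery is not
    under test.
    """
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, truth.config.technical_sd, size=truth.values.shape)
    return truth.values + noise


def logistic_intensity(x: np.ndarray, step: np.ndarray, curve: CurveConfig) -> np.ndarray:
    """Noise-free response of the four-parameter logistic at dilution ``step``."""
    z = curve.eta * (np.asarray(x, float) - np.asarray(step, float) - curve.m)
    return curve.L + (curve.U - curve.L) / (1.0 + np.exp(-z))


# grid layout: per antibody, sample i occupies row i; triplicate series in
# three column blocks, flanking blocks printed in reverse step order
_SERIES_COLS = {1: (0, -1), 2: (6, +1), 3: (16, -1)}  # (start col of step 0, direction)
_POS_COL, _NEG_COL = 18, 19
STEPS = np.arange(5)


def render_slides(truth: TruthMatrix, curve: CurveConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Render a truth matrix into spot-level intensities, one slide per antibody."""
    if curve is None:
        curve = CurveConfig()
    if truth.values.size == 0:
        raise ValueError("empty truth matrix")
    if curve.U <= curve.L:
        raise ValueError("require U > L")
    rng = np.random.default_rng(seed)
    samples = truth.values.index.to_numpy()
    n_s = len(samples)
    d_row, d_col = curve.spatial_gradient
    loading = rng.normal(0.0, truth.config.loading_sd, size=n_s)

    frames = []
    for p in truth.values.columns:
        x_true = truth.values[p].to_numpy() + loading
        tech = rng.normal(0.0, truth.config.technical_sd, size=n_s)
        x_eff = x_true + tech

        recs = {k: [] for k in SPOT_COLUMNS}
        for series, (c0, direction) in _SERIES_COLS.items():
            for k in STEPS:
                col = c0 + direction * int(k)
                y = logistic_intensity(x_eff, np.full(n_s, k), curve)
                y = y + d_row * np.arange(n_s) + d_col * col
                y = y + rng.normal(0.0, curve.noise_sd, size=n_s)
                recs["antibody"].append(np.full(n_s, p, dtype=object))
                recs["sample_id"].append(samples)
                recs["dilution_step"].append(np.full(n_s, k))
                recs["series"].append(np.full(n_s, series))
                recs["row"].append(np.arange(n_s))
                recs["col"].append(np.full(n_s, col))
                recs["intensity"].append(y)
                recs["role"].append(np.full(n_s, "sample", dtype=object))

        # controls appended at the end of each sample row, forming a grid
        x_pool = float(np.mean(truth.values[p].to_numpy()))
        y_pos = logistic_intensity(np.full(n_s, x_pool), np.zeros(n_s), curve)
        y_pos = y_pos + d_row * np.arange(n_s) + d_col * _POS_COL + rng.normal(0.0, curve.noise_sd, n_s)
        y_neg = curve.L + d_row * np.arange(n_s) + d_col * _NEG_COL + rng.normal(0.0, curve.noise_sd, n_s)
        for cid, colpos, y, role in (
            (POSITIVE_CONTROL_ID, _POS_COL, y_pos, "positive_control"),
            (NEGATIVE_CONTROL_ID, _NEG_COL, y_neg, "negative_control"),
        ):
            recs["antibody"].append(np.full(n_s, p, dtype=object))
            recs["sample_id"].append(np.full(n_s, cid, dtype=object))
            recs["dilution_step"].append(np.zeros(n_s, int))
            recs["series"].append(np.ones(n_s, int))
            recs["row"].append(np.arange(n_s))
            recs["col"].append(np.full(n_s, colpos))
            recs["intensity"].append(y)
            recs["role"].append(np.full(n_s, role, dtype=object))

        frames.append(pd.DataFrame({k: np.concatenate(v) for k, v in recs.items()}))

    table = pd.concat(frames, ignore_index=True)
    table["intensity"] = np.clip(table["intensity"].astype(float), 0.0, None)
    for c in ("dilution_step", "series", "row", "col"):
        table[c] = table[c].astype(int)
    return normalize_spot_order(table)
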