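"""Matrix-level QC and normalization.

Filters and diagnostics applied to the samples x antibodies log2 matrix:
a control-based signal-to-noise filter, a replicate-correlation filter
(strictly > 0.5 by default), row median-centering to remove sample
loading differences, a label-swap scan, and variance-components
estimation from exact replicate pairs.

Replicate correlations are computed on quantified log2 values (not raw
spot intensities); this choice is recorded in the QC report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class QcReport:
    """Per-filter bookkeeping emitted by the preprocessing stages."""

    antibodies_in: list[str] = field(default_factory=list)
    antibodies_out: list[str] = field(default_factory=list)
    snr: dict[str, float] = field(default_factory=dict)
    replicate_correlation: dict[str, float] = field(default_factory=dict)
    swap_candidates: list[tuple[str, str, float]] = field(default_factory=list)
    technical_variance: float | None = None
    effect_variance: float | None = None
    notes: list[str] = field(default_factory=list)


def snr_filter(spots: pd.DataFrame, snr_min: float = 2.0) -> tuple[list[str], QcReport]:
    """Retain antibodies whose control signal-to-noise ratio is >= snr_min.

    SNR(antibody) = (mean positive-control - mean negative-control)
                    / sd(negative-control).
    Antibodies without control spots cannot be evaluated and are retained
    with a warning note.
    """
    report = QcReport(notes=["snr computed on control spot intensities"])
    retained = []
    for ab, grp in spots.groupby("antibody", sort=False):
        pos = grp.loc[grp["role"] == "positive_control", "intensity"].to_numpy(float)
        neg = grp.loc[grp["role"] == "negative_control", "intensity"].to_numpy(float)
        report.antibodies_in.append(ab)
        if len(pos) == 0 or len(neg) < 2:
            warnings.warn(f"antibody {ab}: no usable control spots; retained unevaluated")
            report.snr[ab] = float("nan")
            report.notes.append(f"{ab}: unevaluable (missing controls)")
            retained.append(ab)
            continue
        sd_neg = float(np.std(neg, ddof=1))
        snr = float("inf") if sd_neg == 0 else (float(np.mean(pos)) - float(np.mean(neg))) / sd_neg
        report.snr[ab] = snr
        if snr >= snr_min:
            retained.append(ab)
    report.antibodies_out = retained
    return retained, report


def _replicate_pairs(sheet: pd.DataFrame) -> list[tuple[str, str]]:
    """Sample-id pairs occupying the same design cell (exact replicates)."""
    pairs = []
    for _, grp in sheet.groupby(["cell_line", "medium", "treatment"]):
        ids = grp.sort_values("replicate")["sample_id"].tolist()
        if len(ids) == 2:
            pairs.append((ids[0], ids[1]))
    return pairs


def replicate_correlation_filter(
    matrix: pd.DataFrame, sheet: pd.DataFrame, r_min: float = 0.5
) -> tuple[list[str], QcReport]:
    """Retain antibodies with replicate-1 vs replicate-2 Pearson r strictly > r_min.

    The correlation is over design cells having both replicates observed.
    Antibodies with fewer than 3 matched pairs are retained with a warning
    (correlation undefined).
    """
    report = QcReport(
        antibodies_in=list(matrix.columns),
        notes=["replicate correlation computed on quantified log2 values"],
    )
    pairs = _replicate_pairs(sheet)
    retained = []
    for ab in matrix.columns:
        v1, v2 = [], []
        for a, b in pairs:
            x, y = matrix.at[a, ab], matrix.at[b, ab]
            if np.isfinite(x) and np.isfinite(y):
                v1.append(x)
                v2.append(y)
        if len(v1) < 3:
            warnings.warn(f"antibody {ab}: fewer than 3 replicate pairs; correlation undefined, retained")
            report.replicate_correlation[ab] = float("nan")
            report.notes.append(f"{ab}: correlation undefined (<3 pairs)")
            retained.append(ab)
            continue
        r = float(np.corrcoef(v1, v2)[0, 1])
        report.replicate_correlation[ab] = r
        if r > r_min:
            retained.append(ab)
    report.antibodies_out = retained
    return retained, report


def median_center_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each sample (row) on its median over non-missing antibodies."""
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(f"sample(s) entirely missing: {list(matrix.index[all_missing])}")
    med = matrix.median(axis=1, skipna=True)
    return matrix.sub(med, axis=0)


def detect_label_swaps(
    matrix: pd.DataFrame, sheet: pd.DataFrame, margin: float = 0.1
) -> list[tuple[str, str, float]]:
    """Scan for pairs of samples whose labels appear exchanged.

    For samples i, j (each having an exact-replicate partner), the pair is
    flagged when relabelling i as j and j as i strictly increases both
    within-pair replicate correlations by more than ``margin``.  This is a
    QC report only; relabelling requires an explicit config directive.
    """
    partners: dict[str, str] = {}
    for a, b in _replicate_pairs(sheet):
        partners[a] = b
        partners[b] = a
    corr = matrix.T.corr()  # sample-by-sample Pearson over antibodies
    candidates = []
    ids = [s for s in matrix.index if s in partners]
    for ii, i in enumerate(ids):
        for j in ids[ii + 1:]:
            ri, rj = partners[i], partners[j]
            if j == ri:
                continue
            base_i, base_j = corr.at[i, ri], corr.at[j, rj]
            swap_i, swap_j = corr.at[j, ri], corr.at[i, rj]
            if swap_i > base_i + margin and swap_j > base_j + margin:
                evidence = float(min(swap_i - base_i, swap_j - base_j))
                candidates.append((i, j, evidence))
    candidates.sort(key=lambda t: -t[2])
    return candidates


def apply_label_swap(matrix: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    """Exchange the rows of two samples (explicit relabelling directive)."""
    out = matrix.copy()
    out.loc[a], out.loc[b] = matrix.loc[b].to_numpy(), matrix.loc[a].to_numpy()
    return out


def estimate_variance_components(
    matrix: pd.DataFrame, sheet: pd.DataFrame
) -> tuple[float, float]:
    """Estimate (technical_variance, effect_variance) on the log2 scale.

    technical: mean over antibodies and exact-replicate pairs of
    (difference^2)/2 — unbiased for the replicate-to-replicate variance.
    effect: per antibody, the ddof=1 variance over design-cell means
    (replicates averaged) minus the technical contribution of the
    averaging (technical_variance * mean(1/n_replicates per cell)), the
    method-of-moments correction that makes the estimator unbiased for
    the between-cell variance; averaged over antibodies.
    """
    pairs = _replicate_pairs(sheet)
    diffs = []
    for a, b in pairs:
        if a in matrix.index and b in matrix.index:
            d = matrix.loc[a] - matrix.loc[b]
            diffs.append(d.to_numpy(float))
    diffs = np.concatenate(diffs) if diffs else np.array([])
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size == 0:
        raise ValueError("no replicate pairs available")
    technical = float(np.mean(diffs**2) / 2.0)

    cell_of = sheet.set_index("sample_id")[["cell_line", "medium", "treatment"]]
    keys = cell_of.loc[matrix.index].apply(tuple, axis=1)
    cell_means = matrix.groupby(keys.to_numpy()).mean()
    n_per_cell = keys.value_counts()
    noise_share = float(np.mean(1.0 / n_per_cell.to_numpy()))
    effect = float(np.nanmean(cell_means.var(axis=0, ddof=1))) - technical * noise_share
    return technical, effect
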