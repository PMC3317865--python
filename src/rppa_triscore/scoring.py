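"""Trichotomized robust scores, sum scores and lineage concordance calls.

Effect residuals (one value per protein per (cell line, replicate)
column) are trichotomized against the lower/upper quartiles of the pooled
residual distribution: +1 above the upper quartile, -1 below the lower,
0 otherwise.  Pooling is across the entire protein x column matrix per
effect, so strong proteins dominate the tails; values exactly equal to a
quartile score 0 (strict inequalities).  Scores are summed by column, by
cell line within each condition, and by protein; per-lineage concordance
requires a strict majority (> 50%) of a lineage's available columns to
share a score, and the pair of lineage calls maps to one of six grouping
labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ScoreSet:
    """Trichotomized scores and their sums for one effect."""

    effect: str
    scores: pd.DataFrame                 # proteins x (cell line, replicate), {-1,0,+1,NaN}
    condition_scores: pd.DataFrame       # proteins x (cell line, replicate, condition)
    thresholds: tuple[float, float]
    column_sums: pd.Series = field(default=None)
    condition_sums: pd.Series = field(default=None)    # (cell line, condition) -> int
    averaged_sums: pd.Series = field(default=None)     # cell line -> float
    protein_sums: pd.Series = field(default=None)


def trichotomize(
    values: pd.DataFrame, quartiles: tuple[float, float] = (0.25, 0.75)
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Score values against pooled quartiles: +1 top, -1 bottom, 0 middle.

    Thresholds are linear-interpolation quantiles of the pooled
    non-missing values of the whole matrix; comparisons are strict, so
    ties with a threshold score 0.  Missing values stay missing.
    """
    pool = values.to_numpy(float).ravel()
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("all values missing; cannot trichotomize")
    lo, hi = (float(np.quantile(pool, q)) for q in quartiles)
    arr = values.to_numpy(float)
    scores = np.where(arr > hi, 1.0, np.where(arr < lo, -1.0, 0.0))
    scores = np.where(np.isfinite(arr), scores, np.nan)
    return pd.DataFrame(scores, index=values.index, columns=values.columns), (lo, hi)


def majority_threshold(n_columns: int, rule: float = 0.5) -> int:
    """Smallest integer count strictly greater than rule * n_columns."""
    if n_columns <= 0:
        raise ValueError("need at least one column")
    x = round(rule * n_columns, 9)
    return int(x) + 1 if float(x).is_integer() else math.ceil(x)


def sum_scores(scores: ScoreSet) -> ScoreSet:
    """Fill in column, condition, averaged and protein sum scores.

    Missing scores contribute 0; condition sums aggregate a cell line's
    replicate columns within each level of the other factor, and the
    averaged sum is the mean of a line's condition sums (the figure-footer
    arithmetic, e.g. (-17 + -20)/2 = -18.5).
    """
    sc = scores.scores
    scores.column_sums = sc.sum(axis=0, skipna=True).astype(int)
    scores.protein_sums = sc.sum(axis=1, skipna=True).astype(int)
    cond = scores.condition_scores
    per_col = cond.sum(axis=0, skipna=True)
    # aggregate replicates: (cell_line, replicate, condition) -> (cell_line, condition)
    scores.condition_sums = per_col.groupby(level=[0, 2]).sum().astype(int)
    scores.averaged_sums = scores.condition_sums.groupby(level=0).mean()
    return scores


def average_condition_sums(condition_sums) -> float:
    """Mean of a cell line's per-condition sum scores."""
    return float(np.mean(list(condition_sums)))


@dataclass
class ConcordanceCall:
    gl_call: str       # up / down / neutral / ill-defined / absent
    ac_call: str
    grouping: str      # both-up / both-down / both-neutral / GL-specific / AC-specific / ill-defined


_CALL_OF_SCORE = {1.0: "up", -1.0: "down", 0.0: "neutral"}


def _lineage_call(row: pd.Series, cols: list, rule: float) -> str:
    avail = row[cols].dropna() if cols else pd.Series(dtype=float)
    if len(avail) == 0:
        return "absent"
    thr = majority_threshold(len(avail), rule)
    counts = avail.value_counts()
    for score, call in _CALL_OF_SCORE.items():
        if counts.get(score, 0) >= thr:
            return call
    return "ill-defined"


def _grouping(gl: str, ac: str) -> str:
    if "absent" in (gl, ac):
        present = gl if ac == "absent" else ac
        if present in ("up", "down"):
            return f"{'GL' if ac == 'absent' else 'AC'}-specific"
        return "both-neutral" if present == "neutral" else "ill-defined"
    if gl == ac and gl in ("up", "down", "neutral"):
        return f"both-{gl}"
    if gl in ("up", "down"):
        return "GL-specific"
    if ac in ("up", "down"):
        return "AC-specific"
    return "ill-defined"


def concordance_call(
    score_row: pd.Series,
    glioma_cols: list,
    adeno_cols: list,
    rule: float = 0.5,
) -> ConcordanceCall:
    """Per-protein lineage concordance call and six-way grouping.

    Each lineage's call is up/down/neutral when at least the strict
    majority of its available (non-missing) columns share that score,
    else ill-defined; a lineage with no columns yields a degraded
    grouping based on the other lineage alone.
    """
    gl = _lineage_call(score_row, glioma_cols, rule)
    ac = _lineage_call(score_row, adeno_cols, rule)
    return ConcordanceCall(gl_call=gl, ac_call=ac, grouping=_grouping(gl, ac))


def score_effect(
    col_residuals: pd.DataFrame,
    cond_residuals: pd.DataFrame,
    sheet: pd.DataFrame,
    effect: str,
    quartiles: tuple[float, float] = (0.25, 0.75),
    rule: float = 0.5,
) -> tuple[ScoreSet, pd.DataFrame]:
    """Trichotomize one effect's residuals and derive sums and calls.

    ``col_residuals`` / ``cond_residuals`` come from
    :func:`rppa_triscore.anova.effect_residuals`.  Returns the completed
    ScoreSet and a per-protein calls DataFrame (gl_call, ac_call,
    grouping).
    """
    scores, thresholds = trichotomize(col_residuals, quartiles)
    cond_scores, _ = trichotomize(cond_residuals, quartiles)
    ss = ScoreSet(effect=effect, scores=scores, condition_scores=cond_scores, thresholds=thresholds)
    ss = sum_scores(ss)

    lineage_of = sheet.drop_duplicates("cell_line").set_index("cell_line")["lineage"]
    gl_cols = [c for c in scores.columns if lineage_of.get(c[0]) == "glioma"]
    ac_cols = [c for c in scores.columns if lineage_of.get(c[0]) == "adenocarcinoma"]
    calls = {
        p: concordance_call(scores.loc[p], gl_cols, ac_cols, rule)
        for p in scores.index
    }
    calls_df = pd.DataFrame(
        {
            "gl_call": {p: c.gl_call for p, c in calls.items()},
            "ac_call": {p: c.ac_call for p, c in calls.items()},
            "grouping": {p: c.grouping for p, c in calls.items()},
        }
    )
    calls_df.index.name = "protein"
    return ss, calls_df


def figure_table(
    anova_table: pd.DataFrame,
    score_set: ScoreSet,
    calls: pd.DataFrame,
    effect: str,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Figure-style report: significant proteins sorted by fold change.

    Rows are proteins with the effect's ANOVA p-value < ``p_max``, ordered
    by signed fold change; columns are fold change, p-value, grouping and
    the trichotomized scores per (cell line, replicate); a final
    ``sum_score`` row carries the column sums.
    """
    pcol, fcol = f"p_{effect}", f"fc_{effect}"
    keep = anova_table.index[anova_table[pcol] < p_max]
    keep = [p for p in keep if p in score_set.scores.index]
    tab = pd.DataFrame(index=keep)
    tab["fold_change"] = anova_table.loc[keep, fcol]
    tab["p_value"] = anova_table.loc[keep, pcol]
    tab["grouping"] = calls.loc[keep, "grouping"]
    sc = score_set.scores.loc[keep]
    sc.columns = [f"{line}_r{rep}" for line, rep in sc.columns]
    tab = pd.concat([tab, sc], axis=1).sort_values("fold_change", ascending=False)
    footer = pd.DataFrame(
        {c: [score_set.column_sums[(c.rsplit('_r', 1)[0], int(c.rsplit('_r', 1)[1]))]] for c in sc.columns},
        index=["sum_score"],
    )
    return pd.concat([tab, footer])
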