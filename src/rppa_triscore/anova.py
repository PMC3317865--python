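"""Per-protein three-way fixed-effects ANOVA with a treatment x medium interaction.

Model (sum-to-zero contrasts):

    value = mu + cellline + medium + treatment + medium:treatment + error

Term tests use Type II sums of squares (marginality-respecting model
comparisons, full-model residual mean square in the denominator), the
appropriate choice for the mildly unbalanced 85-sample design.  The
engine precomputes one set of design matrices per sample sheet and
evaluates all proteins vectorized; statsmodels' ``anova_lm(typ=2)`` on a
formula fit is used as an independent cross-check in the test suite.

Effect residuals: for the medium effect, each (cell line, replicate)
column gets the 3D - 2D difference averaged over treatment levels after
removing the fitted treatment and interaction contributions (and
symmetrically for treatment), which is the adjusted per-column quantity
the trichotomized scoring consumes.  Per-(column, condition) differences
are returned alongside for condition-level sum scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy import stats

from .design import MEDIA, TREATMENTS

FULL_FORMULA = (
    "C(cell_line, Sum) + C(medium, Sum) + C(treatment, Sum) "
    "+ C(medium, Sum):C(treatment, Sum)"
)
_TERMS = {
    "cellline": "C(cell_line, Sum)",
    "medium": "C(medium, Sum)",
    "treatment": "C(treatment, Sum)",
    "interaction": "C(medium, Sum):C(treatment, Sum)",
}
# Type II comparisons: (terms in reduced model, terms in augmented model)
_TYPE2 = {
    "cellline": (("medium", "treatment", "interaction"), ("cellline", "medium", "treatment", "interaction")),
    "medium": (("cellline", "treatment"), ("cellline", "treatment", "medium")),
    "treatment": (("cellline", "medium"), ("cellline", "medium", "treatment")),
    "interaction": (("cellline", "medium", "treatment"), ("cellline", "medium", "treatment", "interaction")),
}


def _check_factors(sheet: pd.DataFrame) -> None:
    for factor in ("cell_line", "medium", "treatment"):
        if sheet[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 observed levels")


class AnovaEngine:
    """Precomputed design matrices and projectors for one sample sheet."""

    def __init__(self, sheet: pd.DataFrame):
        _check_factors(sheet)
        self.sheet = sheet.reset_index(drop=True)
        df = self.sheet
        self._full = dmatrix(FULL_FORMULA, df, return_type="matrix")
        self._info = self._full.design_info
        X = np.asarray(self._full)
        self.n, self.p_full = X.shape
        if np.linalg.matrix_rank(X) < self.p_full:
            raise ValueError("rank-deficient design matrix")
        self._X = X
        self._slices = {k: self._info.term_name_slices[v] for k, v in _TERMS.items()}
        # orthonormal bases (Q) for every model involved in the Type II tests
        self._Q: dict[tuple[str, ...], np.ndarray] = {}
        self._rank: dict[tuple[str, ...], int] = {}
        needed = {terms for pair in _TYPE2.values() for terms in pair}
        needed.add(("cellline", "medium", "treatment", "interaction"))
        for terms in needed:
            cols = [0] + [i for t in terms for i in range(*self._slices[t].indices(self.p_full))]
            Xm = X[:, sorted(set(cols))]
            Q, R = np.linalg.qr(Xm)
            keep = np.abs(np.diag(R)) > 1e-10 * max(np.abs(np.diag(R)).max(), 1)
            self._Q[terms] = Q[:, keep]
            self._rank[terms] = int(keep.sum())
        self.df_resid = self.n - self._rank[("cellline", "medium", "treatment", "interaction")]

        # balanced prediction grid for marginal effect estimates
        lines = df["cell_line"].drop_duplicates().tolist()
        grid = pd.DataFrame(
            [(l, m, t) for l in lines for m in MEDIA for t in TREATMENTS],
            columns=["cell_line", "medium", "treatment"],
        )
        self._grid = grid
        self._Xg = np.asarray(build_design_matrices([self._info], grid)[0])

    def _rss(self, terms: tuple[str, ...], Y: np.ndarray) -> np.ndarray:
        Q = self._Q[terms]
        return (Y**2).sum(axis=0) - ((Q.T @ Y) ** 2).sum(axis=0)

    def fit(self, values: pd.DataFrame | pd.Series) -> pd.DataFrame:
        """Fit all proteins; returns one row per protein.

        Columns: ``p_cellline, p_medium, p_treatment, p_interaction,
        delta_medium, delta_treatment, fc_medium, fc_treatment``.
        Proteins with missing samples are refit on their complete rows.
        """
        if isinstance(values, pd.Series):
            values = values.to_frame()
        values = values.loc[self.sheet["sample_id"]]
        Y = values.to_numpy(float)
        complete = np.isfinite(Y).all(axis=0)
        rows = []
        index = []
        if complete.any():
            rows.append(self._fit_block(Y[:, complete]))
            index.extend(values.columns[complete])
        for j in np.flatnonzero(~complete):
            mask = np.isfinite(Y[:, j])
            sub = AnovaEngine(self.sheet[mask])
            rows.append(sub._fit_block(Y[mask][:, [j]]))
            index.append(values.columns[j])
        out = pd.concat(rows, ignore_index=True)
        out.index = pd.Index(index, name="protein")
        return out.loc[values.columns]

    def _fit_block(self, Y: np.ndarray) -> pd.DataFrame:
        full_terms = ("cellline", "medium", "treatment", "interaction")
        rss_full = self._rss(full_terms, Y)
        mse = rss_full / self.df_resid
        res: dict[str, np.ndarray] = {}
        for term, (red, aug) in _TYPE2.items():
            df_t = self._rank[aug] - self._rank[red]
            ss = self._rss(red, Y) - self._rss(aug, Y)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = (ss / df_t) / mse
            p = stats.f.sf(F, df_t, self.df_resid)
            # perfect fits (mse == 0) with positive term SS are maximally significant
            p = np.where((mse <= 0) & (ss > 1e-12), 0.0, p)
            p = np.where((mse <= 0) & (ss <= 1e-12), 1.0, p)
            res[f"F_{term}"] = F
            res[f"p_{term}"] = p

        beta, *_ = np.linalg.lstsq(self._X, Y, rcond=None)
        pred = self._Xg @ beta
        is3d = (self._grid["medium"] == "3D").to_numpy()
        ishx = (self._grid["treatment"] == "hypoxia").to_numpy()
        res["delta_medium"] = pred[is3d].mean(axis=0) - pred[~is3d].mean(axis=0)
        res["delta_treatment"] = pred[ishx].mean(axis=0) - pred[~ishx].mean(axis=0)
        res["fc_medium"] = fold_change(res["delta_medium"])
        res["fc_treatment"] = fold_change(res["delta_treatment"])
        return pd.DataFrame(res)

    def term_contribution(self, values: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
        """Fitted contribution of the named terms, per observation x protein.

        Proteins with missing samples are fit on their complete rows; the
        contribution is still evaluated for every observation row.
        """
        values = values.loc[self.sheet["sample_id"]]
        Y = values.to_numpy(float)
        contrib = np.zeros_like(Y)
        complete = np.isfinite(Y).all(axis=0)

        def add(X_fit, Y_fit, X_eval, out):
            beta, *_ = np.linalg.lstsq(X_fit, Y_fit, rcond=None)
            for t in terms:
                sl = self._slices[t]
                out += X_eval[:, sl] @ beta[sl]

        if complete.any():
            block = np.zeros((self.n, int(complete.sum())))
            add(self._X, Y[:, complete], self._X, block)
            contrib[:, complete] = block
        for j in np.flatnonzero(~complete):
            mask = np.isfinite(Y[:, j])
            block = np.zeros((self.n, 1))
            add(self._X[mask], Y[mask, j:j + 1], self._X, block)
            contrib[:, j:j + 1] = block
        return contrib


def fit_three_way_anova(values: pd.Series | pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Convenience wrapper: build an engine for ``sheet`` and fit ``values``."""
    return AnovaEngine(sheet).fit(values)


def fold_change(delta) -> np.ndarray | float:
    """Signed fold change: 2**delta for delta >= 0, -2**(-delta) otherwise."""
    arr = np.asarray(delta, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite effect estimate")
    fc = np.where(arr >= 0, np.exp2(arr), -np.exp2(-arr))
    return float(fc) if np.isscalar(delta) or arr.ndim == 0 else fc


def effect_residuals(
    values: pd.DataFrame, sheet: pd.DataFrame, effect: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjusted per-column level differences for one effect.

    For ``effect='medium'``: per (cell line, replicate) column, the
    (3D - 2D) difference averaged over treatment levels, after removing
    the fitted treatment and interaction contributions; symmetric for
    ``effect='treatment'`` (hypoxia - normoxia, averaged over media with
    medium and interaction removed).

    Returns
    -------
    (column_residuals, condition_residuals)
        ``column_residuals``: proteins x (cell line, replicate) columns;
        ``condition_residuals``: proteins x (cell line, replicate,
        other-factor level) columns.  Columns lacking a complete pair are
        missing (with a warning).
    """
    if effect not in ("medium", "treatment"):
        raise ValueError("effect must be 'medium' or 'treatment'")
    engine = AnovaEngine(sheet)
    values = values.loc[sheet["sample_id"]]
    remove = ("treatment", "interaction") if effect == "medium" else ("medium", "interaction")
    adj = values.to_numpy(float) - engine.term_contribution(values, remove)
    adj = pd.DataFrame(adj, index=sheet["sample_id"], columns=values.columns)

    factor, other = ("medium", "treatment") if effect == "medium" else ("treatment", "medium")
    hi, lo = ("3D", "2D") if effect == "medium" else ("hypoxia", "normoxia")
    other_levels = TREATMENTS if effect == "medium" else MEDIA

    meta = sheet.set_index("sample_id")
    cond_cols: dict[tuple[str, int, str], pd.Series] = {}
    for (line, rep), grp in sheet.groupby(["cell_line", "replicate"]):
        for lev in other_levels:
            sub = grp[grp[other] == lev]
            hi_ids = sub.loc[sub[factor] == hi, "sample_id"].tolist()
            lo_ids = sub.loc[sub[factor] == lo, "sample_id"].tolist()
            if hi_ids and lo_ids:
                cond_cols[(line, int(rep), lev)] = adj.loc[hi_ids[0]] - adj.loc[lo_ids[0]]

    cond = pd.DataFrame(cond_cols)
    cond.columns = pd.MultiIndex.from_tuples(cond.columns, names=["cell_line", "replicate", other])

    col_keys = sorted({(l, r) for l, r in zip(sheet["cell_line"], sheet["replicate"])})
    cols = {}
    for line, rep in col_keys:
        if (line, rep) in {(l, r) for l, r, _ in cond_cols}:
            sub = cond.loc[:, (line, rep)]
            cols[(line, int(rep))] = sub.mean(axis=1)
        else:
            warnings.warn(f"column ({line}, replicate {rep}): no complete {effect} pair; missing")
            cols[(line, int(rep))] = pd.Series(np.nan, index=values.columns)
    col_res = pd.DataFrame(cols)
    col_res.columns = pd.MultiIndex.from_tuples(col_res.columns, names=["cell_line", "replicate"])
    return col_res, cond
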