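"""Joint four-parameter logistic quantification of dilution series.

One shared response curve per antibody (slide) is fit jointly with one
log2 concentration offset per sample:

    y_spot = L + (U - L) / (1 + exp(-eta * (x_s - k))) + noise

where k is the dilution step (1:2 steps, -1 per step on the log2 axis).
The curve center m is fixed at 0, so concentrations are relative to the
curve center; downstream analysis row-median-centers the matrix, making
the absolute anchor immaterial.  Optimization is full nonlinear least
squares over (L, log(U-L), log eta, x_1..x_n) with an analytic Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

MIN_STEPS_PER_SAMPLE = 3


@dataclass
class JointFit:
    """Result of a joint logistic fit for one antibody."""

    L: float
    U: float
    eta: float
    m: float
    x_hat: dict[str, float]
    rss: float
    converged: bool
    flags: dict[str, list[str]] = field(default_factory=dict)
    n_iter: int = 0

    @property
    def quantified(self) -> dict[str, float]:
        """x_hat restricted to samples without a saturation flag."""
        return {
            s: v
            for s, v in self.x_hat.items()
            if not any(f.startswith("saturated") for f in self.flags.get(s, []))
        }


def correct_spatial_trend(spots: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Subtract a least-squares linear intensity trend in (row, col) per slide.

    The two slopes are estimated from complementary anchors that each
    isolate one coordinate: the row slope from the control-spot grid
    (controls share a column within each role, so after removing the
    per-role means the regression on row is clean), and the column slope
    from the mirrored triplicate series (within a (sample, step) group
    the row is fixed while the three series sit in well-separated
    columns).  Either estimator falls back to the other anchor set when
    its own is degenerate; if neither coordinate is estimable the slide
    is returned unchanged with a warning.  The adjustment is centered so
    its mean over the slide's spots is exactly zero.

    Returns the adjusted table and a per-antibody diagnostic dict with
    the fitted ``(d_row, d_col)`` slopes.
    """
    out = spots.copy()
    diags: dict[str, tuple[float, float]] = {}
    for ab, grp in spots.groupby("antibody", sort=False):
        ctrl = grp[grp["role"] != "sample"]
        smp = grp[grp["role"] == "sample"]
        ctrl_groups = ctrl["role"].to_numpy() if len(ctrl) else None
        smp_groups = (
            smp["sample_id"].astype(str) + "|" + smp["dilution_step"].astype(str)
        ).to_numpy() if len(smp) else None

        def slope(coord: str):
            for frame, groups in ((ctrl, ctrl_groups), (smp, smp_groups)):
                if len(frame) >= 3:
                    s = _demeaned_slope(
                        frame["intensity"].to_numpy(float),
                        frame[coord].to_numpy(float),
                        groups,
                    )
                    if s is not None:
                        return s
            return None

        d_row, d_col = slope("row"), slope("col")
        if d_row is None and d_col is None:
            warnings.warn(f"antibody {ab}: too few anchor spots for spatial correction; left unchanged")
            diags[ab] = (0.0, 0.0)
            continue
        d_row = d_row or 0.0
        d_col = d_col or 0.0
        idx = grp.index
        adj = d_row * (grp["row"] - grp["row"].mean()) + d_col * (grp["col"] - grp["col"].mean())
        out.loc[idx, "intensity"] = grp["intensity"] - adj
        diags[ab] = (float(d_row), float(d_col))
    return out, diags


def _demeaned_slope(y, v, groups):
    """Slope of y on v after removing per-group means from both; None if degenerate."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if groups is None:
        ym, vm = y - y.mean(), v - v.mean()
    else:
        df = pd.DataFrame({"y": y, "v": v, "g": groups})
        ym = (df["y"] - df.groupby("g")["y"].transform("mean")).to_numpy()
        vm = (df["v"] - df.groupby("g")["v"].transform("mean")).to_numpy()
    denom = float(vm @ vm)
    if denom < 1e-9:
        return None
    return float(vm @ ym / denom)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def fit_joint_logistic(
    spots: pd.DataFrame,
    ftol: float = 1e-8,
    max_nfev: int = 500,
) -> JointFit:
    """Fit the joint logistic model to one antibody's sample spots.

    Requires at least 2 samples; samples with fewer than 3 distinct
    dilution steps are excluded from quantification (flagged
    ``too-few-steps``).  Initialization: L and U from the 5th/95th
    intensity percentiles, eta = 1, x from inverting the logistic at each
    sample's median step-0 intensity.

    Raises
    ------
    ValueError
        On fewer than 2 quantifiable samples or an all-saturated slide
        (no intensity spread between asymptote candidates).
    """
    smp = spots[spots["role"] == "sample"]
    if smp["antibody"].nunique() > 1:
        raise ValueError("fit_joint_logistic expects spots from a single antibody")
    flags: dict[str, list[str]] = {}
    by_sample = {s: g for s, g in smp.groupby("sample_id", sort=False)}
    usable = {}
    for s, g in by_sample.items():
        if g["dilution_step"].nunique() >= MIN_STEPS_PER_SAMPLE:
            usable[s] = g
        else:
            flags.setdefault(str(s), []).append("too-few-steps")
    if len(usable) < 2:
        raise ValueError("need at least 2 samples with >= 3 distinct dilution steps")

    names = list(usable)
    y_all = np.concatenate([usable[s]["intensity"].to_numpy(float) for s in names])
    k_all = np.concatenate([usable[s]["dilution_step"].to_numpy(float) for s in names])
    s_idx = np.concatenate([np.full(len(usable[s]), i) for i, s in enumerate(names)])

    L0 = float(np.percentile(y_all, 5))
    y_hi = float(y_all.max())
    if y_hi - L0 <= max(1e-9, 1e-6 * max(abs(y_hi), 1.0)):
        raise ValueError("no intensity spread: all samples saturated")
    # upper asymptote starts slightly above the brightest spot (few slides saturate)
    U0 = y_hi + 0.05 * (y_hi - L0)
    gap0 = U0 - L0
    # robust per-sample start: 1-D grid against the initial curve keeps every
    # sample inside the sigmoid's informative range
    x_grid = np.linspace(-8.0, 8.0, 81)
    x0 = np.empty(len(names))
    for i, s in enumerate(names):
        g = usable[s]
        yk = g["intensity"].to_numpy(float)
        kk = g["dilution_step"].to_numpy(float)
        pred = L0 + gap0 * _logistic(x_grid[:, None] - kk[None, :])
        x0[i] = x_grid[int(np.argmin(((pred - yk[None, :]) ** 2).sum(axis=1)))]

    def unpack(p):
        L, loggap, logeta = p[0], p[1], p[2]
        return L, np.exp(loggap), np.exp(logeta), p[3:]

    def residuals(p):
        L, gap, eta, x = unpack(p)
        z = eta * (x[s_idx] - k_all)
        return L + gap * _logistic(z) - y_all

    def jac(p):
        L, gap, eta, x = unpack(p)
        z = eta * (x[s_idx] - k_all)
        sig = _logistic(z)
        dsig = sig * (1 - sig)
        J = np.zeros((len(y_all), 3 + len(names)))
        J[:, 0] = 1.0
        J[:, 1] = gap * sig
        J[:, 2] = gap * dsig * z  # d/d(log eta)
        J[np.arange(len(y_all)), 3 + s_idx] = gap * dsig * eta
        return J

    p0 = np.concatenate([[L0, np.log(gap0), 0.0], x0])
    # bounds keep the optimizer out of the degenerate step-function basin
    lb = np.concatenate([[-np.inf, np.log(gap0) - 5, np.log(0.05)], np.full(len(names), -12.0)])
    ub = np.concatenate([[np.inf, np.log(gap0) + 5, np.log(20.0)], np.full(len(names), 12.0)])
    res = least_squares(residuals, p0, jac=jac, method="trf", bounds=(lb, ub),
                        ftol=ftol, xtol=1e-12, gtol=1e-12, max_nfev=max_nfev)
    L, gap, eta, x = unpack(res.x)
    U = L + gap
    rss = float(2 * res.cost)
    dof = max(len(y_all) - len(res.x), 1)
    sigma = float(np.sqrt(rss / dof))
    overall_mse = rss / len(y_all)

    thr = max(3 * sigma, 0.02 * gap)
    resid_final = residuals(res.x)
    for i, s in enumerate(names):
        ys = y_all[s_idx == i]
        fl = flags.setdefault(str(s), [])
        if ys.max() < L + thr:
            fl.append("saturated-low")
        elif ys.min() > U - thr:
            fl.append("saturated-high")
        mse_s = float(np.mean((resid_final[s_idx == i]) ** 2))
        if overall_mse > 0 and mse_s > 25 * overall_mse:
            fl.append("poor-fit")
    flags = {s: f for s, f in flags.items() if f}
    if all(any(f.startswith("saturated") for f in flags.get(str(s), [])) for s in names):
        raise ValueError("all samples saturated")

    return JointFit(
        L=float(L), U=float(U), eta=float(eta), m=0.0,
        x_hat={str(s): float(x[i]) for i, s in enumerate(names)},
        rss=rss, converged=bool(res.status > 0), flags=flags, n_iter=int(res.nfev),
    )


def assemble_matrix(fits: dict[str, JointFit], sheet: pd.DataFrame) -> pd.DataFrame:
    """Assemble per-antibody fits into a samples x antibodies log2 matrix.

    Saturated samples are left missing (NaN).  Raises ``KeyError`` if a
    fit quantifies a sample absent from the sheet, ``ValueError`` on an
    empty fits mapping.
    """
    if not fits:
        raise ValueError("no fits to assemble")
    samples = sheet["sample_id"].tolist()
    known = set(samples)
    mat = pd.DataFrame(np.nan, index=samples, columns=list(fits))
    mat.index.name = "sample_id"
    for ab, fit in fits.items():
        for s, v in fit.quantified.items():
            if s not in known:
                raise KeyError(f"antibody {ab}: sample {s!r} not in sample sheet")
            mat.loc[s, ab] = v
    return mat
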