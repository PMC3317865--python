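"""Beta-uniform mixture (BUM) modelling of p-value distributions.

The density on (0, 1] is

    f(p) = lam + (1 - lam) * a * p**(a - 1),      0 < a < 1, 0 <= lam <= 1,

a mixture of a uniform null component and a Beta(a, 1) alternative
enriched near zero.  The conservative null-proportion upper bound is
pi_ub = lam + (1 - lam) * a (the density's value at p = 1), and the
estimated FDR of calling p <= tau significant is

    FDRhat(tau) = pi_ub * tau / F(tau),   F(tau) = lam*tau + (1-lam)*tau**a.

``fdr_cutoff`` returns the largest tau with FDRhat(tau) <= target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

P_FLOOR = 1e-12


@dataclass
class BumFit:
    """Maximum-likelihood BUM fit."""

    lam: float
    a: float
    loglik: float
    n: int
    cutoffs: dict[float, float | None] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def pi_ub(self) -> float:
        """Conservative upper bound on the null proportion."""
        return self.lam + (1.0 - self.lam) * self.a


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() <= 0 - P_FLOOR or p.max() > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return np.clip(p, P_FLOOR, 1.0)


def bum_density(p, lam: float, a: float):
    """Mixture density lam + (1-lam)*a*p**(a-1) on (0, 1] (no clamping)."""
    p = np.asarray(p, dtype=float)
    return lam + (1.0 - lam) * a * p ** (a - 1.0)


def bum_loglik(p, lam: float, a: float) -> float:
    """Sum of log f(p_i); p clamped at 1e-12 to protect the likelihood."""
    if not (0.0 <= lam <= 1.0) or not (0.0 < a < 1.0):
        raise ValueError("require lam in [0,1] and a in (0,1)")
    p = _check_p(np.asarray(p))
    return float(np.sum(np.log(bum_density(p, lam, a))))


def fit_bum(p, fdr_targets=()) -> BumFit:
    """Fit (lam, a) by bounded maximum likelihood with a multi-start grid.

    Starts on lam in {0.1..0.9} x a in {0.05..0.95}; each start is refined
    with L-BFGS-B and the best refined optimum is returned.  Requires at
    least 10 p-values; an all-equal degenerate input yields a boundary fit
    with a warning note.
    """
    p = _check_p(np.asarray(p))
    if p.size < 10:
        raise ValueError("need at least 10 p-values to fit a BUM model")
    notes = []
    if np.ptp(p) == 0:
        warnings.warn("degenerate all-equal p-values; boundary BUM fit")
        notes.append("degenerate input: all p-values equal")
    if (np.asarray(p) <= P_FLOOR).any():
        notes.append(f"p-values clamped at floor {P_FLOOR}")

    logp = np.log(p)

    def nll(theta):
        lam, a = theta
        dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
        return -np.sum(np.log(np.maximum(dens, 1e-300)))

    eps = 1e-9
    bounds = [(0.0, 1.0), (eps, 1.0 - eps)]
    best = None
    for lam0 in np.linspace(0.1, 0.9, 5):
        for a0 in np.linspace(0.05, 0.95, 5):
            res = minimize(nll, x0=[lam0, a0], method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    lam, a = float(best.x[0]), float(best.x[1])
    fit = BumFit(lam=lam, a=a, loglik=float(-best.fun), n=int(p.size), notes=notes)
    for target in fdr_targets:
        fit.cutoffs[target] = fdr_cutoff(fit, target)
    return fit


def fdr_estimate(fit: BumFit, tau) -> np.ndarray:
    """FDRhat(tau) = pi_ub * tau / (lam*tau + (1-lam)*tau**a)."""
    tau = np.asarray(tau, dtype=float)
    F = fit.lam * tau + (1.0 - fit.lam) * tau**fit.a
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(F > 0, fit.pi_ub * tau / F, np.nan)


def fdr_cutoff(fit: BumFit, target: float) -> float | None:
    """Largest tau in (0, 1] with FDRhat(tau) <= target (None if unattainable).

    FDRhat is nondecreasing in tau for a < 1, so the cutoff is found by
    monotone bisection down to the p-value floor.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target FDR must lie in (0, 1)")
    lo, hi = P_FLOOR, 1.0
    if fdr_estimate(fit, lo) > target:
        return None
    if fdr_estimate(fit, hi) <= target:
        return 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if fdr_estimate(fit, mid) <= target:
            lo = mid
        else:
            hi = mid
    return float(lo)


def plot_bum_fit(fit: BumFit, p, path, bins: int = 50, title: str | None = None) -> None:
    """Histogram of p-values with the fitted BUM density overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = _check_p(np.asarray(p))
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.hist(p, bins=bins, range=(0, 1), density=True, color="0.8", edgecolor="0.5")
    grid = np.linspace(1e-4, 1, 500)
    ax.plot(grid, bum_density(grid, fit.lam, fit.a), "r-", lw=1.5,
            label=f"BUM lam={fit.lam:.2f}, a={fit.a:.2f}")
    ax.set_xlabel("p-value")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
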