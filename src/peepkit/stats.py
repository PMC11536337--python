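"""Authored statistical primitives: Welch's t, weighted Holm, Poisson GLM.

These are implemented from their defining formulas rather than delegated to a
library, because they are part of the analysis contract of this package and
are cross-checked against independent oracles in the test suite.  Linear and
generalized linear *mixed* models live in :mod:`peepkit.mixed`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = ["FitResult", "welch_t", "holm_adjust", "fit_poisson_glm",
           "poisson_loglik", "mating_success_design", "evidence_label",
           "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge (or diverged)."""


@dataclass
class FitResult:
    """Coefficients, standard errors, tests and diagnostics of one model fit."""

    model: str
    names: List[str]
    estimates: np.ndarray
    se: np.ndarray
    statistic: np.ndarray
    stat_name: str  # "z", "t" or "chi2"
    pvalues: np.ndarray
    df: Optional[np.ndarray] = None
    loglik: float = float("nan")
    cov: Optional[np.ndarray] = None
    random_variances: Dict[str, float] = field(default_factory=dict)
    converged: bool = True
    boundary: bool = False
    extra: Dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "term": self.names,
            "estimate": self.estimates,
            "se": self.se,
            self.stat_name: self.statistic,
            "p": self.pvalues,
        })
        if self.df is not None:
            out["df"] = self.df
        out["evidence"] = [evidence_label(p) for p in self.pvalues]
        return out


def evidence_label(p: float) -> str:
    """Descriptive evidence bands attached to outputs (never used for
    decisions): >0.1 none, 0.05-0.1 weak, 0.01-0.05 moderate, 0.001-0.01
    strong, <0.001 very strong."""
    if not np.isfinite(p):
        return ""
    if p > 0.1:
        return "no evidence"
    if p > 0.05:
        return "weak"
    if p > 0.01:
        return "moderate"
    if p > 0.001:
        return "strong"
    return "very strong"


def welch_t(x: Sequence[float], y: Sequence[float]):
    """Welch's unequal-variance t-test, from the formula.

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny), with Welch-Satterthwaite
    degrees of freedom; two-sided p from the t distribution.  Returns
    ``(t, df, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    s2x = x.var(ddof=1)
    s2y = y.var(ddof=1)
    vx, vy = s2x / nx, s2y / ny
    denom = vx + vy
    if denom == 0:
        if x.mean() == y.mean():
            return 0.0, float(nx + ny - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t = (x.mean() - y.mean()) / math.sqrt(denom)
    # scale by the larger variance term before squaring (underflow-safe)
    m = max(vx, vy)
    ux, uy = vx / m, vy / m
    df = (ux + uy) ** 2 / (ux ** 2 / (nx - 1) + uy ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def holm_adjust(pvalues: Sequence[float],
                weights: Optional[Sequence[float]] = None) -> np.ndarray:
    """Weighted Holm-Bonferroni step-down adjusted p-values.

    Hypotheses are ordered by p_i/w_i; at step j the multiplier is
    sum(w_k, k still in play)/w_(j), and adjusted p-values are the running
    maximum of the stepwise products, capped at 1.  Equal weights reduce to
    classical Holm.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        w = w / w.sum()
    order = np.argsort(p / w, kind="stable")
    adj = np.empty(m)
    remaining = 1.0  # sum of weights not yet stepped past (weights sum to 1)
    running = 0.0
    for j in order:
        running = max(running, p[j] * remaining / w[j])
        adj[j] = min(running, 1.0)
        remaining -= w[j]
    return adj


def poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Poisson log-likelihood with log link (includes the log y! constant)."""
    y = np.asarray(y, dtype=float)
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def fit_poisson_glm(X: np.ndarray, y: np.ndarray,
                    names: Optional[List[str]] = None,
                    tol: float = 1e-8, max_iter: int = 50) -> FitResult:
    """Poisson regression (log link) by iteratively reweighted least squares.

    Convergence when the largest coefficient change drops below ``tol``.
    Wald z statistics from the expected-information covariance
    ``(X' W X)^{-1}`` at the optimum.  Raises :class:`ConvergenceError` on
    non-convergence or separation-like divergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    ptp = X.max(axis=0) - X.min(axis=0)
    const_cols = [names[j] for j in range(p) if ptp[j] == 0 and j > 0]
    if const_cols:
        raise ValueError(f"constant predictor(s): {const_cols}")
    beta = np.zeros(p)
    beta[0] = math.log(max(y.mean(), 1e-12)) if ptp[0] == 0 else 0.0
    for _ in range(max_iter):
        eta = X @ beta
        if np.any(np.abs(eta) > 40):
            raise ConvergenceError(
                "diverging linear predictor (separation-like geometry)")
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / mu
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular weighted design: {exc}") from exc
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            break
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    eta = X @ beta
    mu = np.exp(eta)
    cov = np.linalg.inv((X.T * mu) @ X)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(zstat))
    return FitResult(model="poisson_glm", names=list(names), estimates=beta,
                     se=se, statistic=zstat, stat_name="z", pvalues=pvals,
                     loglik=poisson_loglik(y, eta), cov=cov)


#: predictor preset for the total-mating-success model: body size plus the
#: per-male mean call parameters CD, ICI, T95, PF and FR
MATING_SUCCESS_TERMS = ("body_size_mm", "cd_s", "ici_s", "t95_pct",
                        "pf_hz", "fr_hz")


def mating_success_design(summaries: pd.DataFrame,
                          terms: Sequence[str] = MATING_SUCCESS_TERMS):
    """Design matrix and response for the total-mating-success Poisson GLM."""
    X = np.column_stack([np.ones(len(summaries))]
                        + [summaries[t].to_numpy(dtype=float) for t in terms])
    y = summaries["total_clutches"].to_numpy(dtype=float)
    return X, y, ["intercept", *terms]
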