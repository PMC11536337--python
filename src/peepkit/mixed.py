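"""Mixed-effects models: REML linear mixed models and an AGQ logistic GLMM.

Both fitters are implemented here from the marginal-likelihood formulas.

Linear mixed models
-------------------
``y = X b + sum_k Z_k u_k + e`` with independent random intercepts
``u_k ~ N(0, s2_k I)`` and ``e ~ N(0, s2_e I)``.  The REML criterion is
profiled over ``s2_e`` and the variance *ratios* ``g_k = s2_k / s2_e`` are
optimized on the log scale; all matrix work goes through the Woodbury
identity, so the cost scales with the (small) number of random-effect levels
rather than the number of calls.  A ratio collapsing to ~0 is reported as a
boundary fit, not an error.

Logistic GLMM
-------------
Random-intercept logit model fitted by maximizing the marginal likelihood,
with each cluster's integral evaluated by adaptive Gauss-Hermite quadrature
(nodes recentred at the cluster's posterior mode and rescaled by its
curvature; 1 node = the Laplace approximation).  Standard errors come from
the numerical Hessian of the marginal log-likelihood.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import roots_hermite

from .stats import ConvergenceError, FitResult

__all__ = ["fit_lmm", "descriptive_means", "emm_pairwise_tukey",
           "fit_logistic_glmm", "reml_variance_components"]


# ---------------------------------------------------------------------------
# REML variance components via Woodbury
# ---------------------------------------------------------------------------

def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def reml_variance_components(y: np.ndarray, X: np.ndarray,
                             factors: Dict[str, np.ndarray],
                             names: Optional[List[str]] = None,
                             model: str = "lmm") -> FitResult:
    """REML fit of a linear mixed model with random-intercept factors.

    ``factors`` maps factor name -> label array (one label per row).  Returns
    a :class:`FitResult` whose ``random_variances`` holds the estimated
    variance components (including ``"residual"``); ``extra["cov"]`` is the
    fixed-effect covariance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    fac_names = list(factors)
    Zs = []
    sizes = []
    for f in fac_names:
        codes, uniq = pd.factorize(np.asarray(factors[f]))
        Zs.append(_indicator(codes, uniq.size))
        sizes.append(uniq.size)
    Z = np.hstack(Zs) if Zs else np.zeros((n, 0))
    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    m = Z.shape[1]
    blocks = np.repeat(np.arange(len(sizes)), sizes) if sizes else np.array([])

    def _solve(log_gamma: np.ndarray):
        """Profiled REML pieces for variance ratios exp(log_gamma)."""
        gam = np.exp(np.clip(log_gamma, -30.0, 30.0))
        g = gam[blocks] if m else np.array([])
        sq = np.sqrt(g)
        A = np.eye(m) + (sq[:, None] * ZtZ * sq[None, :])
        cA = np.linalg.cholesky(A)
        logdet_W = 2.0 * float(np.log(np.diag(cA)).sum())
        # W^{-1}M = M - Z G^{1/2} A^{-1} G^{1/2} Z' M  for M in {X, y}
        UtX = sq[:, None] * ZtX
        Uty = sq * Zty
        AiUtX = np.linalg.solve(A, UtX) if m else UtX
        AiUty = np.linalg.solve(A, Uty) if m else Uty
        XtWiX = XtX - UtX.T @ AiUtX
        XtWiy = Xty - UtX.T @ AiUty
        ytWiy = yty - float(Uty @ AiUty)
        beta = np.linalg.solve(XtWiX, XtWiy)
        rss = ytWiy - float(beta @ XtWiy)  # r' W^{-1} r at GLS beta
        rss = max(rss, 1e-300)
        sigma2 = rss / (n - p)
        sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
        crit = (n - p) * math.log(sigma2) + logdet_W + logdet_XtWiX
        return crit, beta, sigma2, XtWiX, gam

    if m:
        x0 = np.zeros(len(sizes))
        res = optimize.minimize(lambda t: _solve(t)[0], x0,
                                method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-10,
                                         "maxiter": 2000})
        if not res.success and not np.isfinite(res.fun):
            raise ConvergenceError("REML optimization failed")
        theta = res.x
    else:
        theta = np.zeros(0)
    crit, beta, sigma2, XtWiX, gam = _solve(theta)
    cov = sigma2 * np.linalg.inv(XtWiX)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    resid_df = n - p - sum(sizes)
    pvals = 2.0 * sps.t.sf(np.abs(tstat), max(resid_df, 1))
    loglik = -0.5 * (crit + (n - p) * (1.0 + math.log(2.0 * math.pi)))
    rvar = {f: float(gam[i] * sigma2) for i, f in enumerate(fac_names)}
    rvar["residual"] = float(sigma2)
    boundary = bool(np.any(gam < 1e-6))
    return FitResult(model=model, names=list(names), estimates=beta, se=se,
                     statistic=tstat, stat_name="t", pvalues=pvals,
                     df=np.full(p, float(max(resid_df, 1))),
                     loglik=loglik, cov=cov, random_variances=rvar,
                     boundary=boundary,
                     extra={"n": n, "factor_sizes": dict(zip(fac_names, sizes))})


# ---------------------------------------------------------------------------
# Call-parameter LMM (condition + temperature + rainfall | male)
# ---------------------------------------------------------------------------

def _lmm_design(calls: pd.DataFrame, response: str, reference: str,
                covariates: Sequence[str]):
    df = calls.dropna(subset=[response]).copy()
    levels = sorted(df["condition"].unique())
    if reference in levels:
        levels = [reference] + [l for l in levels if l != reference]
    cols = [np.ones(len(df))]
    names = ["intercept"]
    cond_idx = []
    for lev in levels[1:]:
        cols.append((df["condition"] == lev).to_numpy(dtype=float))
        names.append(f"condition[{lev}]")
        cond_idx.append(len(names) - 1)
    cov_means = {}
    for c in covariates:
        if c not in df.columns or df[c].isna().all():
            continue
        v = df[c].astype(float).to_numpy()
        cols.append(v)
        names.append(c)
        cov_means[c] = float(np.nanmean(v))
    X = np.column_stack(cols)
    return df, X, names, levels, cond_idx, cov_means


def fit_lmm(calls: pd.DataFrame, response: str, reference: str = "brooding",
            covariates: Sequence[str] = ("temperature_c", "rainfall"),
            group: str = "male_id") -> FitResult:
    """Per-parameter linear mixed model: condition + covariates, male random.

    Treatment coding with ``reference`` (default brooding) as the baseline.
    ``extra["wald_terms"]`` carries per-term Wald chi-square tests (2 df for
    the 3-level condition); ``extra`` also stores what
    :func:`emm_pairwise_tukey` needs.
    """
    df, X, names, levels, cond_idx, cov_means = _lmm_design(
        calls, response, reference, covariates)
    if df["condition"].nunique() < 2:
        raise ValueError("need >= 2 calling conditions in the data")
    fit = reml_variance_components(df[response].to_numpy(dtype=float), X,
                                   {group: df[group].to_numpy()},
                                   names=names, model=f"lmm[{response}]")
    terms = []
    groups = {"condition": cond_idx}
    for c in cov_means:
        groups[c] = [names.index(c)]
    for term, idxs in groups.items():
        b = fit.estimates[idxs]
        V = fit.cov[np.ix_(idxs, idxs)]
        chi2 = float(b @ np.linalg.solve(V, b))
        dof = len(idxs)
        terms.append({"term": term, "chisq": chi2, "df": dof,
                      "p": float(sps.chi2.sf(chi2, dof))})
    fit.extra.update({
        "wald_terms": pd.DataFrame(terms),
        "condition_levels": levels,
        "condition_coef_idx": cond_idx,
        "covariate_means": cov_means,
        "response": response,
        "n_groups": int(df[group].nunique()),
    })
    return fit


def emm_pairwise_tukey(fit: FitResult) -> pd.DataFrame:
    """Pairwise condition contrasts of estimated marginal means (Tukey).

    EMMs are evaluated at the covariate means; the covariates cancel in the
    differences, so each contrast is a linear combination of the condition
    coefficients.  P-values use the studentized-range distribution for
    ``k = #levels`` with containment-style residual df.
    """
    levels: List[str] = fit.extra["condition_levels"]
    cond_idx: List[int] = fit.extra["condition_coef_idx"]
    k = len(levels)
    effects = {levels[0]: np.zeros(len(fit.estimates))}
    for lev, j in zip(levels[1:], cond_idx):
        e = np.zeros(len(fit.estimates))
        e[j] = 1.0
        effects[lev] = e
    n = fit.extra["n"]
    dof = max(n - len(fit.estimates) - (fit.extra["n_groups"] - 1), 2)
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            la, lb = sorted((levels[a], levels[b]))
            c = effects[la] - effects[lb]
            est = float(c @ fit.estimates)
            se = float(np.sqrt(c @ fit.cov @ c))
            q = abs(est) / se * math.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, dof))
            rows.append({"contrast": f"{la.capitalize()} vs. {lb.capitalize()}",
                         "estimate": est, "se": se,
                         "t_ratio": est / se, "df": dof, "p_tukey": p})
    return pd.DataFrame(rows)


def descriptive_means(calls: pd.DataFrame, param: str) -> FitResult:
    """Population mean of one call parameter via an intercept-only LMM.

    Random intercepts: male, recording (nested within male) and calling
    condition; the condition grouping is dropped with a warning when it is
    degenerate (fewer than 2 levels).  The returned intercept estimate is the
    model-based population mean.
    """
    df = calls.dropna(subset=[param])
    factors = {"male_id": df["male_id"].to_numpy(),
               "recording_id": df["recording_id"].to_numpy()}
    if "condition" in df.columns and df["condition"].nunique() >= 2:
        factors["condition"] = df["condition"].to_numpy()
    else:
        warnings.warn(f"{param}: condition grouping degenerate; "
                      "using two-level nesting (male/recording)")
    X = np.ones((len(df), 1))
    return reml_variance_components(df[param].to_numpy(dtype=float), X,
                                    factors, names=["intercept"],
                                    model=f"descriptive[{param}]")


# ---------------------------------------------------------------------------
# Logistic GLMM by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _logistic_irls(X: np.ndarray, y: np.ndarray,
                   tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        new = np.linalg.solve((X.T * w) @ X, (X.T * w) @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


def _cluster_modes(Xb: np.ndarray, y: np.ndarray, gidx: np.ndarray,
                   n_groups: int, sigma2: float, iters: int = 25):
    """Posterior modes and curvatures of the random intercepts (vectorized)."""
    b = np.zeros(n_groups)
    for _ in range(iters):
        eta = np.clip(Xb + b[gidx], -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = np.bincount(gidx, weights=y - mu, minlength=n_groups) - b / sigma2
        hess = -np.bincount(gidx, weights=mu * (1 - mu),
                            minlength=n_groups) - 1.0 / sigma2
        step = grad / hess
        b = b - np.clip(step, -5, 5)
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(Xb + b[gidx], -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    curv = np.bincount(gidx, weights=mu * (1 - mu),
                       minlength=n_groups) + 1.0 / sigma2
    return b, curv


def glmm_marginal_loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                         gidx: np.ndarray, n_groups: int,
                         n_quad: int = 15) -> float:
    """Marginal log-likelihood of the random-intercept logit model.

    ``theta = (beta..., log sigma)``.  Each cluster integral is evaluated by
    Gauss-Hermite quadrature adapted to the cluster's posterior mode and
    curvature; ``n_quad=1`` is the Laplace approximation.
    """
    beta = theta[:-1]
    sigma = math.exp(min(theta[-1], 10.0))
    sigma2 = max(sigma * sigma, 1e-12)
    Xb = X @ beta
    bhat, curv = _cluster_modes(Xb, y, gidx, n_groups, sigma2)
    nodes, weights = roots_hermite(n_quad)
    scale = np.sqrt(2.0 / curv)  # per cluster
    # h(b) summed within cluster, evaluated at each adapted node
    logI = np.full(n_groups, -np.inf)
    vals = np.empty((n_quad, n_groups))
    for t in range(n_quad):
        b_t = bhat + scale * nodes[t]
        eta = np.clip(Xb + b_t[gidx], -35, 35)
        ll_obs = y * eta - np.logaddexp(0.0, eta)
        h = (np.bincount(gidx, weights=ll_obs, minlength=n_groups)
             - b_t * b_t / (2.0 * sigma2))
        vals[t] = math.log(weights[t]) + nodes[t] ** 2 + h
    vmax = vals.max(axis=0)
    logI = vmax + np.log(np.exp(vals - vmax).sum(axis=0))
    logI += np.log(scale) - 0.5 * math.log(2.0 * math.pi * sigma2)
    return float(logI.sum())


def _num_hess(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * eps * eps)
    return H


def fit_logistic_glmm(nights: pd.DataFrame, response: str = "mating_success",
                      fixed: Sequence[str] = ("calling", "clutch_present"),
                      group: str = "male_id", n_quad: int = 15) -> FitResult:
    """Random-intercept logistic GLMM for nightly mating success.

    ``response ~ fixed... + (1 | group)`` fitted by maximizing the AGQ
    marginal likelihood; Wald z tests from the numerical Hessian.  A single
    group degenerates to a plain logistic GLM with zero variance; a variance
    collapsing to ~0 is reported as a boundary fit.
    """
    df = nights.dropna(subset=[response, *fixed]).copy()
    y = df[response].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    X = np.column_stack([np.ones(len(df))]
                        + [df[c].to_numpy(dtype=float) for c in fixed])
    names = ["intercept", *fixed]
    gidx, uniq = pd.factorize(df[group].to_numpy())
    n_groups = uniq.size
    if y.min() == y.max():
        raise ValueError("response has a single class; model not identifiable")

    beta0 = _logistic_irls(X, y)
    if n_groups == 1:
        eta = X @ beta0
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        cov = np.linalg.inv((X.T * (mu * (1 - mu))) @ X)
        se = np.sqrt(np.diag(cov))
        z = beta0 / se
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return FitResult(model="logistic_glmm", names=names, estimates=beta0,
                         se=se, statistic=z, stat_name="z",
                         pvalues=2.0 * sps.norm.sf(np.abs(z)), loglik=ll,
                         cov=cov, random_variances={group: 0.0},
                         boundary=True,
                         extra={"n_quad": n_quad, "n_groups": 1})

    def nll(theta):
        return -glmm_marginal_loglik(theta, X, y, gidx, n_groups, n_quad)

    x0 = np.append(beta0, 0.0)  # log sigma = 0
    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    if not np.isfinite(res.fun):
        raise ConvergenceError("GLMM marginal likelihood is not finite")
    theta = res.x
    sigma = math.exp(theta[-1])
    boundary = sigma < 1e-3
    H = _num_hess(nll, theta)
    try:
        cov_all = np.linalg.inv(H)
        if np.any(np.diag(cov_all)[:-1] <= 0):
            raise np.linalg.LinAlgError("non-PD Hessian")
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    cov = cov_all[:-1, :-1]
    se = np.sqrt(np.abs(np.diag(cov)))
    beta = theta[:-1]
    z = beta / se
    return FitResult(model="logistic_glmm", names=names, estimates=beta,
                     se=se, statistic=z, stat_name="z",
                     pvalues=2.0 * sps.norm.sf(np.abs(z)),
                     loglik=-float(res.fun), cov=cov,
                     random_variances={group: float(sigma ** 2)},
                     converged=bool(res.success or res.status in (0, 2)),
                     boundary=boundary,
                     extra={"n_quad": n_quad, "n_groups": int(n_groups),
                            "log_sigma_se": float(np.sqrt(abs(cov_all[-1, -1])))})
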