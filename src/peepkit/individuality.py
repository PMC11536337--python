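"""Vocal-individuality metrics: CV ratios, PCA, Beecher's Hs, LDA assignment.

The central question is how much individual-identity information a
single-note call carries.  Three complementary views are computed:

* **CVb/CVw ratios** — per parameter, the coefficient of variation between
  individuals (pooled calls) over the within-individual CV (average
  within-recording CV); ratios above 1 indicate individual distinctiveness.
* **Beecher's information capacity Hs** — PCA decorrelates the parameters,
  then each principal component contributes ``log2(sqrt(F))`` bits, where F
  is the one-way ANOVA F ratio with individual as the factor (contributions
  with F < 1 are floored at 0).  ``2**Hs`` is the largest group size in which
  an individual remains identifiable.
* **LDA assignment** — how often a linear discriminant classifier assigns a
  call to the correct male, against the 1/n_males chance level.

The F-to-bits convention follows the identity-metrics literature (the
``calcHS`` convention of the IDmeasurer package); ANOVA units are individual
calls by default, with a recording-means variant behind a flag.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = ["cv", "cv_table", "pca_scores", "beecher_hs", "group_size",
           "lda_assignment", "individuality_report", "PCAResult", "HsResult",
           "LDAResult", "IndividualityReport", "DEFAULT_PARAMS"]

DEFAULT_PARAMS = ("cd_s", "cd90_s", "ici_s", "t95_pct",
                  "pf_hz", "lf_hz", "hf_hz", "fr_hz")


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation in %: sample SD (n-1) over mean, times 100."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("CV needs at least 2 finite values")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / m * 100.0)


def cv_table(table: pd.DataFrame,
             params: Sequence[str] = DEFAULT_PARAMS) -> pd.DataFrame:
    """Per-parameter CVw, CVb and their ratio.

    CVw = mean over males of (mean over that male's recordings of the
    within-recording CV); CVb = CV of all calls pooled.  Expects a table that
    already passed the inclusion filters (>= 2 recordings per male with >= 2
    calls each).
    """
    rows = []
    rec_cv = table.groupby(["male_id", "recording_id"], sort=False)
    for p in params:
        per_rec = rec_cv[p].apply(lambda v: cv(v.dropna()))
        per_male = per_rec.groupby(level="male_id").mean()
        cvw = float(per_male.mean())
        cvb = cv(table[p].dropna())
        rows.append({"parameter": p, "cvw": cvw, "cvb": cvb,
                     "ratio": cvb / cvw})
    return pd.DataFrame(rows)


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the call parameters."""

    params: List[str]
    loadings: np.ndarray       # parameter x PC
    eigenvalues: np.ndarray    # non-increasing; sum = n params
    percent_variance: np.ndarray
    scores: np.ndarray         # call x PC

    def n_above_one(self) -> int:
        return int(np.sum(self.eigenvalues > 1.0))


def pca_scores(table: pd.DataFrame,
               params: Sequence[str] = DEFAULT_PARAMS) -> PCAResult:
    """PCA on the correlation matrix (z-scored parameters).

    The parameters mix units (s, Hz, %), so the covariance matrix would be
    dominated by the Hz-scale columns; standardizing first weights them
    equally.  Sign convention: the largest-magnitude loading of each PC is
    positive.  Rows with any missing parameter are dropped.
    """
    data = table[list(params)].dropna()
    if len(data) < 2:
        raise ValueError("PCA needs at least 2 complete calls")
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    const = [p for p, s in zip(params, sd) if s == 0]
    if const:
        raise ValueError(f"constant parameter(s): {const}")
    Z = (X - X.mean(axis=0)) / sd
    R = (Z.T @ Z) / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    V = eigvecs[:, order]
    for j in range(V.shape[1]):  # deterministic sign
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    return PCAResult(params=list(params), loadings=V, eigenvalues=eigvals,
                     percent_variance=100.0 * eigvals / eigvals.sum(),
                     scores=Z @ V)


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F ratio (between-group MS over within-group MS)."""
    groups = pd.Series(values).groupby(pd.Series(labels))
    k = groups.ngroups
    n = values.size
    grand = values.mean()
    counts = groups.count().to_numpy()
    means = groups.mean().to_numpy()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(((values - grand) ** 2).sum()) - ssb
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    if msw <= 0:
        return float("inf")
    return msb / msw


@dataclass
class HsResult:
    total: float
    per_pc: np.ndarray
    f_values: np.ndarray
    pc_policy: str
    included: np.ndarray  # PC indices entering the sum
    unit: str = "calls"


def beecher_hs(scores: np.ndarray, labels: Sequence, pc_policy: str = "all",
               eigenvalues: Optional[np.ndarray] = None,
               unit: str = "calls",
               recording_ids: Optional[Sequence] = None) -> HsResult:
    """Beecher's information capacity from PC scores and individual labels.

    Per PC: one-way ANOVA with individual as factor; HS_j = log2(sqrt(F_j)),
    floored at 0 when F_j < 1.  ``pc_policy`` selects which PCs enter the
    total: ``"all"`` or ``"eigenvalue_gt1"`` (requires ``eigenvalues``).
    ``unit="recording_means"`` averages scores per recording first
    (``recording_ids`` required).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if unit == "recording_means":
        if recording_ids is None:
            raise ValueError("recording_ids required for recording_means unit")
        df = pd.DataFrame(scores)
        df["_m"] = labels
        df["_r"] = np.asarray(recording_ids)
        agg = df.groupby(["_m", "_r"]).mean()
        labels = agg.index.get_level_values("_m").to_numpy()
        scores = agg.to_numpy()
    elif unit != "calls":
        raise ValueError("unit must be 'calls' or 'recording_means'")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 individuals")
    if counts.min() < 2:
        raise ValueError("every individual needs at least 2 observations")
    f_values = np.array([_anova_f(scores[:, j], labels)
                         for j in range(scores.shape[1])])
    per_pc = np.maximum(0.5 * np.log2(np.maximum(f_values, 1.0)), 0.0)
    if pc_policy == "all":
        included = np.arange(scores.shape[1])
    elif pc_policy == "eigenvalue_gt1":
        if eigenvalues is None:
            raise ValueError("eigenvalues required for pc_policy='eigenvalue_gt1'")
        included = np.flatnonzero(np.asarray(eigenvalues) > 1.0)
    else:
        raise ValueError(f"unknown pc_policy {pc_policy!r}")
    total = float(per_pc[included].sum())
    return HsResult(total=total, per_pc=per_pc, f_values=f_values,
                    pc_policy=pc_policy, included=included, unit=unit)


def group_size(hs_bits: float):
    """Maximum group size 2**Hs in which an individual stays identifiable.

    Returns ``(exact, whole)`` where ``whole`` is the floor as a count of
    whole individuals (at least 1).
    """
    if hs_bits < 0:
        raise ValueError("Hs must be nonnegative")
    exact = 2.0 ** hs_bits
    return exact, max(int(math.floor(exact)), 1)


@dataclass
class LDAResult:
    scheme: str
    per_male: pd.Series          # accuracy % per male
    mean_accuracy: float         # mean over males, %
    sd_accuracy: float           # SD over males, %
    chance: float                # 100 / n_males, %
    n_males: int


def lda_assignment(scores: np.ndarray, labels: Sequence,
                   cv_scheme: str = "loo_call",
                   recording_ids: Optional[Sequence] = None) -> LDAResult:
    """Linear discriminant assignment accuracy under a validation scheme.

    Schemes: ``"loo_call"`` (leave-one-call-out, default),
    ``"loo_recording"`` (leave-one-recording-out; needs ``recording_ids``)
    and ``"resubstitution"``.  A rank-deficient pooled covariance triggers a
    warning and shrinkage regularization.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    uniq, counts = np.unique(y, return_counts=True)
    if uniq.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 males with >= 2 calls each")
    # pooled within-class covariance rank check
    resid = X - pd.DataFrame(X).groupby(pd.Series(y)).transform("mean").to_numpy()
    pooled = resid.T @ resid / max(len(X) - uniq.size, 1)
    solver_kw = {"solver": "svd"}
    if np.linalg.matrix_rank(pooled) < X.shape[1]:
        warnings.warn("singular pooled covariance; using shrinkage (ridge) LDA")
        solver_kw = {"solver": "lsqr", "shrinkage": 1e-6}

    def _fit_predict(train, test):
        clf = LinearDiscriminantAnalysis(**solver_kw)
        clf.fit(X[train], y[train])
        return clf.predict(X[test])

    pred = np.empty(len(y), dtype=y.dtype)
    idx = np.arange(len(y))
    if cv_scheme == "resubstitution":
        pred = _fit_predict(idx, idx)
    elif cv_scheme == "loo_call":
        for i in idx:
            pred[i] = _fit_predict(idx != i, [i])[0]
    elif cv_scheme == "loo_recording":
        if recording_ids is None:
            raise ValueError("recording_ids required for loo_recording")
        rec = np.asarray(recording_ids)
        for r in np.unique(rec):
            mask = rec == r
            pred[mask] = _fit_predict(~mask, mask)
    else:
        raise ValueError(f"unknown cv_scheme {cv_scheme!r}")
    correct = pd.Series(pred == y).groupby(pd.Series(y)).mean() * 100.0
    return LDAResult(scheme=cv_scheme, per_male=correct,
                     mean_accuracy=float(correct.mean()),
                     sd_accuracy=float(correct.std(ddof=1)),
                     chance=100.0 / uniq.size, n_males=int(uniq.size))


@dataclass
class IndividualityReport:
    cv: pd.DataFrame
    pca: PCAResult
    hs_all: HsResult
    hs_conservative: HsResult
    group_size_all: float
    group_size_conservative: float
    lda: LDAResult

    def to_dict(self) -> Dict:
        return {
            "cv_table": self.cv.to_dict(orient="records"),
            "eigenvalues": self.pca.eigenvalues.tolist(),
            "percent_variance": self.pca.percent_variance.tolist(),
            "hs_all_bits": self.hs_all.total,
            "hs_conservative_bits": self.hs_conservative.total,
            "hs_convention": "HS_j = log2(sqrt(F_j)), floored at 0",
            "group_size_all": self.group_size_all,
            "group_size_conservative": self.group_size_conservative,
            "lda_scheme": self.lda.scheme,
            "lda_mean_accuracy_pct": self.lda.mean_accuracy,
            "lda_sd_accuracy_pct": self.lda.sd_accuracy,
            "chance_pct": self.lda.chance,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def individuality_report(table: pd.DataFrame,
                         params: Sequence[str] = DEFAULT_PARAMS,
                         cv_scheme: str = "loo_call") -> IndividualityReport:
    """Full individuality analysis of a filtered call table."""
    data = table.dropna(subset=list(params))
    pca = pca_scores(data, params)
    labels = data["male_id"].to_numpy()
    recs = data["recording_id"].to_numpy()
    hs_all = beecher_hs(pca.scores, labels, "all")
    hs_cons = beecher_hs(pca.scores, labels, "eigenvalue_gt1",
                         eigenvalues=pca.eigenvalues)
    lda = lda_assignment(pca.scores, labels, cv_scheme=cv_scheme,
                         recording_ids=recs)
    return IndividualityReport(
        cv=cv_table(data, params), pca=pca, hs_all=hs_all,
        hs_conservative=hs_cons,
        group_size_all=group_size(hs_all.total)[0],
        group_size_conservative=group_size(hs_cons.total)[0],
        lda=lda)
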