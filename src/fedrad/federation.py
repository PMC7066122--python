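"""Site/coordinator message contract and the pooling formulas.

Sites answer statistic queries over their private tables; the coordinator
sees only aggregates whose size depends on the number of features, never on
the number of patients. Four message types cross the boundary:

* :class:`MomentSummary` — per-feature count, mean, sum of squared deviations,
  missing count and skewness; pooled exactly into global mean/SD.
* :class:`CorrelationMessage` — the local correlation matrix plus the cohort
  size; pooled approximately by inverse-variance-weighted Fisher z averaging.
* :class:`ClusterVoteMessage` — per cluster, the locally best-discriminating
  feature and its AUC; combined by cohort-size-weighted voting.
* :class:`NewtonMessage` — gradient, Hessian and log-likelihood of the
  logistic model at the current coefficients; summing site messages gives the
  exact pooled Newton-Raphson step (GLORE).

Every message serializes to a plain JSON object (``payload()``) so privacy
audits can introspect exactly what would travel over the wire.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SiteDataset

__all__ = [
    "MomentSummary",
    "CorrelationMessage",
    "ClusterVoteMessage",
    "NewtonMessage",
    "PooledMoments",
    "site_moments",
    "pooled_moments",
    "site_correlation",
    "pooled_correlation",
    "site_newton_step",
]

SCHEMA_VERSION = 1


@dataclass
class MomentSummary:
    """Per-feature first/second/third-moment aggregates from one site."""

    site_id: str
    feature_ids: list[str]
    n_per_feature: np.ndarray  # non-missing counts
    mean: np.ndarray
    sum_sq_dev: np.ndarray  # sum (x - mean)^2 over non-missing entries
    missing_count: np.ndarray
    skewness: np.ndarray  # NaN where undefined (n < 3 or constant)

    def __post_init__(self) -> None:
        p = len(self.feature_ids)
        for name in ("n_per_feature", "mean", "sum_sq_dev", "missing_count", "skewness"):
            vec = np.asarray(getattr(self, name))
            if vec.shape != (p,):
                raise ValueError(f"{name} must have length {p}")
            setattr(self, name, vec)
        if np.any(self.sum_sq_dev < -1e-12):
            raise ValueError("sum_sq_dev must be non-negative")

    def payload(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "type": "moments",
            "site_id": self.site_id,
            "feature_ids": list(self.feature_ids),
            "n_per_feature": self.n_per_feature.tolist(),
            "mean": self.mean.tolist(),
            "sum_sq_dev": self.sum_sq_dev.tolist(),
            "missing_count": self.missing_count.tolist(),
            "skewness": self.skewness.tolist(),
        }


@dataclass
class CorrelationMessage:
    """Local feature-feature correlation matrix with the cohort size used."""

    site_id: str
    feature_ids: list[str]
    corr: np.ndarray
    n: int

    def __post_init__(self) -> None:
        p = len(self.feature_ids)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.shape != (p, p):
            raise ValueError("corr must be square over the feature list")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10, equal_nan=True):
            raise ValueError("corr must be symmetric")
        finite = np.isfinite(self.corr)
        if np.any(np.abs(self.corr[finite]) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")

    def payload(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "type": "correlation",
            "site_id": self.site_id,
            "feature_ids": list(self.feature_ids),
            "corr": self.corr.tolist(),
            "n": int(self.n),
        }


@dataclass
class ClusterVoteMessage:
    """One site's winner per cluster: cluster label -> (feature id, local AUC)."""

    site_id: str
    n: int
    best_feature_per_cluster: dict[int, tuple[str, float]]

    def __post_init__(self) -> None:
        for label, (fid, auc) in self.best_feature_per_cluster.items():
            if not (0.5 - 1e-9 <= auc <= 1.0 + 1e-9):
                raise ValueError(f"cluster {label}: AUC {auc} outside [0.5, 1]")

    def payload(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "type": "cluster_vote",
            "site_id": self.site_id,
            "n": int(self.n),
            "votes": {
                str(k): [fid, float(auc)]
                for k, (fid, auc) in self.best_feature_per_cluster.items()
            },
        }


@dataclass
class NewtonMessage:
    """Local gradient/Hessian/log-likelihood of the logistic model at beta."""

    site_id: str
    gradient: np.ndarray  # length p+1 (intercept first)
    hessian: np.ndarray  # (p+1, p+1), X' W X, positive semidefinite
    log_likelihood: float
    n: int  # complete cases used

    def __post_init__(self) -> None:
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.hessian = np.asarray(self.hessian, dtype=float)
        q = self.gradient.shape[0]
        if self.hessian.shape != (q, q):
            raise ValueError("hessian dimensions inconsistent with gradient")
        if not np.allclose(self.hessian, self.hessian.T, atol=1e-8):
            raise ValueError("hessian must be symmetric")

    def payload(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "type": "newton",
            "site_id": self.site_id,
            "gradient": self.gradient.tolist(),
            "hessian": self.hessian.tolist(),
            "log_likelihood": float(self.log_likelihood),
            "n": int(self.n),
        }


@dataclass
class PooledMoments:
    """Coordinator-side global statistics per feature."""

    feature_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray  # NaN flagged where pooled N < 2
    missing_fraction: np.ndarray
    n_total: np.ndarray


def site_moments(dataset: SiteDataset, feature_ids: Sequence[str] | None = None) -> MomentSummary:
    """Compute one site's per-feature moment summary over non-missing entries.

    Skewness is the unadjusted ``g1 = m3 / m2^(3/2)`` with central moments over
    the non-missing entries; it is NaN (flagged undefined) for features with
    fewer than 3 non-missing values or zero variance.
    """
    if dataset.n == 0:
        raise ValueError("empty dataset")
    feats = dataset.features if feature_ids is None else dataset.features[list(feature_ids)]
    values = feats.to_numpy(dtype=float)
    present = np.isfinite(values)
    n = present.sum(axis=0)
    missing = values.shape[0] - n

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(present, values, np.nan), axis=0)
        dev = np.where(present, values - mean, 0.0)
        ss = np.sum(dev**2, axis=0)
        m2 = np.where(n > 0, ss / np.maximum(n, 1), np.nan)
        m3 = np.sum(dev**3, axis=0) / np.maximum(n, 1)
        skew = np.where((n >= 3) & (m2 > 0), m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, np.nan)
    mean = np.where(n > 0, mean, np.nan)
    return MomentSummary(
        site_id=dataset.site_id,
        feature_ids=list(feats.columns),
        n_per_feature=n.astype(int),
        mean=mean,
        sum_sq_dev=ss,
        missing_count=missing.astype(int),
        skewness=skew,
    )


def pooled_moments(summaries: Sequence[MomentSummary]) -> PooledMoments:
    """Pool site moment summaries into exact global mean/SD per feature.

    Uses the exact decomposition of the pooled sum of squares,
    ``SS = sum_k (SS_k + n_k (mu_k - mu)^2)``, so the result matches the
    statistics of the concatenated data to floating precision. The SD is the
    sample SD with ``N - 1`` in the denominator and NaN where pooled N < 2.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    feature_ids = summaries[0].feature_ids
    for s in summaries[1:]:
        if s.feature_ids != feature_ids:
            raise ValueError("inconsistent feature lists across sites")

    n = np.vstack([s.n_per_feature for s in summaries]).astype(float)
    mu = np.vstack([s.mean for s in summaries])
    ss = np.vstack([s.sum_sq_dev for s in summaries])
    missing = np.vstack([s.missing_count for s in summaries]).astype(float)

    n_total = n.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nansum(np.where(n > 0, n * mu, 0.0), axis=0) / n_total
        pooled_ss = np.nansum(np.where(n > 0, ss + n * (mu - mean) ** 2, 0.0), axis=0)
        sd = np.where(n_total >= 2, np.sqrt(pooled_ss / np.maximum(n_total - 1, 1)), np.nan)
    frac = missing.sum(axis=0) / (n_total + missing.sum(axis=0))
    return PooledMoments(
        feature_ids=list(feature_ids),
        mean=np.where(n_total > 0, mean, np.nan),
        sd=sd,
        missing_fraction=frac,
        n_total=n_total.astype(int),
    )


def site_correlation(
    dataset: SiteDataset,
    feature_ids: Sequence[str] | None = None,
    pairwise: bool = True,
) -> CorrelationMessage:
    """One site's Pearson correlation matrix.

    ``pairwise=True`` (default) uses pairwise-complete observations, which
    maximizes data use under MCAR missingness; ``pairwise=False`` restricts to
    complete cases. The reported ``n`` is the number of rows entering the
    computation (all rows for pairwise mode, complete rows otherwise).
    """
    feats = dataset.features if feature_ids is None else dataset.features[list(feature_ids)]
    if pairwise:
        corr = feats.corr(method="pearson", min_periods=2)
        n_used = len(feats)
    else:
        complete = feats.dropna()
        corr = complete.corr(method="pearson")
        n_used = len(complete)
    mat = corr.to_numpy()
    np.fill_diagonal(mat, 1.0)
    return CorrelationMessage(
        site_id=dataset.site_id, feature_ids=list(feats.columns), corr=mat, n=n_used
    )


def pooled_correlation(
    messages: Sequence[CorrelationMessage],
    weight_mode: str = "fisher",
    _clip: float = 1.0 - 1e-7,
) -> pd.DataFrame:
    """Pool site correlation matrices by weighted Fisher z averaging.

    Elementwise ``z_k = atanh(clip(r_k))``; pooled ``z = sum w_k z_k / sum w_k``
    with ``w_k = n_k - 3`` (the inverse variance of z; ``weight_mode="n"``
    selects plain cohort-size weights); result ``tanh(z)`` with the diagonal
    forced to exactly 1. Sites with n <= 3 are excluded with a warning.
    """
    usable = []
    for m in messages:
        if m.n <= 3:
            warnings.warn(f"site {m.site_id!r} excluded from correlation pooling (n <= 3)")
            continue
        usable.append(m)
    if not usable:
        raise ValueError("no site with n > 3 to pool")
    feature_ids = usable[0].feature_ids
    for m in usable[1:]:
        if m.feature_ids != feature_ids:
            raise ValueError("inconsistent feature lists across sites")

    if weight_mode == "fisher":
        w = np.array([m.n - 3 for m in usable], dtype=float)
    elif weight_mode == "n":
        w = np.array([m.n for m in usable], dtype=float)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    z = np.zeros_like(usable[0].corr)
    for wk, m in zip(w, usable):
        r = np.clip(np.nan_to_num(m.corr, nan=0.0), -_clip, _clip)
        z = z + wk * np.arctanh(r)
    pooled = np.tanh(z / w.sum())
    pooled = (pooled + pooled.T) / 2.0
    np.fill_diagonal(pooled, 1.0)
    return pd.DataFrame(pooled, index=feature_ids, columns=feature_ids)


def site_newton_step(
    dataset: SiteDataset,
    feature_ids: Sequence[str],
    beta: np.ndarray,
    labels: pd.Series | None = None,
) -> NewtonMessage:
    """One site's logistic gradient/Hessian/log-likelihood at ``beta``.

    ``beta`` has length p+1 with the intercept first. Rows with a missing
    entry in any model column (or an unknown label) are dropped; the count of
    complete cases is reported as ``n``. With design matrix X (column of ones
    prepended) and fitted probabilities ``p = sigmoid(X beta)``:
    gradient ``X'(y - p)``, Hessian ``X' diag(p(1-p)) X``, and the Bernoulli
    log-likelihood.
    """
    y_all = dataset.outcome if labels is None else labels
    feats = dataset.features[list(feature_ids)]
    mask = feats.notna().all(axis=1) & pd.Series(
        np.isfinite(np.asarray(y_all, dtype=float)), index=feats.index
    )
    x = feats.loc[mask].to_numpy(dtype=float)
    y = np.asarray(y_all[mask], dtype=float)
    if x.shape[0] == 0:
        raise ValueError(f"site {dataset.site_id!r}: zero complete cases")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in design matrix")

    beta = np.asarray(beta, dtype=float)
    design = np.column_stack([np.ones(len(x)), x])
    if design.shape[1] != beta.shape[0]:
        raise ValueError("beta length must be number of features + 1")
    eta = design @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    grad = design.T @ (y - p)
    w = p * (1.0 - p)
    hess = design.T @ (design * w[:, None])
    # numerically safe log-likelihood via log1p(exp(-|eta|))
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return NewtonMessage(
        site_id=dataset.site_id, gradient=grad, hessian=hess, log_likelihood=ll, n=len(y)
    )
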