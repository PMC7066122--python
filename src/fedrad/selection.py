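"""Clustering-based feature selection, centralized and distributed.

Radiomic features are strongly redundant, so dimensionality is first reduced
by average-linkage hierarchical clustering of the inter-feature correlation
matrix (distance ``1 - |r|``, dendrogram cut so that features merge while the
average absolute correlation stays >= the cutoff, 0.6 by default). One
representative per cluster is then chosen by univariate discriminative
performance (AUC):

* centralized — the max-AUC feature per cluster enters the model iff its
  Benjamini-Hochberg-adjusted univariate Wald p-value is below the FDR level;
* distributed — every cohort votes for its locally best feature per cluster
  and a feature is selected when the cohort-size-weighted selection rate
  reaches the vote threshold (80% by default). The distributed path has no
  FDR gate; the vote is its only filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .datasets import SiteDataset
from .federation import ClusterVoteMessage
from .logistic import SeparationError, fit_logistic_centralized

__all__ = [
    "ClusterAssignment",
    "SelectionResult",
    "zscore",
    "cluster_features",
    "univariate_auc",
    "site_cluster_votes",
    "select_representatives_centralized",
    "select_representatives_distributed",
    "cluster_overlap",
]


@dataclass
class ClusterAssignment:
    """Flat cluster labels (1..C) per feature plus the merge history."""

    labels: dict[str, int]
    linkage_record: np.ndarray  # scipy linkage matrix

    @property
    def num_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list[str]:
        return [f for f, c in self.labels.items() if c == label]

    def cluster_labels(self) -> list[int]:
        return sorted(set(self.labels.values()))


@dataclass
class SelectionResult:
    """Selected representatives with full per-cluster provenance."""

    selected: list[str]
    per_cluster: dict[int, dict]
    mode: str

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "selected": list(self.selected),
            "per_cluster": {str(k): v for k, v in self.per_cluster.items()},
        }


def zscore(
    matrix: pd.DataFrame, mean: np.ndarray, sd: np.ndarray
) -> pd.DataFrame:
    """Standardize ``(x - mean) / sd`` per column; missing entries stay missing.

    Columns with zero (or non-finite) SD are flagged constant and removed
    with a warning rather than producing infinities.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if mean.shape[0] != matrix.shape[1] or sd.shape[0] != matrix.shape[1]:
        raise ValueError("mean/sd length must match the number of columns")
    bad = ~(np.isfinite(sd) & (sd > 0))
    if bad.any():
        dropped = [c for c, b in zip(matrix.columns, bad) if b]
        warnings.warn(f"constant features removed before z-scoring: {dropped}")
    keep = ~bad
    out = (matrix.loc[:, keep] - mean[keep]) / sd[keep]
    return out


def cluster_features(
    corr: pd.DataFrame, cutoff: float = 0.6, signed: bool = False
) -> ClusterAssignment:
    """Average-linkage clustering of features from their correlation matrix.

    Distance is ``1 - |r|`` (``1 - r`` when ``signed=True``); the dendrogram is
    cut at height ``1 - cutoff``, so features stay merged while their average
    (absolute) correlation is at least the cutoff. Cluster labels are
    renumbered 1..C in order of first appearance along the feature list, which
    makes labels deterministic for a given column order.
    """
    mat = corr.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    if np.any(np.abs(mat) > 1 + 1e-10):
        raise ValueError("correlations must lie in [-1, 1]")
    features = list(corr.columns)
    if len(features) == 1:
        return ClusterAssignment(labels={features[0]: 1}, linkage_record=np.empty((0, 4)))
    dist = 1.0 - (mat if signed else np.abs(mat))
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=1.0 - cutoff, criterion="distance")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for f, r in zip(features, raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[f] = relabel[r]
    return ClusterAssignment(labels=labels, linkage_record=z)


def univariate_auc(
    feature: Sequence[float], outcome: Sequence[float]
) -> tuple[float, float]:
    """Discriminative AUC of a single feature plus its univariate Wald p-value.

    Complete cases only. The AUC of a univariate logistic model's predictions
    equals ``max(a, 1 - a)`` where ``a`` is the rank-statistic AUC of the raw
    feature (the link is monotone, so only the slope's sign can flip the
    direction); ties count 1/2. The p-value is the two-sided Wald test of the
    slope in the univariate logistic fit; a separated feature gets p = 0.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(outcome, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if np.all(x == x[0]):
        return 0.5, 1.0
    a = roc_auc_score(y, x)
    auc = max(a, 1.0 - a)
    try:
        model = fit_logistic_centralized(x[:, None], y, feature_ids=["x"])
        from .federation import site_newton_step

        ds = SiteDataset(
            site_id="<uni>",
            features=pd.DataFrame({"x": x}),
            outcome=pd.Series(y),
        )
        msg = site_newton_step(ds, ["x"], model.beta)
        cov = np.linalg.inv(msg.hessian)
        se = float(np.sqrt(cov[1, 1]))
        zstat = model.coefficients[0] / se
        pval = float(2.0 * norm.sf(abs(zstat)))
    except SeparationError:
        pval = 0.0
    return float(auc), pval


def site_cluster_votes(
    dataset: SiteDataset,
    clusters: ClusterAssignment,
    labels: pd.Series | None = None,
) -> ClusterVoteMessage:
    """One cohort's vote: per cluster, its locally highest-AUC feature.

    AUC ties are broken toward the lexicographically smallest feature id so
    the vote is deterministic.
    """
    y = dataset.outcome if labels is None else labels
    best: dict[int, tuple[str, float]] = {}
    for label in clusters.cluster_labels():
        candidates = []
        for fid in sorted(clusters.members(label)):
            try:
                auc, _ = univariate_auc(dataset.features[fid], y)
            except ValueError:
                continue
            candidates.append((fid, auc))
        if candidates:
            top = max(a for _, a in candidates)
            winner = min(f for f, a in candidates if a == top)  # ties -> smallest id
            best[label] = (winner, top)
    return ClusterVoteMessage(site_id=dataset.site_id, n=dataset.n, best_feature_per_cluster=best)


def select_representatives_centralized(
    clusters: ClusterAssignment,
    data: pd.DataFrame,
    outcome: Sequence[float],
    fdr: float = 0.05,
) -> SelectionResult:
    """Pick the max-AUC feature per cluster, gated by BH-adjusted p < fdr.

    The Benjamini-Hochberg adjustment is applied across the univariate Wald
    p-values of *all* retained features (not only cluster winners); a cluster's
    winner enters the selection iff its adjusted p is below the FDR level.
    An empty selection is a legal outcome.
    """
    feats = [f for f in data.columns if f in clusters.labels]
    stats = {f: univariate_auc(data[f], outcome) for f in feats}
    pvals = np.array([stats[f][1] for f in feats])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    adj = dict(zip(feats, p_adj))

    selected: list[str] = []
    per_cluster: dict[int, dict] = {}
    for label in clusters.cluster_labels():
        members = [f for f in sorted(clusters.members(label)) if f in stats]
        if not members:
            continue
        top = max(stats[f][0] for f in members)
        winner = min(f for f in members if stats[f][0] == top)  # ties -> smallest id
        entry = {
            "winner": winner,
            "auc": stats[winner][0],
            "p_adjusted": float(adj[winner]),
            "selected": bool(adj[winner] < fdr),
        }
        per_cluster[label] = entry
        if entry["selected"]:
            selected.append(winner)
    return SelectionResult(selected=selected, per_cluster=per_cluster, mode="centralized")


def select_representatives_distributed(
    clusters: ClusterAssignment,
    votes: Sequence[ClusterVoteMessage],
    vote_threshold: float = 0.8,
) -> SelectionResult:
    """Combine cohort votes into the final selection by weighted selection rate.

    For feature f in cluster c, ``weight(f)`` is the total size of cohorts
    whose winner in c is f divided by the total size of all voting cohorts;
    f is selected iff ``weight(f) >= vote_threshold`` (non-strict).
    """
    total_n = float(sum(v.n for v in votes))
    if total_n <= 0:
        raise ValueError("cohort sizes must be positive")
    valid_labels = set(clusters.cluster_labels())
    for v in votes:
        for label, (fid, _) in v.best_feature_per_cluster.items():
            if label not in valid_labels or clusters.labels.get(fid) != label:
                raise ValueError(
                    f"site {v.site_id!r}: vote ({label}, {fid}) inconsistent with clustering"
                )

    selected: list[str] = []
    per_cluster: dict[int, dict] = {}
    for label in clusters.cluster_labels():
        tally: dict[str, float] = {}
        for v in votes:
            if label in v.best_feature_per_cluster:
                fid, _ = v.best_feature_per_cluster[label]
                tally[fid] = tally.get(fid, 0.0) + v.n
        if not tally:
            continue
        winner = max(sorted(tally), key=lambda f: tally[f])
        weight = tally[winner] / total_n
        entry = {
            "winner": winner,
            "vote_weight": weight,
            "tally": {f: w / total_n for f, w in tally.items()},
            "selected": bool(weight >= vote_threshold),
        }
        per_cluster[label] = entry
        if entry["selected"]:
            selected.append(winner)
    return SelectionResult(selected=selected, per_cluster=per_cluster, mode="distributed")


def cluster_overlap(central: ClusterAssignment, distributed: ClusterAssignment) -> float:
    """Fraction of features falling in the dominant distributed subcluster.

    For each centralized cluster, the largest distributed subcluster is the
    most common distributed label among its members; the overlap is the sum of
    those subcluster sizes divided by the total feature count. Identical
    clusterings give 1; all-singleton centralized clusters also give 1 by
    construction (each largest subcluster has size 1).
    """
    if set(central.labels) != set(distributed.labels):
        raise ValueError("clusterings cover different feature sets")
    total = len(central.labels)
    agree = 0
    for label in central.cluster_labels():
        members = central.members(label)
        counts: dict[int, int] = {}
        for f in members:
            d = distributed.labels[f]
            counts[d] = counts.get(d, 0) + 1
        agree += max(counts.values())
    return agree / total
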