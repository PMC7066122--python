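"""Leave-one-cohort-out comparison of centralized vs distributed training.

For each held-out cohort the remaining cohorts train two full pipelines —

* centralized: pool all rows, QC on the pooled data, z-score with pooled
  statistics, pooled correlation matrix, average-linkage clustering,
  max-AUC-per-cluster selection gated by FDR, Newton logistic fit;
* distributed: per-site moment summaries, union QC, z-score with federated
  global statistics, Fisher-pooled correlations, clustering, cohort-size
  weighted voting, GLORE fit —

and both models are validated on the held-out cohort: AUC with DeLong CI, the
paired DeLong test between the two models, calibration slope, classification
discrepancy at the training-median thresholds, and (for the survival
endpoint) Kaplan-Meier risk-group curves with a G-rho test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cleaning import QCThresholds, qc_exclude_centralized, qc_exclude_distributed
from .datasets import SiteDataset, read_site_csv
from .evaluation import (
    auc_delong,
    calibration_test,
    classification_discrepancy,
    delong_paired_test,
    km_and_grho,
)
from .federation import (
    pooled_correlation,
    pooled_moments,
    site_correlation,
    site_moments,
)
from .logistic import (
    LogisticModel,
    SeparationError,
    fit_logistic_centralized,
    fit_logistic_glore,
    predict,
)
from .selection import (
    SelectionResult,
    cluster_features,
    cluster_overlap,
    select_representatives_centralized,
    select_representatives_distributed,
    site_cluster_votes,
    zscore,
)

__all__ = ["WorkflowConfig", "ComparisonReport", "run_leave_one_cohort_out", "feature_overlap"]


@dataclass
class WorkflowConfig:
    """All workflow constants in one place.

    Defaults carry the standard pipeline settings: 20% missingness and
    skewness-5 QC thresholds, 0.6 correlation cutoff for clustering, FDR 0.05
    for the centralized selection gate, and an 80% cohort-size-weighted vote
    threshold for the distributed selection.
    """

    endpoint: str = "binary_outcome"  # or "survival_2y"
    mode: str = "both"  # centralized | distributed | both
    qc: QCThresholds = field(default_factory=QCThresholds)
    corr_cutoff: float = 0.6
    fdr: float = 0.05
    vote_threshold: float = 0.8
    glore_tol: float = 1e-8
    max_iter: int = 25
    rho: float = 0.0
    horizon_years: float = 2.0
    seed: int = 0
    site_files: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.endpoint not in ("binary_outcome", "survival_2y"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.mode not in ("centralized", "distributed", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, lo, hi in (
            ("corr_cutoff", 0.0, 1.0),
            ("fdr", 0.0, 1.0),
            ("vote_threshold", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name} must lie in ({lo}, {hi}]")

    @classmethod
    def from_file(cls, path: str | Path) -> "WorkflowConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        qc = raw.pop("qc", None)
        cfg = cls(**raw)
        if qc:
            cfg.qc = QCThresholds(**qc)
        return cfg


@dataclass
class ComparisonReport:
    """One entry per held-out cohort plus the configuration used."""

    config: dict
    folds: list[dict]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"config": self.config, "folds": self.folds}, indent=1, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"not JSON serializable: {type(obj)}")


def feature_overlap(selA: SelectionResult, selB: SelectionResult) -> dict:
    """Overlap of two selected-feature sets (Jaccard plus both directed fractions)."""
    a, b = set(selA.selected), set(selB.selected)
    if not a and not b:
        warnings.warn("both selections empty: overlap defined as 1")
        return {"jaccard": 1.0, "frac_of_a": 1.0, "frac_of_b": 1.0, "n_common": 0}
    inter = len(a & b)
    return {
        "jaccard": inter / len(a | b),
        "frac_of_a": inter / len(a) if a else 0.0,
        "frac_of_b": inter / len(b) if b else 0.0,
        "n_common": inter,
    }


def _restrict(site: SiteDataset, labels: pd.Series) -> tuple[SiteDataset, pd.Series]:
    """Drop subjects with unknown endpoint status."""
    keep = np.isfinite(np.asarray(labels, dtype=float))
    out = SiteDataset(
        site_id=site.site_id,
        features=site.features.loc[keep],
        outcome=site.outcome.loc[keep],
        time_years=None if site.time_years is None else site.time_years.loc[keep],
        event=None if site.event is None else site.event.loc[keep],
    )
    return out, labels.loc[keep]


def _train_centralized(train, labels, cfg):
    report = qc_exclude_centralized(train, cfg.qc)
    retained = [f for f in train[0].feature_ids if f not in report.excluded]
    # site_id keys keep rows unique even if patient ids collide across sites
    keys = [s.site_id for s in train]
    pooled = pd.concat([s.features[retained] for s in train], axis=0, keys=keys)
    y = pd.concat(labels, axis=0, keys=keys)
    mean = pooled.mean(axis=0).to_numpy()
    sd = pooled.std(axis=0, ddof=1).to_numpy()
    z = zscore(pooled, mean, sd)
    corr = z.corr(method="pearson", min_periods=2)
    clusters = cluster_features(corr, cutoff=cfg.corr_cutoff)
    selection = select_representatives_centralized(clusters, z, y, fdr=cfg.fdr)
    model = None
    if selection.selected:
        complete = z[selection.selected].dropna()
        yy = y.loc[complete.index]
        model = fit_logistic_centralized(
            complete, yy, tol=cfg.glore_tol, max_iter=cfg.max_iter
        )
    scaler = pd.DataFrame({"mean": mean, "sd": sd}, index=retained)
    return {
        "qc": report, "clusters": clusters, "selection": selection,
        "model": model, "scaler": scaler,
    }


def _train_distributed(train, labels, cfg):
    all_feats = train[0].feature_ids
    summaries = [site_moments(s) for s in train]
    report = qc_exclude_distributed(summaries, cfg.qc)
    retained = [f for f in all_feats if f not in report.excluded]
    summaries = [site_moments(s, retained) for s in train]
    pm = pooled_moments(summaries)
    z_sites = []
    for s, lab in zip(train, labels):
        zf = zscore(s.features[retained], pm.mean, pm.sd)
        z_sites.append(
            SiteDataset(site_id=s.site_id, features=zf, outcome=lab)
        )
    kept = list(z_sites[0].feature_ids)
    corr = pooled_correlation([site_correlation(s, kept) for s in z_sites])
    clusters = cluster_features(corr, cutoff=cfg.corr_cutoff)
    votes = [site_cluster_votes(s, clusters) for s in z_sites]
    selection = select_representatives_distributed(
        clusters, votes, vote_threshold=cfg.vote_threshold
    )
    model = None
    if selection.selected:
        model = fit_logistic_glore(
            z_sites, selection.selected, tol=cfg.glore_tol, max_iter=cfg.max_iter
        )
    scaler = pd.DataFrame({"mean": pm.mean, "sd": pm.sd}, index=retained)
    return {
        "qc": report, "clusters": clusters, "selection": selection,
        "model": model, "scaler": scaler,
    }


def _validate(model: LogisticModel, scaler: pd.DataFrame, train, train_labels, heldout, heldout_labels, cfg):
    """Predictions on training pool and held-out cohort, on the model's scale."""
    def transform(ds_features: pd.DataFrame) -> pd.DataFrame:
        cols = scaler.index
        z = zscore(ds_features[cols], scaler["mean"].to_numpy(), scaler["sd"].to_numpy())
        return z[model.feature_ids].dropna()

    train_z = transform(
        pd.concat([s.features for s in train], axis=0, keys=[s.site_id for s in train])
    )
    train_pred = predict(model, train_z)
    val_z = transform(heldout.features)
    val_pred = predict(model, val_z)
    val_y = heldout_labels.loc[val_z.index].to_numpy(dtype=float)
    return {
        "threshold": float(np.median(train_pred)),
        "val_pred": val_pred,
        "val_y": val_y,
        "val_index": val_z.index,
    }


def run_leave_one_cohort_out(
    sites: Sequence[SiteDataset] | None = None,
    config: WorkflowConfig | None = None,
) -> ComparisonReport:
    """Run the full comparison, one fold per held-out cohort."""
    cfg = config or WorkflowConfig()
    if sites is None:
        if not cfg.site_files:
            raise ValueError("provide site datasets or config.site_files")
        sites = [read_site_csv(p) for p in cfg.site_files]
    if len(sites) < 2:
        raise ValueError("leave-one-cohort-out needs at least 2 sites")
    feats0 = sites[0].feature_ids
    for s in sites[1:]:
        if s.feature_ids != feats0:
            raise ValueError("inconsistent feature columns across site files")

    restricted = []
    for s in sites:
        lab = s.binary_label(cfg.endpoint, cfg.horizon_years)
        restricted.append(_restrict(s, lab))

    folds: list[dict] = []
    for k in range(len(sites)):
        heldout, heldout_lab = restricted[k]
        train = [restricted[i][0] for i in range(len(sites)) if i != k]
        train_lab = [restricted[i][1] for i in range(len(sites)) if i != k]
        fold: dict = {"heldout": heldout.site_id}

        pooled_y = pd.concat(train_lab)
        if pooled_y.nunique() < 2:
            fold["error"] = "training fold has a single outcome class"
            folds.append(fold)
            continue

        arms = {}
        if cfg.mode in ("centralized", "both"):
            arms["centralized"] = _train_centralized(train, train_lab, cfg)
        if cfg.mode in ("distributed", "both"):
            arms["distributed"] = _train_distributed(train, train_lab, cfg)

        val = {}
        for name, arm in arms.items():
            entry = {
                "n_excluded_qc": len(arm["qc"].excluded),
                "n_clusters": arm["clusters"].num_clusters,
                "selected": list(arm["selection"].selected),
            }
            if arm["model"] is None:
                entry["model"] = None
                entry["note"] = "empty feature selection; model skipped"
            else:
                entry["model"] = arm["model"].to_json_dict()
                try:
                    v = _validate(
                        arm["model"], arm["scaler"], train, train_lab,
                        heldout, heldout_lab, cfg,
                    )
                    val[name] = v
                    roc = auc_delong(v["val_pred"], v["val_y"])
                    entry["auc"] = roc.auc
                    entry["auc_ci95"] = roc.ci95
                    try:
                        cal = calibration_test(v["val_pred"], v["val_y"])
                        entry["calibration"] = asdict(cal)
                    except ValueError as exc:
                        entry["calibration"] = {"error": str(exc)}
                except (ValueError, SeparationError) as exc:
                    entry["validation_error"] = str(exc)
            fold[name] = entry

        if len(arms) == 2:
            fold["feature_overlap"] = feature_overlap(
                arms["centralized"]["selection"], arms["distributed"]["selection"]
            )
            try:
                fold["cluster_overlap"] = cluster_overlap(
                    arms["centralized"]["clusters"], arms["distributed"]["clusters"]
                )
            except ValueError as exc:
                fold["cluster_overlap"] = None
                fold["cluster_overlap_error"] = str(exc)

        if len(val) == 2:
            a, b = val["centralized"], val["distributed"]
            common = a["val_index"].intersection(b["val_index"])
            pa = pd.Series(a["val_pred"], index=a["val_index"]).loc[common].to_numpy()
            pb = pd.Series(b["val_pred"], index=b["val_index"]).loc[common].to_numpy()
            yy = heldout_lab.loc[common].to_numpy(dtype=float)
            try:
                fold["delong_p"] = delong_paired_test(pa, pb, yy)
            except ValueError as exc:
                fold["delong_p_error"] = str(exc)
            fold["discrepancy"] = classification_discrepancy(
                pa, pb, a["threshold"], b["threshold"]
            )
            if cfg.endpoint == "survival_2y" and heldout.time_years is not None:
                km = {}
                for name, v in val.items():
                    t = heldout.time_years.loc[v["val_index"]].to_numpy(dtype=float)
                    e = heldout.event.loc[v["val_index"]].to_numpy(dtype=float)
                    grp = (v["val_pred"] >= v["threshold"]).astype(float)
                    try:
                        res = km_and_grho(t, e, grp, rho=cfg.rho, horizon_years=cfg.horizon_years)
                        km[name] = {
                            "grho_chi2": res.grho_chi2,
                            "grho_p": res.grho_p,
                            "odds_ratio": res.odds_ratio,
                            "or_ci95": res.or_ci95,
                            "flagged": res.flagged,
                        }
                    except ValueError as exc:
                        km[name] = {"error": str(exc)}
                fold["km"] = km
        folds.append(fold)

    cfg_dict = {**{k: v for k, v in asdict(cfg).items() if k != "qc"},
                "qc": asdict(cfg.qc)}
    return ComparisonReport(config=cfg_dict, folds=folds)
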