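"""Quality-control feature exclusion, centralized and distributed.

Features are dropped when more than 20% of their values are missing or when
their distribution is heavily skewed (|skewness| > 5). Centralized QC
evaluates both rules on the concatenated data; distributed QC applies them to
each site's local moment summary and excludes the union across sites, so raw
values never leave a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import SiteDataset
from .federation import MomentSummary, site_moments

__all__ = ["QCThresholds", "ExclusionReport", "qc_exclude_centralized", "qc_exclude_distributed"]


@dataclass
class QCThresholds:
    missing_max: float = 0.20  # strict: excluded iff missing fraction > this
    skew_max: float = 5.0  # strict: excluded iff |skewness| > this

    def __post_init__(self) -> None:
        if self.missing_max <= 0 or self.skew_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ExclusionReport:
    """Excluded features with, per feature, the rule(s) and site(s) that fired."""

    excluded: set[str]
    reasons: dict[str, list[dict]] = field(default_factory=dict)
    mode: str = "centralized"

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "excluded": sorted(self.excluded),
            "reasons": self.reasons,
        }


def _apply_rules(
    feature_ids: Sequence[str],
    missing_fraction: np.ndarray,
    skewness: np.ndarray,
    thresholds: QCThresholds,
    site_id: str,
    signed_skew: bool = False,
) -> dict[str, list[dict]]:
    reasons: dict[str, list[dict]] = {}
    skew_stat = skewness if signed_skew else np.abs(skewness)
    for j, fid in enumerate(feature_ids):
        hits = []
        if missing_fraction[j] > thresholds.missing_max:
            hits.append({"rule": "missing", "value": float(missing_fraction[j]), "site": site_id})
        if np.isfinite(skew_stat[j]) and skew_stat[j] > thresholds.skew_max:
            hits.append({"rule": "skewness", "value": float(skewness[j]), "site": site_id})
        if hits:
            reasons[fid] = hits
    return reasons


def qc_exclude_centralized(
    all_sites: Sequence[SiteDataset],
    thresholds: QCThresholds = QCThresholds(),
    signed_skew: bool = False,
) -> ExclusionReport:
    """Exclude features by missingness/skewness computed on the pooled rows."""
    feature_ids = all_sites[0].feature_ids
    for s in all_sites[1:]:
        if s.feature_ids != feature_ids:
            raise ValueError("inconsistent feature lists across sites")
    pooled = pd.concat([s.features for s in all_sites], axis=0)
    pooled_ds = SiteDataset(
        site_id="<pooled>",
        features=pooled,
        outcome=pd.Series(np.zeros(len(pooled)), index=pooled.index),
    )
    m = site_moments(pooled_ds)
    frac = m.missing_count / (m.missing_count + m.n_per_feature)
    reasons = _apply_rules(feature_ids, frac, m.skewness, thresholds, "<pooled>", signed_skew)
    return ExclusionReport(excluded=set(reasons), reasons=reasons, mode="centralized")


def qc_exclude_distributed(
    summaries: Sequence[MomentSummary],
    thresholds: QCThresholds = QCThresholds(),
    signed_skew: bool = False,
) -> ExclusionReport:
    """Exclude the union of features failing either rule at any single site."""
    if not summaries:
        raise ValueError("need at least one summary")
    feature_ids = summaries[0].feature_ids
    reasons: dict[str, list[dict]] = {}
    for s in summaries:
        if s.feature_ids != feature_ids:
            raise ValueError("inconsistent feature lists across sites")
        frac = s.missing_count / (s.missing_count + s.n_per_feature)
        site_reasons = _apply_rules(feature_ids, frac, s.skewness, thresholds, s.site_id, signed_skew)
        for fid, hits in site_reasons.items():
            reasons.setdefault(fid, []).extend(hits)
    return ExclusionReport(excluded=set(reasons), reasons=reasons, mode="distributed")
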