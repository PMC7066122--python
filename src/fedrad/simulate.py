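"""Synthetic multi-site radiomics cohorts.

Generates federations of cohorts with the statistical structure the
distributed workflow assumes: block-correlated feature clusters (a factor
model, so the within-cluster correlation is known exactly in expectation), a
logistic binary endpoint driven by a known subset of features, exponential
survival times with administrative censoring, site-level mean shifts,
missing-completely-at-random entries and heavily skewed features.

Factor model: feature j in cluster c, for patient i,

    x_ij = sqrt(rho_b) g_i + sqrt(rho_w - rho_b) u_ic + sqrt(1 - rho_w) e_ij

with independent standard-normal global factor g, cluster factor u_c and
noise e. Each feature is marginally N(0, 1); the expected correlation is
rho_w within a cluster and rho_b across clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import SiteDataset

__all__ = [
    "GeneratorConfig",
    "generate_federation",
    "inject_missingness",
    "inject_skew",
    "feature_names",
]


def feature_names(num_clusters: int, features_per_cluster: int) -> list[str]:
    """Canonical feature identifiers ``c<cluster>_f<index>`` (1-based)."""
    return [
        f"c{c + 1:02d}_f{j + 1:02d}"
        for c in range(num_clusters)
        for j in range(features_per_cluster)
    ]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic federation.

    ``true_coefficients`` maps feature identifiers (one designated feature per
    chosen cluster) to log-odds effect sizes; together with ``intercept`` they
    define the logistic outcome model. Survival times are exponential with
    rate ``baseline_event_rate * exp(beta . x)`` and administratively censored
    at ``censor_horizon_years``.
    """

    num_sites: int = 4
    patients_per_site: Sequence[int] = (206, 441, 100, 141)
    num_clusters: int = 6
    features_per_cluster: int = 5
    within_cluster_corr: float = 0.7
    between_cluster_corr: float = 0.05
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {"c01_f01": 1.0, "c02_f01": -0.8, "c03_f01": 0.6}
    )
    intercept: float = 0.0
    missing_fraction: float = 0.0
    num_skewed_features: int = 0
    site_mean_shift_sd: float = 0.0
    censor_horizon_years: float = 2.0
    baseline_event_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.patients_per_site = list(self.patients_per_site)
        if self.num_sites < 1:
            raise ValueError("num_sites must be >= 1")
        if len(self.patients_per_site) != self.num_sites:
            raise ValueError("patients_per_site length must equal num_sites")
        if any(n < 10 for n in self.patients_per_site):
            raise ValueError("each site needs >= 10 patients")
        if not (0.0 <= self.within_cluster_corr < 1.0):
            raise ValueError("within_cluster_corr must be in [0, 1)")
        if self.between_cluster_corr > self.within_cluster_corr:
            raise ValueError("between_cluster_corr cannot exceed within_cluster_corr")
        if self.between_cluster_corr < 0:
            raise ValueError("between_cluster_corr must be >= 0")
        if not (0.0 <= self.missing_fraction < 0.5):
            raise ValueError("missing_fraction must be in [0, 0.5)")
        names = set(self.feature_ids)
        unknown = set(self.true_coefficients) - names
        if unknown:
            raise ValueError(f"true_coefficients name unknown features: {sorted(unknown)}")

    @property
    def feature_ids(self) -> list[str]:
        return feature_names(self.num_clusters, self.features_per_cluster)

    @property
    def num_features(self) -> int:
        return self.num_clusters * self.features_per_cluster

    def to_dict(self) -> dict:
        return {
            **{k: getattr(self, k) for k in (
                "num_sites", "patients_per_site", "num_clusters",
                "features_per_cluster", "within_cluster_corr",
                "between_cluster_corr", "intercept", "missing_fraction",
                "num_skewed_features", "site_mean_shift_sd",
                "censor_horizon_years", "baseline_event_rate", "seed",
            )},
            "true_coefficients": dict(self.true_coefficients),
        }


def _draw_features(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> np.ndarray:
    rho_w, rho_b = cfg.within_cluster_corr, cfg.between_cluster_corr
    g = rng.standard_normal((n, 1))
    u = rng.standard_normal((n, cfg.num_clusters))
    eps = rng.standard_normal((n, cfg.num_features))
    cluster_of = np.repeat(np.arange(cfg.num_clusters), cfg.features_per_cluster)
    x = (
        np.sqrt(rho_b) * g
        + np.sqrt(rho_w - rho_b) * u[:, cluster_of]
        + np.sqrt(1.0 - rho_w) * eps
    )
    return x


def generate_federation(config: GeneratorConfig) -> list[SiteDataset]:
    """Draw one federation of :class:`~fedrad.datasets.SiteDataset` objects.

    The binary endpoint is Bernoulli with logit ``intercept + beta . x`` on the
    pre-shift feature values, so site mean shifts act as pure measurement
    nuisance and never alter a patient's outcome risk. Bit-reproducible for a
    fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    names = config.feature_ids
    beta = np.array([config.true_coefficients.get(f, 0.0) for f in names])

    sites: list[SiteDataset] = []
    patient_counter = 0
    for s, n in enumerate(config.patients_per_site):
        x = _draw_features(rng, n, config)
        lp = config.intercept + x @ beta
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(float)

        # survival: exponential hazard scaled by the covariate linear predictor
        rate = config.baseline_event_rate * np.exp(x @ beta)
        t = rng.exponential(1.0 / rate)
        event = (t <= config.censor_horizon_years).astype(float)
        time = np.minimum(t, config.censor_horizon_years)

        shift = rng.normal(0.0, config.site_mean_shift_sd, size=config.num_features)
        x_obs = x + shift

        index = [f"p{patient_counter + i:05d}" for i in range(n)]
        patient_counter += n
        features = pd.DataFrame(x_obs, columns=names, index=index)
        ds = SiteDataset(
            site_id=f"site{s + 1}",
            features=features,
            outcome=pd.Series(y, index=index),
            time_years=pd.Series(time, index=index),
            event=pd.Series(event, index=index),
            meta={"true_coefficients": dict(config.true_coefficients)},
        )
        if config.num_skewed_features:
            ds = inject_skew(ds, names[: config.num_skewed_features], severity=2.0)
        if config.missing_fraction > 0:
            ds = inject_missingness(
                ds, names, config.missing_fraction,
                seed=int(rng.integers(2**31)),
            )
        sites.append(ds)
    return sites


def inject_missingness(
    dataset: SiteDataset, feature_ids: Sequence[str], fraction: float, seed: int
) -> SiteDataset:
    """Blank exactly ``round(fraction * n)`` entries per named feature (MCAR)."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    unknown = set(feature_ids) - set(dataset.feature_ids)
    if unknown:
        raise KeyError(f"unknown feature ids: {sorted(unknown)}")
    out = dataset.copy()
    rng = np.random.default_rng(seed)
    k = round(fraction * out.n)
    for f in feature_ids:
        rows = rng.choice(out.n, size=k, replace=False)
        col = out.features[f].to_numpy(dtype=float, copy=True)
        col[rows] = np.nan
        out.features[f] = col
    return out


def inject_skew(
    dataset: SiteDataset, feature_ids: Sequence[str], severity: float
) -> SiteDataset:
    """Replace named features by ``exp(severity * z)`` of their standardized values.

    This yields a lognormal-shaped column; at severity >= 2 the sample skewness
    almost surely exceeds the QC threshold of 5 for n >= 100.
    """
    if severity <= 0:
        raise ValueError("severity must be > 0")
    unknown = set(feature_ids) - set(dataset.feature_ids)
    if unknown:
        raise KeyError(f"unknown feature ids: {sorted(unknown)}")
    out = dataset.copy()
    for f in feature_ids:
        col = out.features[f]
        z = (col - col.mean()) / col.std(ddof=1)
        out.features[f] = np.exp(severity * z)
    return out
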