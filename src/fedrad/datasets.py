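"""Per-site cohort container and its CSV round-trip.

A :class:`SiteDataset` is one hospital's private table: a patients x features
matrix of real-valued radiomic features (``NaN`` marks a missing entry), a
binary endpoint column, and optional survival follow-up. All federated
operations consume these objects; only aggregate messages (see
:mod:`fedrad.federation`) ever leave them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SiteDataset", "read_site_csv", "write_site_csv"]


@dataclass
class SiteDataset:
    """One cohort: feature matrix, endpoint labels and optional survival data.

    Parameters
    ----------
    site_id
        Stable identifier of the cohort (hospital).
    features
        ``(n, p)`` DataFrame of real-valued features; ``NaN`` = missing.
    outcome
        Binary endpoint per patient (0/1, ``NaN`` = unknown status).
    time_years, event
        Optional survival follow-up: time on study in years and the event
        indicator (1 = death observed).
    """

    site_id: str
    features: pd.DataFrame
    outcome: pd.Series
    time_years: pd.Series | None = None
    event: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.features)
        if len(self.outcome) != n:
            raise ValueError(
                f"site {self.site_id!r}: outcome length {len(self.outcome)} "
                f"!= {n} feature rows"
            )
        for name in ("time_years", "event"):
            vec = getattr(self, name)
            if vec is not None and len(vec) != n:
                raise ValueError(f"site {self.site_id!r}: {name} length mismatch")
        self.outcome = pd.Series(
            np.asarray(self.outcome, dtype=float), index=self.features.index
        )

    @property
    def n(self) -> int:
        """Number of patients (rows)."""
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.columns)

    def copy(self) -> "SiteDataset":
        return SiteDataset(
            site_id=self.site_id,
            features=self.features.copy(),
            outcome=self.outcome.copy(),
            time_years=None if self.time_years is None else self.time_years.copy(),
            event=None if self.event is None else self.event.copy(),
            meta=dict(self.meta),
        )

    def binary_label(
        self, endpoint: str = "binary_outcome", horizon_years: float = 2.0
    ) -> pd.Series:
        """Endpoint label per patient, ``NaN`` where the status is unknown.

        ``binary_outcome`` returns the stored endpoint column. ``survival_2y``
        derives death-before-horizon from (time, event): an observed event
        before the horizon gives 1, follow-up beyond the horizon gives 0, and a
        patient censored alive before the horizon has unknown 2-year status.
        """
        if endpoint == "binary_outcome":
            return self.outcome.copy()
        if endpoint == "survival_2y":
            if self.time_years is None or self.event is None:
                raise ValueError(f"site {self.site_id!r} has no survival columns")
            t = np.asarray(self.time_years, dtype=float)
            e = np.asarray(self.event, dtype=float)
            label = np.where(
                (e == 1) & (t < horizon_years),
                1.0,
                np.where(t >= horizon_years, 0.0, np.nan),
            )
            return pd.Series(label, index=self.features.index)
        raise ValueError(f"unknown endpoint {endpoint!r}")


def write_site_csv(dataset: SiteDataset, path: str | Path, config: dict | None = None) -> None:
    """Write one site as CSV (patient id, features, outcome, time_years, event).

    Missing entries are written as empty fields. When ``config`` is given, a
    JSON sidecar ``<path>.json`` records the generating configuration.
    """
    path = Path(path)
    table = dataset.features.copy()
    table.insert(0, "patient_id", dataset.features.index)
    table["outcome"] = dataset.outcome.to_numpy()
    if dataset.time_years is not None:
        table["time_years"] = np.asarray(dataset.time_years, dtype=float)
    if dataset.event is not None:
        table["event"] = np.asarray(dataset.event, dtype=float)
    table.to_csv(path, index=False, na_rep="")
    if config is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"site_id": dataset.site_id, "config": config}, indent=1)
        )


def read_site_csv(path: str | Path, site_id: str | None = None) -> SiteDataset:
    """Read a site CSV written by :func:`write_site_csv`."""
    path = Path(path)
    table = pd.read_csv(path, index_col="patient_id")
    special = [c for c in ("outcome", "time_years", "event") if c in table.columns]
    features = table.drop(columns=special)
    return SiteDataset(
        site_id=site_id or path.stem,
        features=features,
        outcome=table["outcome"],
        time_years=table.get("time_years"),
        event=table.get("event"),
    )
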