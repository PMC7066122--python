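"""Model-comparison statistics for external validation.

Covers the four comparisons used to contrast centralized and distributed
models on a held-out cohort: discrimination (DeLong AUC with variance and a
paired test for correlated AUCs), calibration (slope of observed outcome on
the model's linear predictor, tested against 1), classification discrepancy
(fraction of patients the two models assign to different risk classes at
their training-median thresholds), and survival separation (Kaplan-Meier
curves per risk group with a G-rho test and the 2x2 odds ratio).

The DeLong machinery is written out from the structural components
V10 (per positive, the placement against all negatives) and V01 (per
negative): the AUC is their common mean, and var(AUC) = S10/m + S01/n with
sample (co)variances of the components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import norm

from .logistic import fit_logistic_centralized

__all__ = [
    "ROCResult",
    "CalibrationResult",
    "KMResult",
    "auc_delong",
    "delong_paired_test",
    "calibration_test",
    "classification_discrepancy",
    "km_and_grho",
]


@dataclass
class ROCResult:
    auc: float
    variance: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass
class CalibrationResult:
    slope: float
    std_err: float
    p_vs_one: float
    well_calibrated: bool  # p_vs_one >= 0.05


@dataclass
class KMResult:
    """Per-risk-group survival curves plus the group-comparison statistics."""

    groups: dict[int, dict]  # label -> {event_times, survival, at_risk}
    grho_chi2: float
    grho_p: float
    odds_ratio: float
    or_ci95: tuple[float, float]
    flagged: str | None = None


def _structural_components(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """DeLong V10 (per positive) and V01 (per negative) placement components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return cmp.mean(axis=1), cmp.mean(axis=0)


def _check_labels(labels: np.ndarray) -> None:
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auc_delong(scores: Sequence[float], labels: Sequence[float]) -> ROCResult:
    """AUC with DeLong variance and Wald 95% CI (clipped to [0, 1]).

    The AUC is the mean over positive-negative pairs of the tie-corrected
    indicator; ties count 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    _check_labels(y)
    v10, v01 = _structural_components(s, y)
    m, n = len(v10), len(v01)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.96 * np.sqrt(var)
    return ROCResult(
        auc=auc,
        variance=var,
        ci95=(max(0.0, auc - half), min(1.0, auc + half)),
        n_pos=m,
        n_neg=n,
    )


def delong_paired_test(
    scoresA: Sequence[float], scoresB: Sequence[float], labels: Sequence[float]
) -> float:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    Both score vectors must be over the same subjects. Returns 1.0 when the
    score vectors are identical (zero difference, zero variance).
    """
    a = np.asarray(scoresA, dtype=float)
    b = np.asarray(scoresB, dtype=float)
    y = np.asarray(labels, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("score/label length mismatch")
    _check_labels(y)
    if np.array_equal(a, b):
        return 1.0
    va10, va01 = _structural_components(a, y)
    vb10, vb01 = _structural_components(b, y)
    m, n = len(va10), len(va01)
    aucA, aucB = va10.mean(), vb10.mean()
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        return 1.0
    z = (aucA - aucB) / np.sqrt(var_diff)
    return float(2.0 * norm.sf(abs(z)))


def calibration_test(
    predictions: Sequence[float], labels: Sequence[float], scale: str = "logit"
) -> CalibrationResult:
    """Calibration slope in a validation cohort, tested against 1.

    Fits a univariate logistic regression of the observed labels on the
    model's predictions — on the logit scale by default (the calibration-slope
    convention, under which H0: slope = 1 means the predicted risk gradient is
    reproduced) or on the raw probability scale with ``scale="prob"``. Returns
    the slope, its Wald standard error, and the two-sided p for H0: slope = 1.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predictions must lie strictly in (0, 1)")
    _check_labels(y)
    x = np.log(p / (1.0 - p)) if scale == "logit" else p
    if np.all(x == x[0]):
        raise ValueError("constant predictions: calibration slope undefined")
    model = fit_logistic_centralized(x[:, None], y, feature_ids=["lp"])

    import pandas as pd

    from .datasets import SiteDataset
    from .federation import site_newton_step

    ds = SiteDataset(
        site_id="<cal>", features=pd.DataFrame({"lp": x}), outcome=pd.Series(y)
    )
    msg = site_newton_step(ds, ["lp"], model.beta)
    se = float(np.sqrt(np.linalg.inv(msg.hessian)[1, 1]))
    slope = float(model.coefficients[0])
    pval = float(2.0 * norm.sf(abs((slope - 1.0) / se)))
    return CalibrationResult(
        slope=slope, std_err=se, p_vs_one=pval, well_calibrated=bool(pval >= 0.05)
    )


def classification_discrepancy(
    predA: Sequence[float],
    predB: Sequence[float],
    thresholdA: float,
    thresholdB: float,
) -> float:
    """Fraction of subjects the two models place in different risk classes.

    Each model dichotomizes at its own threshold (the median prediction on its
    training cohort); ties at the threshold classify as high-risk (>=).
    """
    a = np.asarray(predA, dtype=float)
    b = np.asarray(predB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("prediction length mismatch")
    return float(np.mean((a >= thresholdA) != (b >= thresholdB)))


def km_and_grho(
    time: Sequence[float],
    event: Sequence[float],
    group: Sequence[float],
    rho: float = 0.0,
    horizon_years: float = 2.0,
) -> KMResult:
    """Kaplan-Meier curves per risk group with a G-rho test and odds ratio.

    The G-rho (Fleming-Harrington) family weights the log-rank increments by
    ``S(t)^rho``; rho = 0 is the standard log-rank test. The odds ratio is
    from the 2x2 table of group x event-within-horizon, with the
    Haldane-Anscombe 0.5 correction when any cell is empty and a Woolf
    normal-approximation 95% CI on the log scale.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    g = np.asarray(group, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")

    groups: dict[int, dict] = {}
    for lab in labels:
        mask = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        tl = kmf.event_table.index.to_numpy(dtype=float)
        groups[int(lab)] = {
            "event_times": tl,
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].to_numpy(),
            "n": int(mask.sum()),
        }

    flagged = None
    if e.sum() == 0:
        chi2, pval = np.nan, np.nan
        flagged = "no events in either group: test undefined"
    else:
        m0, m1 = g == labels[0], g == labels[1]
        if rho == 0.0:
            res = logrank_test(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
        else:
            res = logrank_test(
                t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1],
                weightings="fleming-harrington", p=rho, q=0.0,
            )
        chi2, pval = float(res.test_statistic), float(res.p_value)

    died = (e == 1) & (t <= horizon_years)
    table = np.array(
        [
            [np.sum(died & (g == labels[1])), np.sum(~died & (g == labels[1]))],
            [np.sum(died & (g == labels[0])), np.sum(~died & (g == labels[0]))],
        ],
        dtype=float,
    )
    if np.any(table == 0):
        table = table + 0.5
    odds_ratio = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    se_log = np.sqrt(np.sum(1.0 / table))
    ci = (
        float(np.exp(np.log(odds_ratio) - 1.96 * se_log)),
        float(np.exp(np.log(odds_ratio) + 1.96 * se_log)),
    )
    return KMResult(
        groups=groups,
        grho_chi2=chi2,
        grho_p=pval,
        odds_ratio=float(odds_ratio),
        or_ci95=ci,
        flagged=flagged,
    )
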