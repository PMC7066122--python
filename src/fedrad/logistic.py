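"""Multivariate logistic regression: centralized Newton (IRLS) reference and
the federated GLORE fitter.

Both fitters run the same Newton-Raphson iteration from beta = 0 with an
L-infinity convergence rule on the coefficient update and step-halving when a
step would decrease the log-likelihood. The only difference is where the
gradient and Hessian come from: the centralized fitter evaluates them on the
pooled design matrix, while GLORE sums per-site :class:`NewtonMessage`
aggregates. Because sums of site gradients/Hessians equal the pooled ones
exactly, the two fitters share a fixed point and converge to identical
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datasets import SiteDataset
from .federation import NewtonMessage, site_newton_step

__all__ = [
    "LogisticModel",
    "SeparationError",
    "SingularHessianError",
    "fit_logistic_centralized",
    "fit_logistic_glore",
    "predict",
]

# On standardized inputs a coefficient this large signals (quasi-)separation:
# the MLE is drifting to infinity rather than converging.
_SEPARATION_BOUND = 30.0


class SeparationError(RuntimeError):
    """Raised when the data are (quasi-)separated and no finite MLE exists."""


class SingularHessianError(np.linalg.LinAlgError):
    """Raised when the Hessian is singular, typically from collinear columns."""


@dataclass
class LogisticModel:
    feature_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    iterations: int
    converged: bool
    log_likelihood: float
    training_meta: dict = field(default_factory=dict)

    @property
    def beta(self) -> np.ndarray:
        """Full coefficient vector, intercept first."""
        return np.concatenate([[self.intercept], self.coefficients])

    def to_json_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "intercept": float(self.intercept),
            "coefficients": [float(b) for b in self.coefficients],
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "log_likelihood": float(self.log_likelihood),
            "training_meta": self.training_meta,
        }


def _collinear_columns(hessian: np.ndarray, feature_ids: Sequence[str]) -> list[str]:
    names = ["(intercept)", *feature_ids]
    _, r = np.linalg.qr(hessian)
    diag = np.abs(np.diag(r))
    tol = diag.max() * len(diag) * np.finfo(float).eps
    return [names[j] for j in np.nonzero(diag <= tol)[0]]


def _newton(
    message_fn: Callable[[np.ndarray], NewtonMessage],
    feature_ids: Sequence[str],
    tol: float,
    max_iter: int,
    max_halvings: int = 10,
) -> tuple[np.ndarray, int, bool, float]:
    """Damped Newton-Raphson from beta = 0 on an aggregated message source."""
    beta = np.zeros(len(feature_ids) + 1)
    msg = message_fn(beta)
    ll = msg.log_likelihood
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(msg.hessian, msg.gradient)
        except np.linalg.LinAlgError as exc:
            bad = _collinear_columns(msg.hessian, feature_ids)
            raise SingularHessianError(
                f"singular Hessian; collinear columns: {bad or 'unknown'}"
            ) from exc
        step = 1.0
        for _ in range(max_halvings + 1):
            trial = beta + step * delta
            trial_msg = message_fn(trial)
            if trial_msg.log_likelihood >= ll - 1e-12:
                break
            step *= 0.5
        update = step * delta
        beta = beta + update
        msg, ll = trial_msg, trial_msg.log_likelihood
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            raise SeparationError(
                "coefficients diverging (|beta| > 30 on standardized inputs); "
                "data are likely separated"
            )
        if np.max(np.abs(update)) < tol:
            converged = True
            break
    if not converged and ll > -1e-6:
        # perfect fit without a stable coefficient vector: the MLE is at
        # infinity, i.e. the data are completely separated
        raise SeparationError(
            "log-likelihood saturated at 0 without coefficient convergence; "
            "data are separated"
        )
    return beta, iterations, converged, ll


def fit_logistic_centralized(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    feature_ids: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by Newton-Raphson on the pooled data.

    ``X`` holds complete cases (no missing entries); an intercept column is
    added internally. Raises :class:`SingularHessianError` for collinear
    designs and :class:`SeparationError` when no finite MLE exists.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        x = X.to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = list(feature_ids) if feature_ids is not None else [f"x{j}" for j in range(x.shape[1])]
    yv = np.asarray(y, dtype=float)
    if x.shape[0] != yv.shape[0]:
        raise ValueError("X and y length mismatch")
    if not np.all(np.isfinite(x)):
        raise ValueError("X contains missing or non-finite values")
    if len(np.unique(yv)) < 2:
        raise ValueError("outcome has a single class")

    ds = SiteDataset(
        site_id="<pooled>",
        features=pd.DataFrame(x, columns=names),
        outcome=pd.Series(yv),
    )
    beta, iters, converged, ll = _newton(
        lambda b: site_newton_step(ds, names, b), names, tol, max_iter
    )
    return LogisticModel(
        feature_ids=names,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        iterations=iters,
        converged=converged,
        log_likelihood=ll,
        training_meta={"mode": "centralized", "tol": tol, "n": int(len(yv))},
    )


def _sum_messages(messages: Sequence[NewtonMessage]) -> NewtonMessage:
    return NewtonMessage(
        site_id="<coordinator>",
        gradient=np.sum([m.gradient for m in messages], axis=0),
        hessian=np.sum([m.hessian for m in messages], axis=0),
        log_likelihood=float(sum(m.log_likelihood for m in messages)),
        n=int(sum(m.n for m in messages)),
    )


def fit_logistic_glore(
    sites: Sequence[SiteDataset],
    feature_ids: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 25,
    labels: Sequence[pd.Series] | None = None,
) -> LogisticModel:
    """Federated logistic fit by aggregating per-site Newton-Raphson messages.

    Each iteration the coordinator broadcasts beta, every site returns its
    :class:`NewtonMessage`, and the summed gradient/Hessian drive the update
    ``beta <- beta + (sum H_k)^-1 sum g_k``. Sites with zero complete cases
    are dropped with a warning. ``labels`` optionally overrides each site's
    stored outcome (e.g. a derived 2-year survival label).
    """
    import warnings

    names = list(feature_ids)
    site_labels = list(labels) if labels is not None else [None] * len(sites)
    active: list[tuple[SiteDataset, pd.Series | None]] = []
    counts: dict[str, int] = {}
    for ds, lab in zip(sites, site_labels):
        try:
            msg = site_newton_step(ds, names, np.zeros(len(names) + 1), labels=lab)
        except ValueError:
            warnings.warn(f"site {ds.site_id!r} dropped: zero complete cases")
            continue
        counts[ds.site_id] = msg.n
        active.append((ds, lab))
    if not active:
        raise ValueError("no site with complete cases")

    def message_fn(beta: np.ndarray) -> NewtonMessage:
        return _sum_messages(
            [site_newton_step(ds, names, beta, labels=lab) for ds, lab in active]
        )

    first = message_fn(np.zeros(len(names) + 1))
    # pooled outcome must contain both classes: at beta=0 the gradient's
    # intercept component is sum(y) - n/2, which hits +-n/2 iff one class
    if abs(first.gradient[0]) >= first.n / 2.0 - 1e-9:
        raise ValueError("pooled outcome has a single class")

    beta, iters, converged, ll = _newton(message_fn, names, tol, max_iter)
    return LogisticModel(
        feature_ids=names,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        iterations=iters,
        converged=converged,
        log_likelihood=ll,
        training_meta={"mode": "distributed", "tol": tol, "complete_cases": counts},
    )


def predict(model: LogisticModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predicted event probabilities ``sigmoid(intercept + X beta)``."""
    if isinstance(X, pd.DataFrame):
        missing = set(model.feature_ids) - set(X.columns)
        if missing:
            raise KeyError(f"missing model features: {sorted(missing)}")
        x = X[model.feature_ids].to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    eta = model.intercept + x @ model.coefficients
    return 1.0 / (1.0 + np.exp(-eta))
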