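"""Ridge-penalized binary logistic regression, fit by damped Newton steps.

This is the classifier underlying the exhaustive descriptor-subset search.
It maximizes

    L(w, b) = sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ] - lambda/2 ||w||^2

with p_i = sigmoid(w.x_i + b); the intercept b is unpenalized. Labels are
mapped attractant -> 1, non-attractant -> 0 internally (the +/-1 coding used
in some toolkits is an I/O convention only). Starting from w = 0, full
Newton steps are taken with step-halving whenever a step would decrease the
penalized log-likelihood, so the objective is non-decreasing across
iterations. With lambda > 0 the objective is strictly concave and the
optimum is unique and finite even on separable data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core_data import LabeledTable, ValidationError, register_report_kind

__all__ = ["LogisticModel", "fit", "predict_proba", "penalized_loglik"]

_P_EPS = 1e-12  # probability clamp inside the log-likelihood only


@register_report_kind
@dataclass
class LogisticModel:
    descriptor_names: list[str]
    weights: list[float]
    intercept: float
    ridge_lambda: float
    converged: bool
    n_iterations: int

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.descriptor_names):
            raise ValidationError("one weight per descriptor required")


def penalized_loglik(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, lam: float
) -> float:
    p = np.clip(expit(X @ w + b), _P_EPS, 1 - _P_EPS)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return ll - 0.5 * lam * float(w @ w)


def fit(
    table: LabeledTable,
    descriptors: tuple[str, ...] | list[str],
    ridge_lambda: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticModel:
    """Fit the penalized model on ``table`` restricted to ``descriptors``.

    Deterministic (zero initialization). Non-convergence within ``max_iter``
    is reported via the ``converged`` flag, never raised.
    """
    descriptors = list(descriptors)
    y = table.labels_binary().astype(float)
    X = table.matrix(descriptors)
    beta, converged, it = fit_arrays(
        X, y, ridge_lambda=ridge_lambda, tol=tol, max_iter=max_iter
    )
    p = X.shape[1]
    return LogisticModel(
        descriptor_names=descriptors,
        weights=[float(v) for v in beta[:p]],
        intercept=float(beta[p]),
        ridge_lambda=float(ridge_lambda),
        converged=converged,
        n_iterations=it,
    )


def fit_arrays(
    X: np.ndarray,
    y: np.ndarray,
    ridge_lambda: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, bool, int]:
    """Newton solver on raw arrays; returns ([w, b], converged, iterations)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValidationError("both classes must be present to fit")
    n, p = X.shape
    lam = float(ridge_lambda)
    if lam < 0:
        raise ValidationError("ridge_lambda must be >= 0")

    beta = np.zeros(p + 1)  # [w, b]
    Xa = np.hstack([X, np.ones((n, 1))])
    pen = np.append(np.full(p, lam), 0.0)  # intercept unpenalized

    ll = penalized_loglik(X, y, beta[:p], beta[p], lam)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prob = expit(Xa @ beta)
        grad = Xa.T @ (y - prob) - pen * beta
        if np.max(np.abs(grad)) <= tol:
            converged = True
            it -= 1
            break
        W = prob * (1 - prob)
        H = (Xa * W[:, None]).T @ Xa + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving damping: never accept a decrease in the objective
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            ll_new = penalized_loglik(X, y, cand[:p], cand[p], lam)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        ll = penalized_loglik(X, y, beta[:p], beta[p], lam)
        prob = expit(Xa @ beta)
        grad = Xa.T @ (y - prob) - pen * beta
        if np.max(np.abs(grad)) <= tol:
            converged = True
            break

    return beta, converged, it


def expit_scores(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """Probabilities for a raw feature matrix in the model's column order."""
    z = np.asarray(X, dtype=float) @ np.asarray(model.weights, dtype=float)
    return expit(z + model.intercept)


def predict_proba(model: LogisticModel, table: LabeledTable) -> np.ndarray:
    """Per-compound probability of the attractant class."""
    for d in model.descriptor_names:
        try:
            table.column(d)
        except ValidationError as exc:
            raise ValidationError(f"model descriptor {d!r} missing: {exc}") from None
    X = table.matrix(model.descriptor_names)
    z = X @ np.asarray(model.weights, dtype=float) + model.intercept
    return expit(z)
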