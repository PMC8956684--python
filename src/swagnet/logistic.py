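"""Ridge-stabilized logistic regression and frozen-model prediction.

Small biomarker panels on strongly separable cohorts routinely produce
complete separation, under which maximum-likelihood slopes diverge. The
fitter therefore adds a fixed, very small ridge penalty on the slopes
(none on the intercept) so that coefficients stay finite while
classifications and, on non-separated data, coefficient values are
indistinguishable from plain maximum likelihood.

The solver is damped Newton-Raphson on the penalized log-likelihood; for
the handful-of-features models used throughout the package it converges
in a few iterations and is cross-checked against an independent
maximum-likelihood implementation in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .cohort import LabeledCohort, Standardization, fit_standardization
from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = ["LogisticFit", "fit_logistic", "FrozenModel", "fit_and_predict"]

#: default ridge applied to slopes only
DEFAULT_RIDGE = 1e-6
#: |slope| above which (on a standardized design) separation is flagged
_SEPARATION_SLOPE = 10.0


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic model: P(y=1|x) = expit(intercept + x @ slopes)."""

    intercept: float
    slopes: np.ndarray
    converged: bool
    separated: bool
    n_iter: int

    @property
    def coef(self) -> np.ndarray:
        """Intercept followed by slopes."""
        return np.concatenate([[self.intercept], self.slopes])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept + np.asarray(X, dtype=float) @ self.slopes)


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE,
                 tol: float = 1e-10, max_iter: int = 100) -> LogisticFit:
    """Fit logistic regression of binary ``y`` on columns of ``X``.

    ``X`` may have zero columns (intercept-only model). The intercept is
    never penalized. Raises ``DataError`` if ``y`` is single-class.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise DataError(f"y length {y.shape} does not match {n} rows")
    if y.min() == y.max():
        raise DataError("logistic fit requires both outcome classes")

    Z = np.column_stack([np.ones(n), X])
    pen = np.zeros(p + 1)
    pen[1:] = ridge
    beta = np.zeros(p + 1)
    beta[0] = np.log(y.mean() / (1 - y.mean()))

    def objective(b):
        eta = Z @ b
        # log-likelihood via logaddexp for numerical safety
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return ll - 0.5 * np.sum(pen * b * b)

    obj = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Z @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = Z.T @ (y - mu) - pen * beta
        hess = (Z * w[:, None]).T @ Z + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_obj = objective(cand)
            if cand_obj >= obj:
                break
            scale /= 2
        improvement = cand_obj - obj
        beta, obj = cand, cand_obj
        if np.max(np.abs(scale * step)) < tol or improvement < 1e-13:
            converged = True
            break

    slopes = beta[1:]
    separated = bool(np.any(np.abs(slopes) > _SEPARATION_SLOPE))
    if separated:
        logger.debug("separation detected (max |slope| = %.1f)",
                     np.abs(slopes).max())
    return LogisticFit(intercept=float(beta[0]), slopes=slopes,
                       converged=converged, separated=separated, n_iter=it)


# ---------------------------------------------------------------------------
# Frozen models: coefficients + training standardization, portable to new data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrozenModel:
    """A fitted panel frozen for later prediction on new cohorts.

    Stores the feature subset, the logistic coefficients estimated on
    the (standardized) training data, and the training means/sds so that
    new data are mapped onto the identical scale before prediction.
    """

    features: tuple
    intercept: float
    slopes: tuple
    means: tuple
    sds: tuple
    cv_error: float | None = None

    def predict_proba(self, cohort: LabeledCohort) -> np.ndarray:
        missing = [f for f in self.features if f not in cohort.feature_ids]
        if missing:
            raise DataError(f"cohort is missing model features: {missing}")
        X = cohort.columns(self.features)
        Xs = (X - np.asarray(self.means)) / np.asarray(self.sds)
        return expit(self.intercept + Xs @ np.asarray(self.slopes))

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "intercept": self.intercept,
            "slopes": list(self.slopes),
            "means": list(self.means),
            "sds": list(self.sds),
            "cv_error": self.cv_error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrozenModel":
        return cls(features=tuple(d["features"]), intercept=float(d["intercept"]),
                   slopes=tuple(float(s) for s in d["slopes"]),
                   means=tuple(float(m) for m in d["means"]),
                   sds=tuple(float(s) for s in d["sds"]),
                   cv_error=d.get("cv_error"))


def freeze_model(features, train: LabeledCohort,
                 cv_error: float | None = None) -> FrozenModel:
    """Standardize on the training cohort, fit, and freeze."""
    features = tuple(features)
    X = train.columns(features)
    std = fit_standardization(X, features)
    fit = fit_logistic(std.transform(X), train.labels)
    return FrozenModel(features=features, intercept=fit.intercept,
                       slopes=tuple(fit.slopes), means=tuple(std.means),
                       sds=tuple(std.sds), cv_error=cv_error)


def fit_and_predict(model_features, train: LabeledCohort,
                    test: LabeledCohort):
    """Fit a panel on ``train`` and predict probabilities on ``test``.

    Standardization parameters come from the training cohort only.
    Returns ``(probabilities, FrozenModel)``.
    """
    frozen = freeze_model(model_features, train)
    return frozen.predict_proba(test), frozen
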