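"""Held-out evaluation: confusion-table metrics at a probability cutoff,
ROC curves, the model-set ROC region, events-per-variable, and an
L1-penalized (lasso) logistic baseline with percentile-bootstrap
confidence intervals."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import LabeledCohort, fit_standardization
from .errors import ConfigError, DataError
from .logistic import fit_and_predict
from .swag import ModelSet

logger = logging.getLogger(__name__)

__all__ = ["MetricsReport", "confusion_metrics", "roc_curve", "auc",
           "RocRegion", "roc_region", "epv", "lasso_baseline",
           "evaluate_model_set"]


@dataclass(frozen=True)
class MetricsReport:
    """Classification metrics at a fixed probability cutoff.

    Ratios with zero denominators (e.g. sensitivity when no positives
    are present) are reported as ``nan`` and listed in ``undefined``
    rather than silently set to 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def undefined(self) -> tuple:
        out = []
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            if np.isnan(getattr(self, name)):
                out.append(name)
        return tuple(out)

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "ppv": self.ppv,
                "npv": self.npv, "tp": self.tp, "fp": self.fp,
                "tn": self.tn, "fn": self.fn, "cutoff": self.cutoff}


def confusion_metrics(labels, probabilities,
                      cutoff: float = 0.5) -> MetricsReport:
    """Threshold probabilities at ``cutoff`` (>= counts as positive) and
    tabulate the confusion counts."""
    labels = np.asarray(labels, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    if labels.shape != probabilities.shape:
        raise DataError("labels and probabilities must have equal length")
    if not 0 < cutoff < 1:
        raise ConfigError("cutoff must lie in (0, 1)")
    predicted = probabilities >= cutoff
    report = MetricsReport(
        tp=int(np.sum(predicted & (labels == 1))),
        fp=int(np.sum(predicted & (labels == 0))),
        tn=int(np.sum(~predicted & (labels == 0))),
        fn=int(np.sum(~predicted & (labels == 1))),
        cutoff=cutoff,
    )
    if report.undefined:
        logger.warning("undefined metrics (zero denominator): %s",
                       ", ".join(report.undefined))
    return report


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_curve(labels, scores):
    """ROC points over all distinct score thresholds, plus the (0,0) and
    (1,1) endpoints. Returns ``(fpr, tpr)`` arrays ordered by ascending
    false-positive rate."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # keep only the last index of each tied score block
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos, 1.0]
    fpr = np.r_[0.0, fps[distinct] / n_neg, 1.0]
    return fpr, tpr


def auc(labels, scores) -> float:
    """Area under the ROC curve (trapezoid rule).

    Equals the probability that a random positive outranks a random
    negative, with ties counted half.
    """
    fpr, tpr = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class RocRegion:
    """Pointwise envelope of a family of ROC curves on a common grid."""

    fpr_grid: np.ndarray
    tpr_curves: np.ndarray   # one row per model
    lower: np.ndarray
    upper: np.ndarray

    def contains(self, fpr, tpr) -> bool:
        lo = np.interp(fpr, self.fpr_grid, self.lower)
        hi = np.interp(fpr, self.fpr_grid, self.upper)
        return bool(lo - 1e-12 <= tpr <= hi + 1e-12)


def _interp_roc(fpr, tpr, grid):
    """Right-continuous step interpolation of an ROC curve onto a grid
    (the TPR attained at the largest FPR <= grid point)."""
    idx = np.searchsorted(fpr, grid, side="right") - 1
    return tpr[np.clip(idx, 0, len(tpr) - 1)]


def roc_region(curves, grid=None) -> RocRegion:
    """Envelope of ``curves`` (iterable of (fpr, tpr) pairs).

    All curves are interpolated onto a common FPR grid (union of the
    curves' FPR values by default); the region's bounds are the
    pointwise minimum and maximum TPR.
    """
    curves = list(curves)
    if not curves:
        raise DataError("roc_region needs at least one curve")
    if grid is None:
        grid = np.unique(np.concatenate([np.asarray(f) for f, _ in curves]))
    tpr_rows = np.vstack([_interp_roc(np.asarray(f), np.asarray(t), grid)
                          for f, t in curves])
    return RocRegion(fpr_grid=np.asarray(grid), tpr_curves=tpr_rows,
                     lower=tpr_rows.min(axis=0), upper=tpr_rows.max(axis=0))


# ---------------------------------------------------------------------------
# Events per variable
# ---------------------------------------------------------------------------

def epv(n_events: int, n_variables: int) -> float:
    """Events per variable: the smaller outcome-category count divided by
    the number of model variables; a rough external-validity index (the
    higher, the safer the model size for the available events)."""
    if n_variables <= 0:
        raise ConfigError("n_variables must be positive")
    if n_events <= 0:
        raise ConfigError("n_events must be positive")
    return n_events / n_variables


# ---------------------------------------------------------------------------
# Lasso baseline
# ---------------------------------------------------------------------------

def lasso_baseline(train: LabeledCohort, test: LabeledCohort,
                   n_boot: int = 2000, seed: int = 0, cv_folds: int = 10,
                   n_penalties: int = 30):
    """L1-penalized logistic baseline with bootstrap CIs.

    The penalty is chosen by stratified ``cv_folds``-fold CV
    misclassification on the standardized training data (mirroring the
    error criterion of the wrapper search); nonzero-coefficient features
    are reported, test metrics are computed at the 0.5 cutoff, and 95%
    percentile bootstrap confidence intervals for each metric come from
    resampling the test set ``n_boot`` times.

    Returns a dict with ``selected_features``, ``report``, ``ci``,
    ``C`` (inverse penalty) and ``probabilities``.
    """
    train.require_both_classes()
    std = fit_standardization(train.matrix, train.feature_ids)
    Xtr = std.transform(train.matrix)
    ytr = train.labels
    Cs = np.logspace(-2, 2, n_penalties)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xtr, ytr))
    cv_err = np.zeros(len(Cs))
    for i, C in enumerate(Cs):
        errs = []
        for tr, te in folds:
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=2000)
            clf.fit(Xtr[tr], ytr[tr])
            errs.append(np.mean(clf.predict(Xtr[te]) != ytr[te]))
        cv_err[i] = np.mean(errs)
    best_C = float(Cs[int(np.argmin(cv_err))])
    clf = LogisticRegression(l1_ratio=1.0, C=best_C, solver="liblinear",
                             max_iter=2000)
    clf.fit(Xtr, ytr)
    coef = clf.coef_.ravel()
    selected = tuple(f for f, c in zip(train.feature_ids, coef) if c != 0)
    if not selected:
        logger.warning("lasso selected no features; intercept-only baseline")
    Xte = std.transform(test.matrix)
    proba = clf.predict_proba(Xte)[:, 1]
    report = confusion_metrics(test.labels, proba)

    rng = np.random.default_rng(seed)
    names = ("accuracy", "sensitivity", "specificity", "ppv", "npv")
    boot = {name: [] for name in names}
    n_test = test.n_samples
    for _ in range(n_boot):
        idx = rng.integers(n_test, size=n_test)
        rep = confusion_metrics(test.labels[idx], proba[idx])
        for name in names:
            boot[name].append(getattr(rep, name))
    ci = {}
    for name in names:
        vals = np.asarray(boot[name], dtype=float)
        vals = vals[~np.isnan(vals)]
        ci[name] = ((float(np.percentile(vals, 2.5)),
                     float(np.percentile(vals, 97.5)))
                    if len(vals) else (float("nan"), float("nan")))
    return {"selected_features": selected, "report": report, "ci": ci,
            "C": best_C, "probabilities": proba}


# ---------------------------------------------------------------------------
# Model-set evaluation bundle
# ---------------------------------------------------------------------------

def evaluate_model_set(model_set: ModelSet, train: LabeledCohort,
                       test: LabeledCohort, cutoff: float = 0.5):
    """Fit every retained model on ``train`` and evaluate on ``test``.

    Returns a dict with a per-model metrics DataFrame (test error, AUC,
    confusion metrics), the frozen models, per-model ROC curves, the
    joint ROC region, and per-dimension EPV (events = smaller training
    outcome class).
    """
    rows, frozen, curves, aucs = [], [], [], {}
    for m in model_set.models:
        proba, fm = fit_and_predict(m.features, train, test)
        rep = confusion_metrics(test.labels, proba, cutoff=cutoff)
        model_auc = auc(test.labels, proba)
        curves.append(roc_curve(test.labels, proba))
        aucs[m.key] = model_auc
        frozen.append(fm)
        rows.append({"features": "|".join(m.features),
                     "dimension": m.dimension, "cv_error": m.cv_error,
                     "test_error": 1 - rep.accuracy, "auc": model_auc,
                     **{k: v for k, v in rep.as_dict().items()
                        if k not in ("cutoff",)}})
    table = pd.DataFrame(rows)
    n_events = min(train.n_cases, train.n_controls)
    epv_by_dim = {d: epv(n_events, d) for d in model_set.dimensions}
    return {"table": table, "frozen_models": frozen, "roc_curves": curves,
            "roc_region": roc_region(curves), "auc_by_model": aucs,
            "epv_by_dimension": epv_by_dim}
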