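"""Repeated stratified k-fold cross-validated classification error.

The score of a candidate panel is its mean held-out misclassification
proportion at the 0.5 probability cutoff over k folds repeated r times.
Fold standardization parameters are always computed on the training
folds only. Within one search run, the same fold partition (drawn once
from the run seed) is used for every candidate model so that scores are
directly comparable across models and the whole search is deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold

from .cohort import LabeledCohort, fit_standardization
from .errors import ConfigError, DataError
from .logistic import fit_logistic

logger = logging.getLogger(__name__)

__all__ = ["make_folds", "cv_error"]


def make_folds(labels: np.ndarray, k_folds: int, n_repeats: int, seed: int,
               max_retries: int = 20):
    """Stratified (train_idx, test_idx) pairs, k folds x n_repeats.

    Stratification makes single-class training folds essentially
    impossible, but if one occurs (tiny minority classes) the fold set
    is regenerated from a fresh derived seed, with a log message.
    """
    labels = np.asarray(labels)
    if k_folds < 2:
        raise ConfigError("k_folds must be >= 2")
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise DataError("cross-validation requires both classes")
    if k_folds > len(labels):
        raise ConfigError(f"k_folds={k_folds} exceeds n={len(labels)}")
    leave_one_out = k_folds == len(labels)
    for attempt in range(max_retries):
        fold_seed = int((seed + 1_000_003 * attempt) % (2**31 - 1))
        if leave_one_out:
            folds = [(np.delete(np.arange(len(labels)), i), np.array([i]))
                     for i in range(len(labels))] * n_repeats
        else:
            splitter = RepeatedStratifiedKFold(
                n_splits=k_folds, n_repeats=n_repeats, random_state=fold_seed)
            folds = [(tr, te) for tr, te in splitter.split(
                np.zeros((len(labels), 1)), labels)]
        ok = all(labels[tr].min() != labels[tr].max() for tr, _ in folds)
        if ok:
            return folds
        logger.warning("single-class training fold; regenerating folds "
                       "(attempt %d)", attempt + 1)
    raise DataError("could not build folds with both classes in every "
                    "training part")


def cv_error(features, cohort: LabeledCohort, k_folds: int = 10,
             n_repeats: int = 10, seed: int = 0, folds=None) -> float:
    """Mean held-out misclassification of the panel ``features``.

    Pass precomputed ``folds`` to share one partition across many
    candidate panels (as the search does); otherwise folds are drawn
    from ``seed``.
    """
    features = tuple(features)
    X = cohort.columns(features)
    y = cohort.labels
    if folds is None:
        folds = make_folds(y, k_folds, n_repeats, seed)
    fold_errors = []
    for train_idx, test_idx in folds:
        Xtr, ytr = X[train_idx], y[train_idx]
        std = fit_standardization(Xtr) if X.shape[1] else None
        fit = fit_logistic(std.transform(Xtr) if std else Xtr, ytr)
        proba = fit.predict_proba(std.transform(X[test_idx]) if std
                                  else X[test_idx])
        predicted = (proba >= 0.5).astype(int)
        fold_errors.append(float(np.mean(predicted != y[test_idx])))
    return float(np.mean(fold_errors))
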