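"""Labeled expression cohorts: container, TSV round trip, stratified
splitting and design-matrix standardization.

A cohort is a samples x features matrix of continuous expression values
(log-intensity scale) together with a binary outcome per sample
(1 = case, e.g. invasive carcinoma; 0 = control, e.g. normal tissue).
Every downstream stage of the package consumes this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "LabeledCohort",
    "SplitSpec",
    "Standardization",
    "read_cohort",
    "write_cohort",
    "split_cohort",
    "standardize_design",
]


@dataclass(frozen=True)
class LabeledCohort:
    """Expression matrix plus binary labels.

    Parameters
    ----------
    matrix : ndarray, shape (n_samples, n_features)
        Continuous feature values; no missing entries allowed.
    labels : ndarray, shape (n_samples,)
        Binary outcome, values in {0, 1}; 1 marks the case class.
    feature_ids : tuple of str
        Unique feature identifiers, one per matrix column.
    sample_ids : tuple of str
        Unique sample identifiers, one per matrix row.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_ids: tuple
    sample_ids: tuple

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if matrix.ndim != 2:
            raise DataError("expression matrix must be two-dimensional")
        n, p = matrix.shape
        if n == 0:
            raise DataError("empty cohort: matrix has no rows")
        if labels.shape != (n,):
            raise DataError(
                f"labels length {labels.shape} does not match {n} samples"
            )
        if len(self.feature_ids) != p:
            raise DataError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.feature_ids)) != p:
            raise DataError("duplicate feature ids")
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample ids")
        if not np.isfinite(matrix).all():
            raise DataError("matrix contains missing or non-finite values")
        if not np.isin(labels, (0, 1)).all():
            raise DataError("labels must be binary (0/1)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n_samples - self.labels.sum())

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise DataError(f"unknown feature id: {feature_id!r}") from None

    def columns(self, feature_ids) -> np.ndarray:
        """Sub-matrix for the requested features, in the given order."""
        idx = [self.feature_index(f) for f in feature_ids]
        return self.matrix[:, idx]

    def subset(self, row_indices) -> "LabeledCohort":
        """Row subset preserving ids and feature order."""
        row_indices = np.asarray(row_indices, dtype=int)
        return LabeledCohort(
            matrix=self.matrix[row_indices],
            labels=self.labels[row_indices],
            feature_ids=self.feature_ids,
            sample_ids=tuple(self.sample_ids[i] for i in row_indices),
        )

    def require_both_classes(self):
        if self.n_cases == 0 or self.n_controls == 0:
            raise DataError("cohort must contain both outcome classes")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.feature_ids),
                          index=list(self.sample_ids))
        df.index.name = "sample_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, labels) -> "LabeledCohort":
        """Build from a samples x features DataFrame and a label Series
        (aligned on the index) or array."""
        if isinstance(labels, pd.Series):
            labels = labels.reindex(df.index).to_numpy()
        return cls(
            matrix=df.to_numpy(dtype=float),
            labels=np.asarray(labels),
            feature_ids=tuple(df.columns),
            sample_ids=tuple(str(i) for i in df.index),
        )


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: LabeledCohort, matrix_path, labels_path,
                 float_format: str = "%.10g") -> None:
    """Write a cohort as two TSV files.

    The matrix file has a ``sample_id`` index column and one column per
    feature; the label file has columns ``sample_id`` and ``label``.
    """
    cohort.to_frame().to_csv(matrix_path, sep="\t", float_format=float_format)
    pd.DataFrame({"sample_id": list(cohort.sample_ids),
                  "label": cohort.labels}).to_csv(labels_path, sep="\t",
                                                  index=False)


def read_cohort(matrix_path, labels_path) -> LabeledCohort:
    """Read a cohort written by :func:`write_cohort`.

    Raises
    ------
    DataError
        On empty matrices, duplicate ids, or sample ids present in one
        file but not the other (the offending ids are named).
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise DataError(f"empty cohort: {matrix_path} has no sample rows")
    lab = pd.read_csv(labels_path, sep="\t")
    if not {"sample_id", "label"} <= set(lab.columns):
        raise DataError(f"{labels_path} must have columns sample_id, label")
    lab = lab.set_index(lab["sample_id"].astype(str))["label"]
    if lab.index.has_duplicates:
        dupes = sorted(lab.index[lab.index.duplicated()].unique())
        raise DataError(f"duplicate sample ids in label file: {dupes}")
    matrix_ids = [str(i) for i in df.index]
    missing = [s for s in matrix_ids if s not in lab.index]
    if missing:
        raise DataError(f"label file missing sample ids: {missing}")
    extra = [s for s in lab.index if s not in set(matrix_ids)]
    if extra:
        raise DataError(f"label file has unknown sample ids: {extra}")
    labels = lab.loc[matrix_ids].to_numpy()
    df.index = matrix_ids
    return LabeledCohort.from_frame(df, labels)


# ---------------------------------------------------------------------------
# Train/test splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """How to split a cohort into training and test subsets.

    Exactly one of ``test_fraction`` or ``test_size`` must be set. The
    split is class-stratified by default, with per-class test counts
    assigned by largest-remainder rounding so the class balance of each
    part matches the cohort as closely as integer counts allow.
    """

    test_fraction: float | None = None
    test_size: int | None = None
    stratified: bool = True
    seed: int = 0

    def resolve_test_size(self, n: int) -> int:
        if (self.test_fraction is None) == (self.test_size is None):
            raise ConfigError("set exactly one of test_fraction / test_size")
        if self.test_size is not None:
            size = int(self.test_size)
        else:
            if not 0 < self.test_fraction < 1:
                raise ConfigError("test_fraction must lie in (0, 1)")
            size = int(round(self.test_fraction * n))
        if not 2 <= size <= n - 2:
            raise ConfigError(f"test size {size} out of range for n={n}")
        return size


def _largest_remainder(counts: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` among classes proportionally to ``counts``."""
    quotas = counts * total / counts.sum()
    base = np.floor(quotas).astype(int)
    remainder = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:remainder]] += 1
    return base


def split_cohort(cohort: LabeledCohort, spec: SplitSpec):
    """Stratified train/test partition of a cohort.

    Returns ``(train, test)`` cohorts that are disjoint and exhaustive.
    Reproducible under a fixed ``spec.seed``.
    """
    cohort.require_both_classes()
    n = cohort.n_samples
    test_size = spec.resolve_test_size(n)
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        class_counts = np.array([cohort.n_controls, cohort.n_cases])
        test_per_class = _largest_remainder(class_counts, test_size)
        test_idx = []
        for cls, n_test_cls in zip((0, 1), test_per_class):
            cls_idx = np.flatnonzero(cohort.labels == cls)
            if n_test_cls < 1 or n_test_cls > len(cls_idx) - 1:
                raise DataError(
                    f"class {cls} too small to stratify a test set of {test_size}"
                )
            test_idx.extend(rng.choice(cls_idx, size=n_test_cls, replace=False))
    else:
        test_idx = rng.choice(n, size=test_size, replace=False)
    test_mask = np.zeros(n, dtype=bool)
    test_mask[np.asarray(test_idx, dtype=int)] = True
    train = cohort.subset(np.flatnonzero(~test_mask))
    test = cohort.subset(np.flatnonzero(test_mask))
    train.require_both_classes()
    test.require_both_classes()
    return train, test


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardization:
    """Per-feature centering/scaling parameters (population sd, ddof=0)."""

    means: np.ndarray
    sds: np.ndarray
    feature_ids: tuple = field(default=())

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.means) / self.sds

    def inverse(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix, dtype=float) * self.sds + self.means

    def subset(self, feature_ids) -> "Standardization":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return Standardization(self.means[idx], self.sds[idx],
                               tuple(feature_ids))


def fit_standardization(matrix: np.ndarray, feature_ids=()) -> Standardization:
    matrix = np.asarray(matrix, dtype=float)
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0)
    if feature_ids and np.any(sds == 0):
        bad = [f for f, s in zip(feature_ids, sds) if s == 0]
        raise DataError(f"constant features cannot be standardized: {bad}")
    if np.any(sds == 0):
        raise DataError("constant column cannot be standardized")
    return Standardization(means, sds, tuple(feature_ids))


def standardize_design(cohort: LabeledCohort):
    """Center and rescale every column to mean 0, sd 1.

    Returns ``(standardized_cohort, Standardization)`` so the transform
    can be inverted or re-applied to new data.
    """
    std = fit_standardization(cohort.matrix, cohort.feature_ids)
    return replace(cohort, matrix=std.transform(cohort.matrix)), std
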