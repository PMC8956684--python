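import numpy as np
import pytest

from swagnet import CohortConfig, LabeledCohort, generate_cohort


def make_cohort(matrix, labels, prefix="f"):
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    return LabeledCohort(
        matrix=matrix,
        labels=np.asarray(labels, dtype=int),
        feature_ids=tuple(f"{prefix}{j}" for j in range(p)),
        sample_ids=tuple(f"s{i}" for i in range(n)),
    )


@pytest.fixture
def separator_cohort():
    """20 samples: feature f0 equals the label recoded +-1, f1..f3 noise."""
    rng = np.random.default_rng(11)
    labels = np.array([0, 1] * 10)
    matrix = np.column_stack([
        np.where(labels == 1, 1.0, -1.0) + 0.01 * rng.standard_normal(20),
        rng.standard_normal(20),
        rng.standard_normal(20),
        rng.standard_normal(20),
    ])
    return make_cohort(matrix, labels)


@pytest.fixture
def imbalanced_cohort():
    """125 samples (70 controls / 55 cases), 12 continuous features, two
    of them informative -- a cohort-scale class imbalance."""
    cfg = CohortConfig(n_samples=125, n_features=12, prevalence=0.44,
                       effects={0: 2.0, 1: -2.0}, seed=42)
    cohort = generate_cohort(cfg)
    # pin the exact 70/55 class composition by relabeling deterministically
    rng = np.random.default_rng(7)
    labels = np.zeros(125, dtype=int)
    case_rows = rng.choice(125, size=55, replace=False)
    labels[case_rows] = 1
    # keep features informative for the pinned labels
    matrix = cohort.matrix.copy()
    matrix[:, 0] += 1.5 * labels
    matrix[:, 1] -= 1.5 * labels
    return make_cohort(matrix, labels, prefix="marker-")
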