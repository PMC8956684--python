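"""The sparse wrapper search: screening, dimension growth, retention.

The search wraps a classification learner (logistic regression) in a
greedy combinatorial exploration. It first scores every one-feature
model by repeated k-fold cross-validation and keeps the features whose
error falls at or below the empirical alpha-quantile of all one-feature
errors (the screening step). For each dimension d = 2..p_max it then
builds candidate models by taking a retained model of dimension d-1 and
adding one screened feature it does not already contain, scores all
candidates, and again keeps those at or below the alpha-quantile of the
candidate errors. The output is not a single model but a set of
near-equivalent sparse models per dimension, which is the object all
effect and network analysis downstream consumes.

The model/results surface (`SparseWrapperSearch` / `SwagResults`)
mirrors the statsmodels convention: build the search from data, call
``fit()``, and read estimates, diagnostics and ``summary()`` off the
results object.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import LabeledCohort
from .crossval import cv_error, make_folds
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "SwagConfig", "ScoredModel", "ModelSet", "ScreeningResult",
    "screen_features", "grow_dimension", "run_swag", "select_model_set",
    "SparseWrapperSearch", "SwagResults",
    "write_model_set_json", "read_model_set_json",
    "write_model_table", "read_model_table",
]


@dataclass(frozen=True)
class SwagConfig:
    """Search hyper-parameters.

    Parameters
    ----------
    p_max : int
        Maximum model dimension to grow to.
    alpha : float in (0, 1)
        Retention proportion: models with CV error at or below the
        empirical alpha-quantile of their dimension's errors survive.
        Small values (0.01-0.1) keep only the strongest models.
    m_models : int or None
        Number of candidate models built per dimension; ``None`` means
        exhaustive enumeration of all achievable extensions.
    k_folds, n_repeats : int
        Cross-validation folds and repetitions per model score.
    seed : int
        Drives fold assignment and candidate sampling.
    learner : str
        Classification procedure; only ``"logistic"`` ships.
    """

    p_max: int = 5
    alpha: float = 0.05
    m_models: int | None = 100
    k_folds: int = 10
    n_repeats: int = 10
    seed: int = 0
    learner: str = "logistic"

    def __post_init__(self):
        if self.p_max < 1:
            raise ConfigError("p_max must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.m_models is not None and self.m_models < 1:
            raise ConfigError("m_models must be >= 1 (or None for exhaustive)")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if self.learner != "logistic":
            raise ConfigError(f"unknown learner {self.learner!r}")

    def to_dict(self) -> dict:
        return {"p_max": self.p_max, "alpha": self.alpha,
                "m_models": self.m_models, "k_folds": self.k_folds,
                "n_repeats": self.n_repeats, "seed": self.seed,
                "learner": self.learner}


@dataclass(frozen=True)
class ScoredModel:
    """A feature subset with its cross-validated error."""

    features: tuple
    cv_error: float

    def __post_init__(self):
        feats = tuple(self.features)
        if len(set(feats)) != len(feats):
            raise ConfigError(f"duplicate features in model: {feats}")
        object.__setattr__(self, "features", feats)
        if not 0 <= self.cv_error <= 1:
            raise ConfigError("cv_error must lie in [0, 1]")

    @property
    def dimension(self) -> int:
        return len(self.features)

    @property
    def key(self) -> frozenset:
        return frozenset(self.features)


@dataclass(frozen=True)
class ScreeningResult:
    """Dimension-1 survivors plus the full error table and threshold."""

    retained: tuple           # feature ids surviving screening
    errors: dict              # feature id -> cv error (all p features)
    threshold: float          # alpha-quantile retention cutoff


@dataclass(frozen=True)
class ModelSet:
    """Per-dimension retained models: the search output.

    ``models_by_dimension`` maps dimension -> tuple of ScoredModel,
    each sorted by (cv_error, features). ``screened_features`` are the
    dimension-1 survivors; every feature of any larger model belongs to
    it.
    """

    models_by_dimension: dict
    screened_features: tuple
    thresholds: dict = field(default_factory=dict)
    config: SwagConfig | None = None
    seed: int | None = None

    def __post_init__(self):
        screened = set(self.screened_features)
        for d, models in self.models_by_dimension.items():
            keys = [m.key for m in models]
            if len(set(keys)) != len(keys):
                raise DataError(f"duplicate feature sets at dimension {d}")
            for m in models:
                if m.dimension != d:
                    raise DataError(
                        f"model {m.features} filed under dimension {d}")
                if d >= 2 and not set(m.features) <= screened:
                    raise DataError(
                        f"model {m.features} uses unscreened features")

    @property
    def dimensions(self) -> tuple:
        return tuple(sorted(self.models_by_dimension))

    @property
    def models(self) -> tuple:
        """All retained models across dimensions, ascending dimension."""
        out = []
        for d in self.dimensions:
            out.extend(self.models_by_dimension[d])
        return tuple(out)

    def __len__(self) -> int:
        return sum(len(v) for v in self.models_by_dimension.values())

    @property
    def feature_ids(self) -> tuple:
        """Distinct features appearing in at least one model."""
        seen = {}
        for m in self.models:
            for f in m.features:
                seen[f] = None
        return tuple(seen)

    def containing(self, feature_id: str) -> tuple:
        return tuple(m for m in self.models if feature_id in m.features)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"features": "|".join(m.features), "dimension": m.dimension,
                 "cv_error": m.cv_error} for m in self.models]
        return pd.DataFrame(rows, columns=["features", "dimension",
                                           "cv_error"])


# ---------------------------------------------------------------------------
# Retention rule
# ---------------------------------------------------------------------------

def _retention_threshold(errors, alpha: float) -> float:
    """Empirical alpha-quantile of the candidate errors.

    The ``higher`` order statistic is used so the threshold is always an
    observed error: retention keeps at least the best ceil(alpha * n)
    models (plus ties), and alpha -> 1 keeps everything.
    """
    return float(np.quantile(np.asarray(errors, dtype=float), alpha,
                             method="higher"))


def _retain(models, alpha: float):
    """Keep models with error <= the alpha-quantile; ties all retained."""
    errors = [m.cv_error for m in models]
    threshold = _retention_threshold(errors, alpha)
    kept = [m for m in models if m.cv_error <= threshold]
    kept.sort(key=lambda m: (m.cv_error, m.features))
    return tuple(kept), threshold


# ---------------------------------------------------------------------------
# Search stages
# ---------------------------------------------------------------------------

def screen_features(cohort: LabeledCohort, config: SwagConfig,
                    folds=None) -> ScreeningResult:
    """Score every one-feature model and keep the best alpha-fraction."""
    if cohort.n_features == 0:
        raise DataError("cohort has no features to screen")
    cohort.require_both_classes()
    if folds is None:
        folds = make_folds(cohort.labels, config.k_folds, config.n_repeats,
                           config.seed)
    errors = {f: cv_error((f,), cohort, folds=folds)
              for f in cohort.feature_ids}
    threshold = _retention_threshold(list(errors.values()), config.alpha)
    retained = tuple(f for f in cohort.feature_ids
                     if errors[f] <= threshold)
    logger.info("screening: %d/%d features retained (threshold %.4f)",
                len(retained), cohort.n_features, threshold)
    return ScreeningResult(retained=retained, errors=errors,
                           threshold=threshold)


def _achievable(prev_retained, screened) -> set:
    """All distinct extensions of previous models by one screened feature."""
    out = set()
    for m in prev_retained:
        base = set(m.features)
        for f in screened:
            if f not in base:
                out.add(frozenset(base | {f}))
    return out


def grow_dimension(prev_retained, screened, d: int, config: SwagConfig,
                   rng: np.random.Generator):
    """Candidate feature sets of dimension ``d``.

    Each candidate is a model sampled uniformly (with replacement) from
    the previous dimension's retained models, extended by one screened
    feature it does not contain; duplicates are removed after formation.
    When the number of distinct achievable combinations does not exceed
    ``m_models``, the exhaustive distinct set is returned instead.
    """
    if d < 2:
        raise ConfigError("grow_dimension applies to dimensions >= 2")
    if not prev_retained:
        raise DataError("no retained models to grow from")
    achievable = _achievable(prev_retained, screened)
    if not achievable:
        logger.warning("dimension %d: no screened feature extends any "
                       "model; stopping growth", d)
        return []
    ordered_achievable = sorted(tuple(sorted(s)) for s in achievable)
    if config.m_models is None or len(achievable) <= config.m_models:
        return ordered_achievable
    prev = list(prev_retained)
    screened = list(screened)
    seen = set()
    out = []
    max_draws = 50 * config.m_models
    draws = 0
    while len(out) < config.m_models and draws < max_draws:
        draws += 1
        base = prev[rng.integers(len(prev))]
        extras = [f for f in screened if f not in base.features]
        if not extras:
            continue
        cand = frozenset(base.features) | {extras[rng.integers(len(extras))]}
        if cand not in seen:
            seen.add(cand)
            out.append(tuple(sorted(cand)))
    if len(out) < config.m_models:
        logger.warning("dimension %d: only %d distinct candidates found "
                       "after %d draws", d, len(out), draws)
    return out


def run_swag(cohort: LabeledCohort, config: SwagConfig) -> ModelSet:
    """Full search: screening then growth/retention up to ``p_max``."""
    cohort.require_both_classes()
    folds = make_folds(cohort.labels, config.k_folds, config.n_repeats,
                       config.seed)
    rng = np.random.default_rng(config.seed)
    screening = screen_features(cohort, config, folds=folds)
    score_cache = {frozenset((f,)): e for f, e in screening.errors.items()}

    by_dim = {1: tuple(sorted(
        (ScoredModel((f,), screening.errors[f]) for f in screening.retained),
        key=lambda m: (m.cv_error, m.features)))}
    thresholds = {1: screening.threshold}

    for d in range(2, config.p_max + 1):
        candidates = grow_dimension(by_dim[d - 1], screening.retained, d,
                                    config, rng)
        if not candidates:
            break
        scored = []
        for feats in candidates:
            key = frozenset(feats)
            if key not in score_cache:
                score_cache[key] = cv_error(feats, cohort, folds=folds)
            scored.append(ScoredModel(tuple(feats), score_cache[key]))
        kept, threshold = _retain(scored, config.alpha)
        logger.info("dimension %d: %d/%d candidates retained "
                    "(threshold %.4f)", d, len(kept), len(scored), threshold)
        by_dim[d] = kept
        thresholds[d] = threshold

    return ModelSet(models_by_dimension=by_dim,
                    screened_features=screening.retained,
                    thresholds=thresholds, config=config, seed=config.seed)


def select_model_set(model_set: ModelSet, dims=None,
                     max_test_error: float | None = None,
                     test_errors: dict | None = None) -> ModelSet:
    """Post-processing subset: restrict dimensions, optionally cap a
    per-model test error (``test_errors`` maps frozenset(features) ->
    error). Ordering by cv_error is preserved."""
    if dims is None:
        dims = model_set.dimensions
    dims = sorted(set(dims))
    bad = [d for d in dims if d not in model_set.models_by_dimension]
    if bad:
        raise ConfigError(f"dimensions {bad} not present in model set")
    by_dim = {}
    for d in dims:
        kept = model_set.models_by_dimension[d]
        if max_test_error is not None:
            if test_errors is None:
                raise ConfigError("max_test_error requires test_errors")
            kept = tuple(m for m in kept
                         if test_errors[m.key] <= max_test_error)
        if kept:
            by_dim[d] = kept
    if not by_dim:
        logger.warning("model-set selection produced an empty set")
    return replace(model_set, models_by_dimension=by_dim,
                   thresholds={d: model_set.thresholds.get(d) for d in by_dim})


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_model_set_json(model_set: ModelSet, path) -> None:
    payload = {
        "screened_features": list(model_set.screened_features),
        "thresholds": {str(d): t for d, t in model_set.thresholds.items()},
        "seed": model_set.seed,
        "config": model_set.config.to_dict() if model_set.config else None,
        "models": [{"features": list(m.features), "cv_error": m.cv_error}
                   for m in model_set.models],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model_set_json(path) -> ModelSet:
    with open(path) as fh:
        payload = json.load(fh)
    models = [ScoredModel(tuple(m["features"]), float(m["cv_error"]))
              for m in payload["models"]]
    if not models:
        raise DataError(f"model file {path} contains no models")
    by_dim = {}
    for m in models:
        by_dim.setdefault(m.dimension, []).append(m)
    by_dim = {d: tuple(sorted(v, key=lambda m: (m.cv_error, m.features)))
              for d, v in by_dim.items()}
    config = (SwagConfig(**payload["config"]) if payload.get("config")
              else None)
    return ModelSet(
        models_by_dimension=by_dim,
        screened_features=tuple(payload["screened_features"]),
        thresholds={int(d): t for d, t in payload["thresholds"].items()},
        config=config, seed=payload.get("seed"))


def write_model_table(model_set: ModelSet, path) -> None:
    """Flat one-model-per-row TSV (pipe-joined features)."""
    model_set.to_frame().to_csv(path, sep="\t", index=False)


def read_model_table(path) -> ModelSet:
    """Read a one-model-per-row TSV with ``features`` (pipe-joined) and
    optional ``cv_error`` / ``dimension`` columns.

    Useful for re-analysing externally published model lists; screened
    features default to the union of all model features.
    """
    df = pd.read_csv(path, sep="\t")
    if "features" not in df.columns:
        raise DataError(f"{path}: expected a 'features' column")
    if df.empty:
        raise DataError(f"model table {path} is empty")
    models = []
    for _, row in df.iterrows():
        feats = tuple(str(row["features"]).split("|"))
        err = float(row["cv_error"]) if "cv_error" in df.columns else 0.0
        models.append(ScoredModel(feats, err))
    by_dim = {}
    for m in models:
        by_dim.setdefault(m.dimension, []).append(m)
    by_dim = {d: tuple(sorted(v, key=lambda m: (m.cv_error, m.features)))
              for d, v in by_dim.items()}
    screened = []
    seen = set()
    for m in models:
        for f in m.features:
            if f not in seen:
                seen.add(f)
                screened.append(f)
    return ModelSet(models_by_dimension=by_dim,
                    screened_features=tuple(screened))


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class SparseWrapperSearch:
    """Sparse wrapper model search over a labeled cohort.

    Parameters mirror :class:`SwagConfig`; the cohort passed here is the
    training data the search learns on.

    Examples
    --------
    >>> search = SparseWrapperSearch(train, p_max=3, alpha=0.1, seed=7)
    >>> res = search.fit()
    >>> res.summary()          # doctest: +SKIP
    """

    def __init__(self, cohort: LabeledCohort, p_max: int = 5,
                 alpha: float = 0.05, m_models: int | None = 100,
                 k_folds: int = 10, n_repeats: int = 10, seed: int = 0,
                 learner: str = "logistic"):
        self.cohort = cohort
        self.config = SwagConfig(p_max=p_max, alpha=alpha, m_models=m_models,
                                 k_folds=k_folds, n_repeats=n_repeats,
                                 seed=seed, learner=learner)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str,
                       **kwargs) -> "SparseWrapperSearch":
        """Build from a DataFrame whose ``label_column`` holds the
        binary outcome and whose remaining columns are features."""
        labels = df[label_column].to_numpy()
        features = df.drop(columns=[label_column])
        cohort = LabeledCohort.from_frame(features, labels)
        return cls(cohort, **kwargs)

    def fit(self) -> "SwagResults":
        model_set = run_swag(self.cohort, self.config)
        return SwagResults(self, model_set)


class SwagResults:
    """Results of a sparse wrapper search.

    Carries the retained :class:`ModelSet` and exposes the downstream
    analyses — effect profiles, synonym detection, co-occurrence
    networks, held-out evaluation — as methods, so the full study reads
    off one object.
    """

    def __init__(self, model: SparseWrapperSearch, model_set: ModelSet):
        self.model = model
        self.model_set = model_set

    # -- selection ------------------------------------------------------
    def select(self, dims=None, max_test_error=None,
               test_errors=None) -> "SwagResults":
        subset = select_model_set(self.model_set, dims=dims,
                                  max_test_error=max_test_error,
                                  test_errors=test_errors)
        return SwagResults(self.model, subset)

    # -- downstream analyses (lazy imports avoid module cycles) ---------
    def effect_profiles(self, min_occurrence: float = 0.10,
                        dims=None) -> pd.DataFrame:
        from .effects import effect_table
        ms = (self.model_set if dims is None
              else select_model_set(self.model_set, dims=dims))
        return effect_table(ms, self.model.cohort,
                            min_occurrence=min_occurrence)

    def network(self, n_boot: int = 5000, seed: int | None = None):
        from .network import build_network, pairwise_correlations
        from .effects import effect_profiles as _profiles
        profiles = _profiles(self.model_set, self.model.cohort)
        correlations = pairwise_correlations(
            self.model_set, self.model.cohort, n_boot=n_boot,
            seed=self.model.config.seed if seed is None else seed)
        return build_network(self.model_set, profiles, correlations)

    def focal_network(self, focal_feature: str):
        from .network import focal_subnetwork
        return focal_subnetwork(focal_feature, self.model_set,
                                self.model.cohort)

    def evaluate(self, test: LabeledCohort, cutoff: float = 0.5):
        from .metrics import evaluate_model_set
        return evaluate_model_set(self.model_set, self.model.cohort, test,
                                  cutoff=cutoff)

    def frozen_models(self):
        from .logistic import freeze_model
        return [freeze_model(m.features, self.model.cohort, m.cv_error)
                for m in self.model_set.models]

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        ms = self.model_set
        cfg = self.model.config
        lines = [
            "Sparse wrapper search results",
            "=" * 64,
            f"training samples: {self.model.cohort.n_samples} "
            f"({self.model.cohort.n_cases} cases / "
            f"{self.model.cohort.n_controls} controls)",
            f"features screened: {self.model.cohort.n_features} -> "
            f"{len(ms.screened_features)} retained "
            f"(alpha = {cfg.alpha}, threshold = "
            f"{ms.thresholds.get(1, float('nan')):.4f})",
            f"cv: {cfg.k_folds}-fold x {cfg.n_repeats} repeats, "
            f"seed {cfg.seed}",
            "",
            f"{'dim':>4} {'models':>7} {'min err':>8} {'median':>8} "
            f"{'max err':>8} {'threshold':>10}",
        ]
        for d in ms.dimensions:
            errs = [m.cv_error for m in ms.models_by_dimension[d]]
            thr = ms.thresholds.get(d)
            lines.append(
                f"{d:>4} {len(errs):>7} {min(errs):>8.4f} "
                f"{float(np.median(errs)):>8.4f} {max(errs):>8.4f} "
                f"{'' if thr is None else format(thr, '>10.4f')}")
        lines.append("")
        lines.append(f"total retained models: {len(ms)} over "
                     f"{len(ms.feature_ids)} distinct features")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<SwagResults: {len(self.model_set)} models, "
                f"dims {self.model_set.dimensions}>")
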