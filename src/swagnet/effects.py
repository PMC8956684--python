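"""Single vs associative coefficient analysis.

A feature's *single* effect is the slope of the one-feature logistic fit
on the standardized design; its *associative* effect is the collection
of its coefficients across every retained multivariate model that
contains it. Features whose single and median associative coefficients
agree in sign are classified oncogenic (both positive: expression
activates the case outcome) or protective (both negative); a sign
disagreement — the Yule-Simpson reversal driven by correlated partners
— marks the feature *antagonistic* when it occurs in enough models for
the median to be meaningful, and *unstable* otherwise.

Effect fits use the full standardized dataset (no train-only
restriction), unlike predictive evaluation which standardizes on the
training data only; the asymmetry is deliberate, since effect analysis
describes the cohort rather than predicting out of sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import LabeledCohort, standardize_design
from .errors import ConfigError, DataError
from .logistic import FrozenModel, fit_logistic
from .metrics import confusion_metrics
from .swag import ModelSet

logger = logging.getLogger(__name__)

__all__ = ["EffectProfile", "single_beta", "associative_betas",
           "classify_effect", "occurrence_rate", "effect_profiles",
           "effect_table", "find_synonyms", "apply_frozen_models"]


@dataclass(frozen=True)
class EffectProfile:
    """Coefficient summary of one feature over a model set."""

    feature_id: str
    beta_single: float
    betas_associative: tuple        # (features tuple, coefficient) pairs
    occurrence_rate: float
    effect_class: str

    @property
    def associative_values(self) -> np.ndarray:
        return np.asarray([b for _, b in self.betas_associative], dtype=float)

    @property
    def median_associative(self) -> float:
        return float(np.median(self.associative_values))

    @property
    def range_associative(self) -> tuple:
        vals = self.associative_values
        return float(vals.min()), float(vals.max())


def single_beta(feature_id: str, cohort: LabeledCohort,
                standardized: bool = False) -> float:
    """Slope of the one-feature logistic fit on the standardized design."""
    if not standardized:
        cohort, _ = standardize_design(cohort)
    X = cohort.columns((feature_id,))
    fit = fit_logistic(X, cohort.labels)
    if fit.separated:
        logger.warning("separation in single fit of %s", feature_id)
    return float(fit.slopes[0])


def associative_betas(feature_id: str, model_set: ModelSet,
                      cohort: LabeledCohort, standardized: bool = False):
    """The feature's coefficient in every retained model containing it.

    Returns ``(pairs, median, (min, max))`` where ``pairs`` is a list of
    ``(model_features, coefficient)``.
    """
    containing = model_set.containing(feature_id)
    if not containing:
        raise DataError(f"feature {feature_id!r} occurs in no retained model")
    if not standardized:
        cohort, _ = standardize_design(cohort)
    pairs = []
    for m in containing:
        X = cohort.columns(m.features)
        fit = fit_logistic(X, cohort.labels)
        pairs.append((m.features, float(fit.slopes[m.features.index(feature_id)])))
    values = np.asarray([b for _, b in pairs])
    return pairs, float(np.median(values)), (float(values.min()),
                                             float(values.max()))


def occurrence_rate(feature_id: str, model_set: ModelSet) -> float:
    """Proportion of retained models containing the feature."""
    if len(model_set) == 0:
        raise DataError("model set is empty")
    return len(model_set.containing(feature_id)) / len(model_set)


def classify_effect(beta_single: float, median_associative: float,
                    occurrence: float,
                    min_occurrence: float = 0.10) -> str:
    """Classify a feature from its single and median associative signs.

    ``oncogenic`` if both positive; ``protective`` if both negative;
    ``antagonistic`` if the signs disagree and the feature occurs in at
    least ``min_occurrence`` of the models; ``unstable`` otherwise
    (discordant but rare, or an exact-zero coefficient).
    """
    s, a = np.sign(beta_single), np.sign(median_associative)
    if s == 0 or a == 0:
        logger.warning("exact-zero coefficient: classified unstable")
        return "unstable"
    if s > 0 and a > 0:
        return "oncogenic"
    if s < 0 and a < 0:
        return "protective"
    return "antagonistic" if occurrence >= min_occurrence else "unstable"


def effect_profiles(model_set: ModelSet, cohort: LabeledCohort,
                    min_occurrence: float = 0.10):
    """EffectProfile for every feature appearing in the model set."""
    std_cohort, _ = standardize_design(cohort)
    profiles = []
    for f in model_set.feature_ids:
        bs = single_beta(f, std_cohort, standardized=True)
        pairs, median, _rng = associative_betas(f, model_set, std_cohort,
                                                standardized=True)
        occ = occurrence_rate(f, model_set)
        cls = classify_effect(bs, median, occ, min_occurrence)
        profiles.append(EffectProfile(feature_id=f, beta_single=bs,
                                      betas_associative=tuple(pairs),
                                      occurrence_rate=occ, effect_class=cls))
    return profiles


def effect_table(model_set: ModelSet, cohort: LabeledCohort,
                 min_occurrence: float = 0.10) -> pd.DataFrame:
    """Tabular effect summary: one row per feature, sorted by occurrence
    (feature, single beta, median/range of associative betas, class,
    occurrence %)."""
    rows = []
    for p in effect_profiles(model_set, cohort, min_occurrence):
        lo, hi = p.range_associative
        rows.append({"feature": p.feature_id,
                     "beta_single": p.beta_single,
                     "median_associative": p.median_associative,
                     "assoc_min": lo, "assoc_max": hi,
                     "occurrence_pct": 100 * p.occurrence_rate,
                     "effect_class": p.effect_class})
    df = pd.DataFrame(rows)
    return df.sort_values(["occurrence_pct", "feature"],
                          ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Paradigmatic substitution: synonym pairs
# ---------------------------------------------------------------------------

def find_synonyms(model_set: ModelSet, test_metrics: dict,
                  tolerance: float = 0.0):
    """Swap-equivalent feature pairs across equally performing models.

    Two features f, g are synonyms if two retained models exist whose
    feature sets differ exactly by exchanging f for g and whose test
    performance (``test_metrics``: frozenset(features) -> AUC or any
    scalar score) differs by at most ``tolerance``.

    Returns a list of dicts with the pair, the shared context and the
    two scores.
    """
    models = list(model_set.models)
    out = []
    seen = set()
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            a, b = set(models[i].features), set(models[j].features)
            if len(a) != len(b):
                continue
            only_a, only_b = a - b, b - a
            if len(only_a) == 1 and len(only_b) == 1:
                f, g = next(iter(only_a)), next(iter(only_b))
                sa = test_metrics[frozenset(a)]
                sb = test_metrics[frozenset(b)]
                if abs(sa - sb) <= tolerance:
                    key = (frozenset((f, g)), frozenset(a & b))
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append({"pair": tuple(sorted((f, g))),
                                "context": tuple(sorted(a & b)),
                                "scores": (sa, sb)})
    return out


# ---------------------------------------------------------------------------
# External validation with frozen models
# ---------------------------------------------------------------------------

def write_frozen_models(frozen_models, path) -> None:
    with open(path, "w") as fh:
        json.dump([fm.to_dict() for fm in frozen_models], fh, indent=1,
                  sort_keys=True)
        fh.write("\n")


def read_frozen_models(path):
    with open(path) as fh:
        payload = json.load(fh)
    if not payload:
        raise DataError(f"frozen-model file {path} is empty")
    return [FrozenModel.from_dict(d) for d in payload]


def apply_frozen_models(frozen_models, new_cohort: LabeledCohort,
                        refit: bool = True, min_occurrence: float = 0.10):
    """Validate a frozen model set on a new cohort.

    Prediction mode evaluates each model's frozen coefficients (with the
    original training standardization) on the new cohort. Refit mode
    re-estimates single and associative effect profiles on the new
    cohort and reports the sign concordance of each feature's single and
    median associative coefficients with the frozen slopes.

    Returns a dict with ``prediction`` (per-model metrics DataFrame) and,
    when ``refit``, ``effects`` (effect table on the new cohort) and
    ``concordance`` (per-feature sign agreement DataFrame).
    """
    frozen_models = list(frozen_models)
    if not frozen_models:
        raise DataError("no frozen models supplied")
    missing = sorted({f for fm in frozen_models for f in fm.features
                      if f not in new_cohort.feature_ids})
    if missing:
        raise DataError(f"new cohort is missing features: {missing}")

    rows = []
    for fm in frozen_models:
        proba = fm.predict_proba(new_cohort)
        rep = confusion_metrics(new_cohort.labels, proba)
        from .metrics import auc as _auc
        rows.append({"features": "|".join(fm.features),
                     "dimension": len(fm.features),
                     "test_error": 1 - rep.accuracy,
                     "auc": _auc(new_cohort.labels, proba),
                     **{k: v for k, v in rep.as_dict().items()
                        if k not in ("cutoff",)}})
    result = {"prediction": pd.DataFrame(rows)}

    if refit:
        from .swag import ModelSet, ScoredModel
        by_dim = {}
        seen = set()
        for fm in frozen_models:
            key = frozenset(fm.features)
            if key in seen:
                continue
            seen.add(key)
            m = ScoredModel(fm.features, fm.cv_error or 0.0)
            by_dim.setdefault(m.dimension, []).append(m)
        ms = ModelSet(
            models_by_dimension={d: tuple(v) for d, v in by_dim.items()},
            screened_features=tuple(
                dict.fromkeys(f for fm in frozen_models for f in fm.features)))
        table = effect_table(ms, new_cohort, min_occurrence)
        # original per-feature summaries from the frozen slopes
        orig = {}
        for fm in frozen_models:
            for f, b in zip(fm.features, fm.slopes):
                orig.setdefault(f, []).append(b)
        conc_rows = []
        for _, row in table.iterrows():
            f = row["feature"]
            orig_median = float(np.median(orig[f]))
            conc_rows.append({
                "feature": f,
                "original_median_associative": orig_median,
                "new_median_associative": row["median_associative"],
                "associative_sign_concordant": bool(
                    np.sign(orig_median)
                    == np.sign(row["median_associative"])),
            })
        result["effects"] = table
        result["concordance"] = pd.DataFrame(conc_rows)
    return result
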