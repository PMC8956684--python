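"""Sparse wrapper search: screening, growth, retention, determinism and
serialization."""

import itertools

import numpy as np
import pytest

from swagnet import (ConfigError, DataError, ModelSet, ScoredModel,
                     SparseWrapperSearch, SwagConfig, cv_error,
                     generate_cohort, grow_dimension, read_model_set_json,
                     read_model_table, run_swag, screen_features,
                     select_model_set, write_model_set_json,
                     write_model_table)
from swagnet.crossval import make_folds
from swagnet.simulate import CohortConfig

from conftest import make_cohort


def _model_set(feature_sets, errors=None):
    by_dim = {}
    for i, fs in enumerate(feature_sets):
        err = 0.1 if errors is None else errors[i]
        m = ScoredModel(tuple(fs), err)
        by_dim.setdefault(m.dimension, []).append(m)
    screened = tuple(dict.fromkeys(f for fs in feature_sets for f in fs))
    return ModelSet({d: tuple(v) for d, v in by_dim.items()},
                    screened_features=screened)


class TestScreening:
    def test_alpha_near_one_retains_everything(self, separator_cohort):
        cfg = SwagConfig(p_max=1, alpha=0.999, k_folds=5, n_repeats=1)
        res = screen_features(separator_cohort, cfg)
        assert set(res.retained) == set(separator_cohort.feature_ids)

    def test_perfect_separator_survives_tight_alpha(self, separator_cohort):
        cfg = SwagConfig(p_max=1, alpha=0.2, k_folds=5, n_repeats=2)
        res = screen_features(separator_cohort, cfg)
        assert "f0" in res.retained
        assert res.errors["f0"] == 0.0

    def test_duplicated_columns_tie_together(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(60)
        y = (x + 0.5 * rng.standard_normal(60) > 0).astype(int)
        matrix = np.column_stack([x, x, rng.standard_normal(60)])
        cohort = make_cohort(matrix, y)
        cfg = SwagConfig(p_max=1, alpha=0.5, k_folds=5, n_repeats=2, seed=1)
        res = screen_features(cohort, cfg)
        assert res.errors["f0"] == res.errors["f1"]
        assert ("f0" in res.retained) == ("f1" in res.retained)


class TestGrowDimension:
    def test_single_achievable_combination_deduplicated(self):
        prev = [ScoredModel(("A",), 0.1), ScoredModel(("B",), 0.2)]
        cfg = SwagConfig(p_max=2, alpha=0.1, m_models=10)
        cands = grow_dimension(prev, ("A", "B"), 2, cfg,
                               np.random.default_rng(0))
        assert cands == [("A", "B")]

    def test_exhaustive_enumeration_when_m_large(self):
        prev = [ScoredModel(("A",), 0.1), ScoredModel(("B",), 0.2)]
        cfg = SwagConfig(p_max=2, alpha=0.1, m_models=1000)
        cands = grow_dimension(prev, ("A", "B", "C"), 2, cfg,
                               np.random.default_rng(0))
        assert sorted(cands) == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_candidates_have_d_distinct_screened_features(self):
        prev = [ScoredModel(("A", "B"), 0.1), ScoredModel(("B", "C"), 0.2)]
        screened = ("A", "B", "C", "D", "E")
        cfg = SwagConfig(p_max=3, alpha=0.1, m_models=4)
        cands = grow_dimension(prev, screened, 3, cfg,
                               np.random.default_rng(1))
        assert 1 <= len(cands) <= 4
        for c in cands:
            assert len(set(c)) == 3
            assert set(c) <= set(screened)

    def test_saturated_models_yield_empty(self):
        prev = [ScoredModel(("A", "B"), 0.1)]
        cfg = SwagConfig(p_max=3, alpha=0.1, m_models=10)
        assert grow_dimension(prev, ("A", "B"), 3, cfg,
                              np.random.default_rng(0)) == []


class TestRunSwag:
    def test_p_max_one_equals_screening(self, separator_cohort):
        cfg = SwagConfig(p_max=1, alpha=0.4, k_folds=5, n_repeats=2, seed=0)
        ms = run_swag(separator_cohort, cfg)
        screening = screen_features(
            separator_cohort, cfg,
            folds=make_folds(separator_cohort.labels, 5, 2, 0))
        assert ms.dimensions == (1,)
        assert {m.features[0] for m in ms.models} == set(screening.retained)

    def test_planted_pair_recovered_among_dimension_two(self):
        cfg = CohortConfig(n_samples=400, n_features=22, prevalence=0.5,
                           effects={0: 2.0, 1: -2.0}, seed=8)
        cohort = generate_cohort(cfg)
        swag_cfg = SwagConfig(p_max=2, alpha=0.2, m_models=None, k_folds=10,
                              n_repeats=2, seed=8)
        ms = run_swag(cohort, swag_cfg)
        pairs = {m.key for m in ms.models_by_dimension.get(2, ())}
        assert frozenset({"feat-01", "feat-02"}) in pairs

    def test_all_noise_errors_near_class_prior(self):
        errs = []
        for s in range(8):
            cohort = generate_cohort(CohortConfig(
                n_samples=300, n_features=8, prevalence=0.5, seed=100 + s))
            ms = run_swag(cohort, SwagConfig(p_max=2, alpha=0.3,
                                             m_models=None, k_folds=5,
                                             n_repeats=1, seed=s))
            errs.extend(m.cv_error for m in ms.models)
        assert abs(np.mean(errs) - 0.5) < 0.08  # retention biases slightly low

    def test_identical_seed_identical_model_set(self, imbalanced_cohort):
        cfg = SwagConfig(p_max=3, alpha=0.3, m_models=20, k_folds=5,
                         n_repeats=2, seed=13)
        a = run_swag(imbalanced_cohort, cfg)
        b = run_swag(imbalanced_cohort, cfg)
        assert a.models == b.models
        assert a.screened_features == b.screened_features
        assert a.thresholds == b.thresholds

    def test_retained_errors_at_or_below_threshold(self, imbalanced_cohort):
        ms = run_swag(imbalanced_cohort,
                      SwagConfig(p_max=3, alpha=0.3, m_models=20, k_folds=5,
                                 n_repeats=1, seed=2))
        for d in ms.dimensions:
            for m in ms.models_by_dimension[d]:
                assert m.cv_error <= ms.thresholds[d] + 1e-12

    def test_screening_monotone_in_alpha(self, imbalanced_cohort):
        folds = make_folds(imbalanced_cohort.labels, 5, 1, 3)
        small = screen_features(imbalanced_cohort,
                                SwagConfig(alpha=0.2, k_folds=5,
                                           n_repeats=1, seed=3), folds=folds)
        large = screen_features(imbalanced_cohort,
                                SwagConfig(alpha=0.6, k_folds=5,
                                           n_repeats=1, seed=3), folds=folds)
        assert set(small.retained) <= set(large.retained)


class TestModelSetInvariants:
    def test_unscreened_feature_rejected(self):
        with pytest.raises(DataError, match="unscreened"):
            ModelSet({2: (ScoredModel(("A", "Z"), 0.1),)},
                     screened_features=("A", "B"))

    def test_duplicate_sets_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            ModelSet({2: (ScoredModel(("A", "B"), 0.1),
                          ScoredModel(("B", "A"), 0.2))},
                     screened_features=("A", "B"))


class TestSelection:
    def test_identity_when_unconstrained(self):
        ms = _model_set([("A",), ("B",), ("A", "B")])
        assert select_model_set(ms).models == ms.models

    def test_dimension_counts_add_up(self):
        ms = _model_set([("A",), ("B",), ("A", "B"), ("A", "C"),
                         ("A", "B", "C")])
        sub = select_model_set(ms, dims=[2, 3])
        assert len(sub) == 3

    def test_zero_test_error_ceiling(self):
        ms = _model_set([("A", "B"), ("A", "C")])
        test_errors = {frozenset(("A", "B")): 0.0,
                       frozenset(("A", "C")): 0.2}
        sub = select_model_set(ms, max_test_error=0.0,
                               test_errors=test_errors)
        assert [m.key for m in sub.models] == [frozenset(("A", "B"))]


class TestSerialization:
    def test_json_round_trip(self, tmp_path, imbalanced_cohort):
        ms = run_swag(imbalanced_cohort,
                      SwagConfig(p_max=2, alpha=0.3, m_models=10, k_folds=5,
                                 n_repeats=1, seed=4))
        path = tmp_path / "ms.json"
        write_model_set_json(ms, path)
        back = read_model_set_json(path)
        assert back.models == ms.models
        assert back.screened_features == ms.screened_features
        assert back.config == ms.config

    def test_table_round_trip_preserves_models(self, tmp_path):
        ms = _model_set([("A", "B", "C", "D"), ("A", "B", "C", "E")],
                        errors=[0.05, 0.08])
        path = tmp_path / "ms.tsv"
        write_model_table(ms, path)
        back = read_model_table(path)
        assert {m.key for m in back.models} == {m.key for m in ms.models}

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("features\tdimension\tcv_error\n")
        with pytest.raises(DataError, match="empty"):
            read_model_table(path)


class TestOracleEquivalence:
    def test_greedy_matches_exhaustive_brute_force(self):
        """With exhaustive candidate generation, the retained models per
        dimension coincide with the best alpha-fraction of a brute-force
        enumeration of all combinations of screened features.

        Retention must be generous enough (alpha = 0.9) that the greedy
        chain's candidate pool provably covers every combination: with at
        most two pairs dropped at dimension 2, no triple can lose all of
        its parent pairs.
        """
        agreements = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cohort = generate_cohort(CohortConfig(
                n_samples=150, n_features=8, prevalence=0.5,
                effects={0: 1.5, 1: -1.5, 2: 1.0}, seed=200 + seed))
            cfg = SwagConfig(p_max=3, alpha=0.9, m_models=None, k_folds=5,
                             n_repeats=2, seed=seed)
            ms = run_swag(cohort, cfg)
            folds = make_folds(cohort.labels, 5, 2, seed)
            ok = True
            for d in (2, 3):
                if d not in ms.models_by_dimension:
                    ok = False
                    break
                scored = []
                for combo in itertools.combinations(
                        sorted(ms.screened_features), d):
                    scored.append((cv_error(combo, cohort, folds=folds),
                                   frozenset(combo)))
                errors = [e for e, _ in scored]
                thr = np.quantile(errors, cfg.alpha, method="higher")
                brute = {k for e, k in scored if e <= thr}
                greedy = {m.key for m in ms.models_by_dimension[d]}
                ok = ok and greedy == brute
            agreements += ok
        assert agreements == n_seeds
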