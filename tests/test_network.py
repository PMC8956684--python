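"""Spearman correlation with bootstrap inference and co-occurrence
network construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swagnet import (DataError, bootstrap_correlation, build_network,
                     cooccurrence_rate, effect_profiles, focal_subnetwork,
                     generate_cohort, occurrence_rate, spearman_rho)
from swagnet.network import (pairwise_correlations, write_dot,
                             write_edge_list, write_graphml)
from swagnet.simulate import CohortConfig
from swagnet.swag import ModelSet, ScoredModel

from test_effects import model_set


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(-2, 2, 20)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.linspace(-2, 2, 20)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_five_point_example(self):
        # sum of squared rank differences = 6 -> 1 - 6*6/(5*24) = 0.7
        assert spearman_rho([1, 2, 3, 4, 5],
                            [2, 3, 1, 4, 5]) == pytest.approx(0.7)

    def test_constant_vector_flagged(self):
        with pytest.raises(DataError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_to_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base)
        assert spearman_rho(x, y**3) == pytest.approx(base)
        assert spearman_rho(-x, y) == pytest.approx(-base)


class TestBootstrapCorrelation:
    def test_monotone_pair_pinned_at_one(self):
        x = np.linspace(0, 1, 30)
        est = bootstrap_correlation(x, x**2, n_boot=200, seed=0)
        assert est.ci95[0] == pytest.approx(1.0)
        assert est.ci95[1] == pytest.approx(1.0)
        assert est.p_value == pytest.approx(2 / 200)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        a = bootstrap_correlation(x, y, n_boot=300, seed=9)
        b = bootstrap_correlation(x, y, n_boot=300, seed=9)
        assert a == b

    def test_null_ci_covers_zero(self):
        rng = np.random.default_rng(5)
        est = bootstrap_correlation(rng.standard_normal(200),
                                    rng.standard_normal(200),
                                    n_boot=500, seed=1)
        assert est.ci95[0] < 0 < est.ci95[1]
        assert est.p_value > 0.05


class TestCooccurrence:
    def test_always_and_never_together(self):
        ms = model_set(("A", "B"), ("A", "B", "C"), ("C", "D"))
        assert cooccurrence_rate("A", "B", ms) == pytest.approx(2 / 3)
        assert cooccurrence_rate("A", "D", ms) == 0.0

    def test_brute_force_recount_on_random_fixture(self):
        rng = np.random.default_rng(6)
        features = [f"m{i}" for i in range(10)]
        sets, seen = [], set()
        while len(sets) < 30:
            fs = tuple(sorted(rng.choice(features, size=4, replace=False)))
            if fs not in seen:
                seen.add(fs)
                sets.append(fs)
        ms = model_set(*sets)
        for f, g in itertools.combinations(features, 2):
            expected = sum(1 for s in sets if f in s and g in s) / 30
            assert cooccurrence_rate(f, g, ms) == pytest.approx(expected)

    def test_bounded_by_marginal_occurrences(self):
        rng = np.random.default_rng(7)
        features = [f"m{i}" for i in range(8)]
        sets = {tuple(sorted(rng.choice(features, size=3, replace=False)))
                for _ in range(20)}
        ms = model_set(*sets)
        for f, g in itertools.combinations(features, 2):
            assert cooccurrence_rate(f, g, ms) <= min(
                occurrence_rate(f, ms), occurrence_rate(g, ms)) + 1e-12


@pytest.fixture(scope="module")
def network_cohort():
    return generate_cohort(CohortConfig(
        n_samples=400, n_features=5, effects={0: 1.5, 1: -1.5},
        correlation_blocks=[((0, 2), 0.6)], seed=20))


class TestBuildNetwork:
    def test_single_model_two_nodes_one_full_edge(self, network_cohort):
        ms = model_set(("feat-1", "feat-2"))
        graph = build_network(ms, effect_profiles(ms, network_cohort))
        assert set(graph.nodes) == {"feat-1", "feat-2"}
        assert graph.edges["feat-1", "feat-2"]["weight"] == 100.0
        assert graph.nodes["feat-1"]["size"] == 100.0

    def test_node_count_equals_distinct_features(self, network_cohort):
        ms = model_set(("feat-1", "feat-2"), ("feat-1", "feat-3"),
                       ("feat-4", "feat-5"))
        graph = build_network(ms, effect_profiles(ms, network_cohort))
        assert graph.number_of_nodes() == len(ms.feature_ids)

    def test_edges_match_pair_enumeration(self, network_cohort):
        sets = [("feat-1", "feat-2"), ("feat-1", "feat-3"),
                ("feat-2", "feat-3"), ("feat-1", "feat-4")]
        ms = model_set(*sets)
        graph = build_network(ms, effect_profiles(ms, network_cohort))
        for f, g in itertools.combinations(ms.feature_ids, 2):
            count = sum(1 for s in sets if f in s and g in s)
            if count:
                assert graph.edges[f, g]["weight"] == pytest.approx(
                    100 * count / len(sets))
            else:
                assert not graph.has_edge(f, g)

    def test_missing_profile_listed(self, network_cohort):
        ms = model_set(("feat-1", "feat-2"))
        profiles = [p for p in effect_profiles(ms, network_cohort)
                    if p.feature_id != "feat-2"]
        with pytest.raises(DataError, match="feat-2"):
            build_network(ms, profiles)

    def test_correlation_attributes_attached(self, network_cohort):
        ms = model_set(("feat-1", "feat-3"))
        corr = pairwise_correlations(ms, network_cohort)
        graph = build_network(ms, effect_profiles(ms, network_cohort), corr)
        edge = graph.edges["feat-1", "feat-3"]
        # planted rho = 0.6 between these columns
        assert edge["rho"] == pytest.approx(0.6, abs=0.1)
        assert edge["rho_sign"] == 1


class TestFocalSubnetwork:
    def test_percentages_relative_to_restricted_set(self, network_cohort):
        ms = model_set(("feat-1", "feat-2"), ("feat-1", "feat-3"),
                       ("feat-2", "feat-3"))
        graph = focal_subnetwork("feat-1", ms, network_cohort)
        # two models contain the focal feature; each partner in one of them
        assert graph.nodes["feat-2"]["size"] == 50.0
        assert graph.nodes["feat-3"]["size"] == 50.0
        assert graph.nodes["feat-1"]["size"] == 100.0

    def test_single_focal_model_partner_at_100(self, network_cohort):
        ms = model_set(("feat-1", "feat-4"), ("feat-2", "feat-3"))
        graph = focal_subnetwork("feat-1", ms, network_cohort)
        assert set(graph.nodes) == {"feat-1", "feat-4"}
        assert graph.nodes["feat-4"]["size"] == 100.0

    def test_restricted_recount_matches_brute_force(self, network_cohort):
        sets = [("feat-1", "feat-2", "feat-3"), ("feat-1", "feat-2"),
                ("feat-2", "feat-3"), ("feat-1", "feat-4")]
        ms = model_set(*sets)
        graph = focal_subnetwork("feat-1", ms, network_cohort)
        focal_sets = [s for s in sets if "feat-1" in s]
        for node, data in graph.nodes(data=True):
            expected = 100 * sum(1 for s in focal_sets if node in s) \
                / len(focal_sets)
            assert data["size"] == pytest.approx(expected)

    def test_sign_comes_from_single_effect(self, network_cohort):
        ms = model_set(("feat-1", "feat-2"))
        graph = focal_subnetwork("feat-1", ms, network_cohort)
        assert graph.nodes["feat-1"]["sign"] == 1    # planted +1.5
        assert graph.nodes["feat-2"]["sign"] == -1   # planted -1.5

    def test_absent_focal_rejected(self, network_cohort):
        ms = model_set(("feat-1", "feat-2"))
        with pytest.raises(DataError, match="feat-5"):
            focal_subnetwork("feat-5", ms, network_cohort)


class TestExports:
    def test_graphml_edgelist_dot_written(self, tmp_path, network_cohort):
        import networkx as nx
        ms = model_set(("feat-1", "feat-2"), ("feat-1", "feat-3"))
        corr = pairwise_correlations(ms, network_cohort)
        graph = build_network(ms, effect_profiles(ms, network_cohort), corr)
        gpath = tmp_path / "g.graphml"
        write_graphml(graph, gpath)
        back = nx.read_graphml(gpath)
        assert set(back.nodes) == set(graph.nodes)
        epath = tmp_path / "edges.tsv"
        write_edge_list(graph, epath)
        lines = epath.read_text().splitlines()
        assert lines[0] == "source\ttarget\tweight\trho\trho_sign"
        assert len(lines) == 1 + graph.number_of_edges()
        dpath = tmp_path / "g.dot"
        write_dot(graph, dpath)
        assert "--" in dpath.read_text()
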