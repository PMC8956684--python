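"""Model-set co-occurrence networks and bootstrap Spearman correlation.

Nodes are the features retained in at least one model; a node's size is
its occurrence percentage over the model set and its colour/sign comes
from a designated coefficient summary (median associative effect for
the full network, single effect for focal subnetworks). An undirected
edge joins two features that appear together in at least one model,
weighted by their co-occurrence percentage and annotated with the
Spearman rank correlation of their expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import spearmanr

from .cohort import LabeledCohort, standardize_design
from .errors import DataError
from .swag import ModelSet

logger = logging.getLogger(__name__)

__all__ = ["spearman_rho", "CorrelationEstimate", "bootstrap_correlation",
           "cooccurrence_rate", "pairwise_correlations", "build_network",
           "focal_subnetwork", "write_graphml", "write_edge_list",
           "write_dot"]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise DataError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("rank correlation undefined for a constant vector")
    return float(spearmanr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationEstimate:
    """Bootstrap summary of a rank correlation between two features."""

    pair: tuple
    rho_hat: float
    ci95: tuple
    p_value: float
    n_boot: int
    seed: int
    boot_mean: float
    boot_sd: float
    n_degenerate: int = 0


def bootstrap_correlation(x, y, n_boot: int = 5000, seed: int = 0,
                          pair: tuple = ("x", "y")) -> CorrelationEstimate:
    """Non-parametric paired bootstrap of the Spearman correlation.

    Rows are resampled with replacement; the 95% CI is the 2.5/97.5
    percentile interval and the two-sided p-value is
    ``2 * min(frac <= 0, frac >= 0)``, floored at ``2 / n_boot`` so an
    all-one-sided resample distribution is never reported as exactly 0.
    Resamples in which either vector is constant are skipped and
    counted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho_hat = spearman_rho(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    draws = []
    degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            degenerate += 1
            continue
        draws.append(spearmanr(xb, yb).statistic)
    if degenerate:
        logger.warning("%d degenerate bootstrap resamples skipped",
                       degenerate)
    draws = np.asarray(draws, dtype=float)
    if len(draws) == 0:
        raise DataError("all bootstrap resamples degenerate")
    ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    frac_le = np.mean(draws <= 0)
    frac_ge = np.mean(draws >= 0)
    p = float(np.clip(2 * min(frac_le, frac_ge), 2 / n_boot, 1.0))
    return CorrelationEstimate(pair=tuple(pair), rho_hat=rho_hat, ci95=ci,
                               p_value=p, n_boot=n_boot, seed=seed,
                               boot_mean=float(draws.mean()),
                               boot_sd=float(draws.std()),
                               n_degenerate=degenerate)


def cooccurrence_rate(f: str, g: str, model_set: ModelSet) -> float:
    """Proportion of models containing both features."""
    if len(model_set) == 0:
        raise DataError("model set is empty")
    both = sum(1 for m in model_set.models
               if f in m.features and g in m.features)
    return both / len(model_set)


def pairwise_correlations(model_set: ModelSet, cohort: LabeledCohort,
                          n_boot: int | None = None, seed: int = 0) -> dict:
    """Spearman correlations (optionally bootstrapped) for every feature
    pair of the model set, computed on the standardized full design.

    Returns frozenset pair -> float rho (or CorrelationEstimate when
    ``n_boot`` is set).
    """
    std_cohort, _ = standardize_design(cohort)
    feats = model_set.feature_ids
    out = {}
    for i, f in enumerate(feats):
        for g in feats[i + 1:]:
            x = std_cohort.columns((f,)).ravel()
            y = std_cohort.columns((g,)).ravel()
            if n_boot:
                out[frozenset((f, g))] = bootstrap_correlation(
                    x, y, n_boot=n_boot, seed=seed, pair=(f, g))
            else:
                out[frozenset((f, g))] = spearman_rho(x, y)
    return out


def _edge_rho(correlations, f, g):
    if correlations is None:
        return None
    est = correlations.get(frozenset((f, g)))
    if est is None:
        return None
    return est.rho_hat if isinstance(est, CorrelationEstimate) else float(est)


def _assemble(models, sign_by_feature, correlations) -> nx.Graph:
    n_models = len(models)
    graph = nx.Graph(n_models=n_models)
    feats = list(dict.fromkeys(f for m in models for f in m.features))
    for f in feats:
        occ = 100 * sum(1 for m in models if f in m.features) / n_models
        graph.add_node(f, size=occ, sign=int(np.sign(sign_by_feature[f])))
    for i, f in enumerate(feats):
        for g in feats[i + 1:]:
            both = sum(1 for m in models
                       if f in m.features and g in m.features)
            if both == 0:
                continue
            attrs = {"weight": 100 * both / n_models}
            rho = _edge_rho(correlations, f, g)
            if rho is not None:
                attrs["rho"] = rho
                attrs["rho_sign"] = int(np.sign(rho))
            graph.add_edge(f, g, **attrs)
    return graph


def build_network(model_set: ModelSet, effect_profiles,
                  correlations=None) -> nx.Graph:
    """Full co-occurrence network of a model set.

    Node sign is the sign of the feature's *median associative*
    coefficient (its typical in-model direction); node ``size`` is the
    occurrence percentage; edge ``weight`` the co-occurrence percentage,
    with Spearman ``rho``/``rho_sign`` attributes when ``correlations``
    (as returned by :func:`pairwise_correlations`) are supplied.
    """
    if len(model_set) == 0:
        raise DataError("model set is empty")
    profile_by_feature = {p.feature_id: p for p in effect_profiles}
    missing = [f for f in model_set.feature_ids
               if f not in profile_by_feature]
    if missing:
        raise DataError(f"missing effect profiles for features: {missing}")
    signs = {f: profile_by_feature[f].median_associative
             for f in model_set.feature_ids}
    graph = _assemble(list(model_set.models), signs, correlations)
    graph.graph["sign_source"] = "median_associative"
    return graph


def focal_subnetwork(focal_feature: str, model_set: ModelSet,
                     cohort: LabeledCohort, correlations=None) -> nx.Graph:
    """Partner network of one feature.

    Restricts the model set to models containing the focal feature;
    node sizes and edge weights are percentages relative to that
    restricted set, and node sign is the sign of each feature's
    *single* effect on the cohort.
    """
    focal_models = model_set.containing(focal_feature)
    if not focal_models:
        raise DataError(f"focal feature {focal_feature!r} occurs in no model")
    from .effects import single_beta
    std_cohort, _ = standardize_design(cohort)
    feats = dict.fromkeys(f for m in focal_models for f in m.features)
    signs = {f: single_beta(f, std_cohort, standardized=True) for f in feats}
    graph = _assemble(list(focal_models), signs, correlations)
    graph.graph["sign_source"] = "single"
    graph.graph["focal_feature"] = focal_feature
    return graph


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_edge_list(graph: nx.Graph, path) -> None:
    """TSV edge list: source, target, weight, rho, rho_sign."""
    import pandas as pd
    rows = []
    for u, v, data in sorted(graph.edges(data=True)):
        rows.append({"source": u, "target": v,
                     "weight": data.get("weight"),
                     "rho": data.get("rho"),
                     "rho_sign": data.get("rho_sign")})
    pd.DataFrame(rows, columns=["source", "target", "weight", "rho",
                                "rho_sign"]).to_csv(path, sep="\t",
                                                    index=False)


def write_dot(graph: nx.Graph, path) -> None:
    """Minimal DOT export for quick rendering."""
    lines = ["graph cooccurrence {"]
    for node, data in sorted(graph.nodes(data=True)):
        colour = {1: "tomato", -1: "steelblue"}.get(data.get("sign"), "gray")
        lines.append(f'  "{node}" [width={data.get("size", 0) / 50:.2f}, '
                     f'color={colour}];')
    for u, v, data in sorted(graph.edges(data=True)):
        lines.append(f'  "{u}" -- "{v}" '
                     f'[penwidth={data.get("weight", 0) / 20:.2f}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
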