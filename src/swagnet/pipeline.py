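"""Config-driven orchestration of the full analysis.

A run executes: stratified split -> sparse wrapper search on the
training data -> optional dimension selection -> held-out evaluation
(per-model metrics, ROC region, EPV, lasso baseline) -> effect profiles
-> co-occurrence networks, writing every artifact plus a manifest that
records the configuration and derived seeds. One global seed
deterministically derives per-stage seeds, so a rerun with the same
config reproduces the output bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (LabeledCohort, SplitSpec, read_cohort, split_cohort,
                     write_cohort)
from .effects import (apply_frozen_models, find_synonyms, read_frozen_models,
                      write_frozen_models)
from .errors import ConfigError
from .metrics import lasso_baseline
from .network import (pairwise_correlations, write_edge_list, write_graphml)
from .simulate import CohortConfig, generate_cohort
from .swag import SparseWrapperSearch, write_model_set_json, write_model_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "derive_seed", "run_simulate", "run_analysis",
           "run_validation"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = np.uint64(1469598103934665603)
    for ch in f"{global_seed}:{stage}".encode():
        h = np.uint64((int(h) ^ ch) * 1099511628211 % 2**64)
    return int(h % (2**31 - 1))


@dataclass
class RunConfig:
    """End-to-end run settings (mirrors the YAML config layout)."""

    matrix_path: str
    labels_path: str
    output_dir: str
    seed: int = 0
    test_fraction: float | None = 0.2
    test_size: int | None = None
    p_max: int = 5
    alpha: float = 0.05
    m_models: int | None = 100
    k_folds: int = 10
    n_repeats: int = 10
    dims: list | None = None
    min_occurrence: float = 0.10
    n_boot: int = 2000
    lasso: bool = True
    networks: bool = True
    focal_feature: str | None = None
    synonym_tolerance: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"matrix_path", "labels_path", "output_dir"} - set(raw)
        if missing:
            raise ConfigError(f"config missing keys: {sorted(missing)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def run_simulate(config: CohortConfig, matrix_path, labels_path,
                 config_echo_path=None) -> LabeledCohort:
    """Generate a synthetic cohort and write it (plus a config echo)."""
    cohort = generate_cohort(config)
    write_cohort(cohort, matrix_path, labels_path)
    if config_echo_path:
        echo = {"n_samples": config.n_samples,
                "n_features": config.n_features,
                "prevalence": config.prevalence,
                "effects": {str(k): v for k, v in config.effects.items()},
                "correlation_blocks": [
                    {"features": list(idx), "rho": rho}
                    for idx, rho in config.correlation_blocks],
                "noise_sd": config.noise_sd, "seed": config.seed}
        with open(config_echo_path, "w") as fh:
            yaml.safe_dump(echo, fh, sort_keys=True)
    return cohort


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory result bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.matrix_path, config.labels_path)
    logger.info("cohort: %d samples (%d cases), %d features",
                cohort.n_samples, cohort.n_cases, cohort.n_features)

    split_seed = derive_seed(config.seed, "split")
    spec = SplitSpec(test_fraction=config.test_fraction,
                     test_size=config.test_size, seed=split_seed)
    train, test = split_cohort(cohort, spec)
    logger.info("split: train %d (%d/%d), test %d (%d/%d)",
                train.n_samples, train.n_controls, train.n_cases,
                test.n_samples, test.n_controls, test.n_cases)

    search = SparseWrapperSearch(
        train, p_max=config.p_max, alpha=config.alpha,
        m_models=config.m_models, k_folds=config.k_folds,
        n_repeats=config.n_repeats, seed=derive_seed(config.seed, "swag"))
    results = search.fit()
    if config.dims:
        results = results.select(dims=config.dims)
    write_model_set_json(results.model_set, out / "model_set.json")
    write_model_table(results.model_set, out / "model_set.tsv")

    evaluation = results.evaluate(test)
    evaluation["table"].to_csv(out / "model_metrics.tsv", sep="\t",
                               index=False, float_format="%.6g")
    write_frozen_models(evaluation["frozen_models"],
                        out / "frozen_models.json")

    bundle = {"train": train, "test": test, "results": results,
              "evaluation": evaluation}

    bundle["synonyms"] = find_synonyms(results.model_set,
                                       evaluation["auc_by_model"],
                                       tolerance=config.synonym_tolerance)
    with open(out / "synonyms.json", "w") as fh:
        json.dump([{"pair": list(s["pair"]), "context": list(s["context"]),
                    "scores": list(s["scores"])} for s in bundle["synonyms"]],
                  fh, indent=1, sort_keys=True)
        fh.write("\n")

    if config.lasso:
        lasso = lasso_baseline(train, test, n_boot=config.n_boot,
                               seed=derive_seed(config.seed, "lasso"))
        bundle["lasso"] = lasso
        with open(out / "lasso_baseline.json", "w") as fh:
            json.dump({"selected_features": list(lasso["selected_features"]),
                       "C": lasso["C"],
                       "metrics": {k: v for k, v in
                                   lasso["report"].as_dict().items()},
                       "ci95": lasso["ci"]}, fh, indent=1, sort_keys=True)
            fh.write("\n")

    effect_df = results.effect_profiles(min_occurrence=config.min_occurrence)
    effect_df.to_csv(out / "effect_table.tsv", sep="\t", index=False,
                     float_format="%.6g")
    bundle["effects"] = effect_df

    if config.networks:
        from .effects import effect_profiles as _profiles
        from .network import build_network, focal_subnetwork
        profiles = _profiles(results.model_set, cohort,
                             min_occurrence=config.min_occurrence)
        correlations = pairwise_correlations(
            results.model_set, cohort,
            seed=derive_seed(config.seed, "network"))
        graph = build_network(results.model_set, profiles, correlations)
        write_graphml(graph, out / "network.graphml")
        write_edge_list(graph, out / "network_edges.tsv")
        bundle["network"] = graph
        if config.focal_feature:
            focal = focal_subnetwork(config.focal_feature,
                                     results.model_set, cohort, correlations)
            write_graphml(focal, out / "focal_network.graphml")
            write_edge_list(focal, out / "focal_network_edges.tsv")
            bundle["focal_network"] = focal

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "derived_seeds": {stage: derive_seed(config.seed, stage)
                          for stage in ("split", "swag", "lasso", "network")},
        "cohort": {"n_samples": cohort.n_samples,
                   "n_features": cohort.n_features,
                   "n_cases": cohort.n_cases},
        "split": {"train": [train.n_controls, train.n_cases],
                  "test": [test.n_controls, test.n_cases]},
        "models_retained": len(results.model_set),
        "epv_by_dimension": {str(d): v for d, v in
                             evaluation["epv_by_dimension"].items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    (out / "summary.txt").write_text(results.summary() + "\n")
    bundle["manifest"] = manifest
    return bundle


def run_validation(frozen_path, matrix_path, labels_path, output_dir,
                   min_occurrence: float = 0.10) -> dict:
    """Apply a frozen model set to a new cohort and write the report."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    frozen = read_frozen_models(frozen_path)
    cohort = read_cohort(matrix_path, labels_path)
    report = apply_frozen_models(frozen, cohort, refit=True,
                                 min_occurrence=min_occurrence)
    report["prediction"].to_csv(out / "validation_metrics.tsv", sep="\t",
                                index=False, float_format="%.6g")
    report["effects"].to_csv(out / "validation_effects.tsv", sep="\t",
                             index=False, float_format="%.6g")
    report["concordance"].to_csv(out / "validation_concordance.tsv",
                                 sep="\t", index=False, float_format="%.6g")
    return report
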