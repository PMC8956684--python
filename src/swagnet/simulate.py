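"""Synthetic labeled cohorts with the statistical structure the analysis
assumes.

Features are drawn from a correlated multivariate Gaussian with unit
marginal variance (optionally rescaled by ``noise_sd``), and the binary
outcome from a logistic model on the latent features:

    logit P(y = 1 | z) = b0 + sum_j beta_j z_j

The intercept ``b0`` is solved numerically so the *population* case
prevalence matches the configured value; labels are then per-sample
Bernoulli draws, so realized prevalence varies binomially, as in a
sequentially collected cohort. Correlated blocks let the generator plant
Yule-Simpson sign reversals: a feature whose marginal association with
the outcome has the opposite sign of its conditional (within-model)
effect, the structure behind "antagonistic" features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .cohort import LabeledCohort
from .errors import ConfigError

__all__ = ["CohortConfig", "generate_cohort", "simpson_config",
           "population_intercept"]


@dataclass(frozen=True)
class CohortConfig:
    """Generative recipe for a synthetic cohort.

    Parameters
    ----------
    n_samples, n_features : int
        Cohort dimensions.
    prevalence : float in (0, 1)
        Target population probability of the case class.
    effects : dict[int, float]
        Conditional log-odds coefficient per feature index; unlisted
        features have coefficient 0 (pure noise).
    correlation_blocks : list[(tuple[int, ...], float)]
        Disjoint index sets with a common pairwise correlation.
    noise_sd : float
        Marginal standard deviation of the generated features. Labels
        depend on the unit-variance latents, so ``noise_sd`` only
        rescales the observed columns.
    seed : int
        RNG seed; generation is bit-reproducible under a fixed seed.
    """

    n_samples: int
    n_features: int
    prevalence: float = 0.5
    effects: dict = field(default_factory=dict)
    correlation_blocks: list = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_features < 1:
            raise ConfigError("n_samples and n_features must be positive")
        if not 0 < self.prevalence < 1:
            raise ConfigError("prevalence must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        for j in self.effects:
            if not 0 <= int(j) < self.n_features:
                raise ConfigError(f"effect index {j} out of range")
        seen = set()
        for k, (idx, rho) in enumerate(self.correlation_blocks):
            idx = tuple(idx)
            if len(idx) < 2:
                raise ConfigError(f"correlation block {k} needs >= 2 features")
            if not all(0 <= int(j) < self.n_features for j in idx):
                raise ConfigError(f"correlation block {k} index out of range")
            if seen & set(idx):
                raise ConfigError(f"correlation block {k} overlaps another block")
            seen |= set(idx)
            if not -1 < rho < 1:
                raise ConfigError(f"correlation block {k}: |rho| must be < 1")
            # equicorrelation is positive definite iff rho > -1/(m-1)
            m = len(idx)
            if rho <= -1.0 / (m - 1):
                raise ConfigError(
                    f"correlation block {k} (features {idx}, rho={rho}) is "
                    f"not positive definite: need rho > {-1.0 / (m - 1):.4f}"
                )

    def correlation_matrix(self) -> np.ndarray:
        R = np.eye(self.n_features)
        for idx, rho in self.correlation_blocks:
            idx = np.asarray(tuple(idx), dtype=int)
            R[np.ix_(idx, idx)] = rho
            R[idx, idx] = 1.0
        return R

    def effect_vector(self) -> np.ndarray:
        beta = np.zeros(self.n_features)
        for j, b in self.effects.items():
            beta[int(j)] = float(b)
        return beta


def population_intercept(config: CohortConfig) -> float:
    """Intercept making the population prevalence equal the target.

    The linear predictor s = beta' z is Gaussian with variance
    beta' R beta, so prevalence(b0) = E[expit(b0 + s)] is a smooth,
    strictly increasing 1-D function solved by bracketed root finding.
    """
    beta = config.effect_vector()
    sigma = float(np.sqrt(beta @ config.correlation_matrix() @ beta))

    if sigma == 0:
        return float(np.log(config.prevalence / (1 - config.prevalence)))

    def prevalence(b0):
        val, _ = quad(lambda s: expit(b0 + s) * norm.pdf(s, scale=sigma),
                      -10 * sigma, 10 * sigma)
        return val

    lo, hi = -30 - 10 * sigma, 30 + 10 * sigma
    return float(brentq(lambda b0: prevalence(b0) - config.prevalence, lo, hi,
                        xtol=1e-10))


def generate_cohort(config: CohortConfig) -> LabeledCohort:
    """Draw a labeled cohort from the configured generative model."""
    rng = np.random.default_rng(config.seed)
    R = config.correlation_matrix()
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ConfigError(f"correlation matrix not positive definite: {exc}")
    z = rng.standard_normal((config.n_samples, config.n_features)) @ chol.T
    b0 = population_intercept(config)
    eta = b0 + z @ config.effect_vector()
    labels = (rng.random(config.n_samples) < expit(eta)).astype(int)
    width = len(str(config.n_features))
    feature_ids = tuple(f"feat-{j + 1:0{width}d}"
                        for j in range(config.n_features))
    sample_ids = tuple(f"sample-{i + 1:04d}" for i in range(config.n_samples))
    return LabeledCohort(matrix=config.noise_sd * z, labels=labels,
                         feature_ids=feature_ids, sample_ids=sample_ids)


def simpson_config(beta_focal: float, beta_confounder: float, rho: float,
                   n_samples: int = 2000, n_features: int = 2,
                   prevalence: float = 0.5, seed: int = 0) -> CohortConfig:
    """Two-informative-feature config planting a marginal sign reversal.

    Feature 0 is the focal feature, feature 1 the correlated confounder.
    In the Gaussian linear approximation the focal feature's marginal
    slope is proportional to ``beta_focal + beta_confounder * rho``;
    the config is accepted only when that quantity has the opposite sign
    of ``beta_focal``, which guarantees (at large n) that single and
    within-model coefficient estimates disagree in sign.
    """
    if not -1 < rho < 1:
        raise ConfigError("|rho| must be < 1")
    if n_features < 2:
        raise ConfigError("need at least 2 features")
    marginal = beta_focal + beta_confounder * rho
    if beta_focal * marginal >= 0:
        raise ConfigError(
            f"no sign reversal: beta_focal={beta_focal} and implied marginal "
            f"slope {marginal:.4g} share the same sign (need "
            f"beta_focal * (beta_focal + beta_confounder * rho) < 0)"
        )
    return CohortConfig(
        n_samples=n_samples,
        n_features=n_features,
        prevalence=prevalence,
        effects={0: float(beta_focal), 1: float(beta_confounder)},
        correlation_blocks=[((0, 1), float(rho))],
        seed=seed,
    )
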