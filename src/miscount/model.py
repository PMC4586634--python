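"""Data model and observed-data likelihood for cross-misclassified Poisson counts.

Two event streams are counted per observational unit over a person-time
``t``: events labelled as the cause of interest (``w1``) and events labelled
as any other cause (``w2``).  The true counts ``y1 ~ Poisson(t * lambda)``
and ``y2 ~ Poisson(t * mu)`` are never observed; labels cross over with
sensitivity ``se`` (probability a true cause-of-interest event keeps its
label) and specificity ``sp`` (probability another-cause event keeps its
label).  Marginally the observed counts are again Poisson, with mixture
rates

    E[w1] = t * (lambda * se + mu * (1 - sp))
    E[w2] = t * (lambda * (1 - se) + mu * sp)

so that ``E[w1] + E[w2] = t * (lambda + mu)`` for every (se, sp): the
relabelling shuffles events between streams but conserves the total.

Rates follow log-linear models in an exposure ``x`` and covariates ``z``,
optionally with cluster-level random intercepts on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy.special import gammaln

__all__ = [
    "StructuralError",
    "NumericOverflowError",
    "PrecisionError",
    "Effects",
    "Misclass",
    "ObservedDataset",
    "ModelSpec",
    "ParameterState",
    "case_rates",
    "observed_loglik",
    "latent_count_oracle",
]

# Mixture rates are floored here before taking logs; a zero rate facing a
# positive count then yields -inf rather than a NaN or an exception.
RATE_FLOOR = 1e-300


class StructuralError(ValueError):
    """Inconsistent shapes, labels, or domain violations in inputs."""


class NumericOverflowError(FloatingPointError):
    """A log-linear predictor produced a non-finite rate."""


class PrecisionError(ArithmeticError):
    """A truncated enumeration left non-negligible tail mass."""


class Effects(str, Enum):
    fixed = "fixed"
    #: one intercept per cluster shared by both streams' log-rates
    random_shared = "random_shared"
    #: each stream its own intercept, one common variance
    random_common_variance = "random_common_variance"
    #: each stream its own intercept, bivariate normal (sigma1, sigma2, rho)
    random_correlated = "random_correlated"


class Misclass(str, Enum):
    none = "none"  # naive analysis: observed labels taken at face value
    known = "known"  # se, sp fixed at given values
    unknown = "unknown"  # se, sp given beta priors


@dataclass
class ObservedDataset:
    """Per-unit observed counts, person-time, design, optional clusters.

    Parameters
    ----------
    w1, w2
        Nonnegative integer counts of events labelled cause-of-interest /
        other-cause.
    t
        Positive person-time (opportunity size) per unit.
    x
        Exposure of interest per unit (binary or real).
    z
        ``(n, p)`` matrix of further covariates; ``p`` may be 0.
    cluster
        Optional integer cluster labels, required by random-intercept
        models.  Labels must form the contiguous set ``0..K-1``.
    """

    w1: np.ndarray
    w2: np.ndarray
    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    cluster: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1)
        self.w2 = np.asarray(self.w2)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.z.shape[0] == 1 and self.n != 1 and self.z.size == 0:
            self.z = np.empty((self.n, 0))
        if self.z.shape[0] != self.n and self.z.shape[1] == self.n:
            self.z = self.z.T
        for name in ("w1", "w2"):
            w = getattr(self, name)
            if np.any(w < 0) or not np.issubdtype(w.dtype, np.integer):
                if np.any(w != np.floor(w)) or np.any(w < 0):
                    raise StructuralError(f"{name} must be nonnegative integers")
                setattr(self, name, w.astype(np.int64))
        lengths = {self.w1.shape[0], self.w2.shape[0], self.t.shape[0],
                   self.x.shape[0], self.z.shape[0]}
        if lengths != {self.n}:
            raise StructuralError(f"column lengths differ: {sorted(lengths)}")
        if np.any(self.t <= 0):
            raise StructuralError("person-time t must be strictly positive")
        if self.cluster is not None:
            self.cluster = np.asarray(self.cluster, dtype=np.int64)
            if self.cluster.shape[0] != self.n:
                raise StructuralError("cluster column length differs from n")
            labels = np.unique(self.cluster)
            if not np.array_equal(labels, np.arange(labels.size)):
                raise StructuralError(
                    "cluster labels must be the contiguous set 0..K-1; "
                    f"got {labels.tolist()[:10]}"
                )

    @property
    def n(self) -> int:
        return int(np.asarray(self.w1).shape[0])

    @property
    def p(self) -> int:
        return int(self.z.shape[1])

    @property
    def n_clusters(self) -> int:
        if self.cluster is None:
            return 0
        return int(self.cluster.max()) + 1

    @property
    def design(self) -> np.ndarray:
        """``(n, p+2)`` design matrix: intercept, exposure, then z columns.

        The exposure always occupies the second column so the inferential
        targets beta1 / gamma1 have a stable position.
        """
        return np.column_stack([np.ones(self.n), self.x, self.z])


@dataclass
class ModelSpec:
    """Which effects structure and misclassification treatment to fit."""

    effects: Effects = Effects.fixed
    misclass: Misclass = Misclass.unknown
    p: int = 0

    def __post_init__(self) -> None:
        self.effects = Effects(self.effects)
        self.misclass = Misclass(self.misclass)

    @property
    def has_random_effects(self) -> bool:
        return self.effects is not Effects.fixed

    @property
    def n_coef(self) -> int:
        return self.p + 2


@dataclass
class ParameterState:
    """One point in parameter space for a given ModelSpec.

    ``beta`` parameterises the cause-of-interest log-rate, ``gamma`` the
    other-cause log-rate; each has length ``p + 2`` laid out as
    (intercept, exposure, z-coefficients).  ``e_lambda`` / ``e_mu`` are
    per-cluster random intercepts.
    """

    beta: np.ndarray
    gamma: np.ndarray
    se: float = 1.0
    sp: float = 1.0
    sigma: float = 0.0
    sigma1: float = 0.0
    sigma2: float = 0.0
    rho: float = 0.0
    e_lambda: np.ndarray = field(default_factory=lambda: np.zeros(0))
    e_mu: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.e_lambda = np.atleast_1d(np.asarray(self.e_lambda, dtype=float))
        self.e_mu = np.atleast_1d(np.asarray(self.e_mu, dtype=float))
        if not (0.0 < self.se <= 1.0 and 0.0 < self.sp <= 1.0):
            raise StructuralError("se and sp must lie in (0, 1]")
        if not -1.0 < self.rho < 1.0:
            raise StructuralError("rho must lie in (-1, 1)")
        if min(self.sigma, self.sigma1, self.sigma2) < 0.0:
            raise StructuralError("random-effect standard deviations must be >= 0")


def case_rates(
    state: ParameterState, data: ObservedDataset, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit rates (lambda_i, mu_i) from the log-linear models.

    ``log lambda_i = beta0 + beta1 x_i + z_i' beta_z [+ e_lambda[k_i]]`` and
    analogously for ``mu_i`` with gamma and ``e_mu``.
    """
    D = data.design
    q = D.shape[1]
    if state.beta.shape[0] != q or state.gamma.shape[0] != q:
        raise StructuralError(
            f"coefficient length {state.beta.shape[0]}/{state.gamma.shape[0]} "
            f"does not match design width {q}"
        )
    eta_l = D @ state.beta
    eta_m = D @ state.gamma
    if spec.has_random_effects:
        if data.cluster is None:
            raise StructuralError("model has random effects but data has no clusters")
        K = data.n_clusters
        if state.e_lambda.shape[0] != K:
            raise StructuralError(
                f"random-intercept vectors must have one entry per cluster ({K})"
            )
        if spec.effects is Effects.random_shared:
            eta_l = eta_l + state.e_lambda[data.cluster]
            eta_m = eta_m + state.e_lambda[data.cluster]
        else:
            if state.e_mu.shape[0] != K:
                raise StructuralError(
                    f"random-intercept vectors must have one entry per cluster ({K})"
                )
            eta_l = eta_l + state.e_lambda[data.cluster]
            eta_m = eta_m + state.e_mu[data.cluster]
    with np.errstate(over="ignore"):
        lam = np.exp(eta_l)
        mu = np.exp(eta_m)
    for name, r in (("lambda", lam), ("mu", mu)):
        bad = ~np.isfinite(r)
        if bad.any():
            raise NumericOverflowError(
                f"non-finite {name} rate at unit {int(np.argmax(bad))}"
            )
    return lam, mu


def _mixture_rates(
    lam: np.ndarray, mu: np.ndarray, se: float, sp: float
) -> tuple[np.ndarray, np.ndarray]:
    r1 = lam * se + mu * (1.0 - sp)
    r2 = lam * (1.0 - se) + mu * sp
    return r1, r2


def observed_loglik(
    state: ParameterState, data: ObservedDataset, spec: ModelSpec
) -> float:
    """Exact log-likelihood of the observed, possibly mislabelled counts.

    Marginalising the latent true counts analytically, each unit contributes
    two independent Poisson log-pmfs with the mixture rates; the factorial
    constants are included so values are true log-probabilities.  A zero
    mixture rate facing a positive count gives ``-inf`` (not an exception).
    With ``se = sp = 1`` (or ``misclass='none'``) this reduces to the naive
    product-Poisson log-likelihood.
    """
    lam, mu = case_rates(state, data, spec)
    se, sp = state.se, state.sp
    if spec.misclass is Misclass.none:
        se = sp = 1.0
    r1, r2 = _mixture_rates(lam, mu, se, sp)
    if np.any((r1 == 0.0) & (data.w1 > 0)) or np.any((r2 == 0.0) & (data.w2 > 0)):
        return -np.inf
    m1 = np.maximum(data.t * r1, RATE_FLOOR)
    m2 = np.maximum(data.t * r2, RATE_FLOOR)
    ll = (
        data.w1 * np.log(m1)
        + data.w2 * np.log(m2)
        - data.t * (lam + mu)
        - gammaln(data.w1 + 1.0)
        - gammaln(data.w2 + 1.0)
    )
    return float(np.sum(ll))


def latent_count_oracle(
    lam: float,
    mu: float,
    se: float,
    sp: float,
    t: float,
    w1: int,
    w2: int,
    cap: int = 60,
) -> float:
    """Brute-force log P(w1, w2) by enumerating latent configurations.

    Enumerates true counts ``y1, y2`` up to ``cap`` with mislabelled
    subcounts ``u1 ~ Binomial(y1, 1-se)`` and ``u2 ~ Binomial(y2, 1-sp)``,
    summing the probability of every configuration with
    ``w1 = y1 - u1 + u2`` and ``w2 = y2 + u1 - u2``.  Relabelling
    conserves the total, so every consistent configuration has
    ``y1 + y2 = w1 + w2`` and the enumeration is exact (no truncation)
    once ``cap >= w1 + w2``.  Deliberately independent of
    :func:`observed_loglik`; serves as its testing oracle.
    """
    from scipy.stats import binom, poisson

    if w1 < 0 or w2 < 0:
        raise StructuralError("counts must be nonnegative")
    total_events = w1 + w2
    if cap < total_events:
        raise PrecisionError(
            f"cap={cap} cannot reach configurations with y1+y2={total_events}"
        )
    total = 0.0
    for y1 in range(total_events + 1):
        y2 = total_events - y1
        py = poisson.pmf(y1, t * lam) * poisson.pmf(y2, t * mu)
        if py == 0.0:
            continue
        for u1 in range(y1 + 1):
            u2 = w1 - y1 + u1
            if u2 < 0 or u2 > y2:
                continue
            total += (
                py
                * binom.pmf(u1, y1, 1.0 - se)
                * binom.pmf(u2, y2, 1.0 - sp)
            )
    if total == 0.0:
        return -np.inf
    return float(np.log(total))
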