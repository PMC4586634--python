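"""Prior construction and evaluation.

Regression coefficients get diffuse independent N(0, sd=10) priors.
Sensitivity and specificity get beta priors, built either from validation
data (gold-standard relabelling of m subjects, w of them correct, giving
the conjugate Beta(w+1, m-w+1)) or from expert statements of a most-likely
value and a tail percentile.  Random-effect standard deviations get
Unif(0, D) priors and the random-intercept correlation Unif(-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .model import Effects, Misclass, ModelSpec, ParameterState, StructuralError

__all__ = [
    "ElicitationError",
    "PriorSpec",
    "beta_from_validation",
    "beta_from_mode_percentile",
    "beta_moments",
    "log_prior",
]


class ElicitationError(ValueError):
    """No beta distribution satisfies the elicited statements."""


@dataclass
class PriorSpec:
    """All prior settings for one model fit.

    Exactly one of ``se_beta`` / ``se_fixed`` is used downstream, selected
    by the model's misclassification treatment (likewise for sp); the naive
    model ignores both and imposes se = sp = 1.
    """

    coef_sd: float = 10.0
    se_beta: tuple[float, float] = (1.0, 1.0)
    sp_beta: tuple[float, float] = (1.0, 1.0)
    se_fixed: Optional[float] = None
    sp_fixed: Optional[float] = None
    sigma_upper: float = 5.0
    sigma1_upper: float = 5.0
    sigma2_upper: float = 5.0

    def __post_init__(self) -> None:
        if self.coef_sd <= 0:
            raise StructuralError("coef_sd must be positive")
        for name in ("se_beta", "sp_beta"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise StructuralError(f"{name} parameters must be positive")
        for name in ("sigma_upper", "sigma1_upper", "sigma2_upper"):
            if getattr(self, name) <= 0:
                raise StructuralError(f"{name} must be positive")
        for name in ("se_fixed", "sp_fixed"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v <= 1.0:
                raise StructuralError(f"{name} must lie in (0, 1]")


def beta_from_validation(m: int, w: int) -> tuple[float, float]:
    """Conjugate beta prior from a gold-standard validation subsample.

    With ``m`` subjects whose true status is known and ``w`` of them
    correctly labelled, the binomial likelihood combined with a uniform
    prior gives Beta(w + 1, m - w + 1).
    """
    if m < 1 or not 0 <= w <= m:
        raise StructuralError(f"need 0 <= w <= m with m >= 1; got m={m}, w={w}")
    return (float(w + 1), float(m - w + 1))


def beta_from_mode_percentile(
    mode: float,
    tail_prob: float,
    tail_value: float,
    statistic: str = "mode",
) -> tuple[float, float]:
    """Beta parameters from an expert's most-likely value plus a lower tail.

    Finds (a, b) with a, b > 1 such that the beta's mode (or, with
    ``statistic='mean'``, its mean) equals ``mode`` and
    ``P(X < tail_value) = tail_prob``, by one-dimensional root search in a.
    The mean variant reflects how rough published elicitations are often
    centred; the mode variant is the Beta-Buster-style convention.
    """
    if not 0.0 < mode < 1.0:
        raise ElicitationError("most-likely value must lie in (0, 1)")
    if not 0.0 < tail_prob < 0.5:
        raise ElicitationError("tail probability must lie in (0, 0.5)")
    if not 0.0 < tail_value < mode:
        raise ElicitationError(
            "lower-tail elicitation needs 0 < tail_value < most-likely value"
        )
    if statistic == "mode":
        def b_of_a(a: float) -> float:
            return 1.0 + (a - 1.0) * (1.0 - mode) / mode
    elif statistic == "mean":
        def b_of_a(a: float) -> float:
            return a * (1.0 - mode) / mode
    else:
        raise ValueError("statistic must be 'mode' or 'mean'")

    def objective(a: float) -> float:
        return stats.beta.cdf(tail_value, a, b_of_a(a)) - tail_prob

    lo = 1.0 + 1e-9
    hi = 2.0
    # cdf at tail_value decreases monotonically in a; expand until bracketed
    while objective(hi) > 0.0:
        hi *= 2.0
        if hi > 1e8:
            raise ElicitationError(
                "no beta with the requested centre places so little mass "
                f"below {tail_value}"
            )
    if objective(lo) < 0.0:
        raise ElicitationError(
            f"every beta with centre {mode} already has P(X < {tail_value}) "
            f"< {tail_prob}; tail statement is uninformative"
        )
    a = optimize.brentq(objective, lo, hi, xtol=1e-12)
    b = b_of_a(a)
    if abs(stats.beta.cdf(tail_value, a, b) - tail_prob) > 1e-6:
        raise ElicitationError("root search failed to meet the tail statement")
    return (float(a), float(b))


def beta_moments(params: tuple[float, float]) -> tuple[float, float]:
    """Mean and standard deviation of a Beta(a, b) distribution."""
    a, b = params
    if a <= 0 or b <= 0:
        raise StructuralError("beta parameters must be positive")
    mean = a / (a + b)
    sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
    return (float(mean), float(sd))


def _bvn_logpdf(e1: np.ndarray, e2: np.ndarray, s1: float, s2: float, r: float) -> float:
    det = (1.0 - r * r) * s1 * s1 * s2 * s2
    q = (
        (e1 / s1) ** 2 - 2.0 * r * (e1 / s1) * (e2 / s2) + (e2 / s2) ** 2
    ) / (1.0 - r * r)
    return float(np.sum(-np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * q))


def log_prior(state: ParameterState, priors: PriorSpec, spec: ModelSpec) -> float:
    """Joint log prior density at ``state`` under ``spec``'s structure.

    Additive over parameter blocks: normal coefficients; beta se/sp when
    unknown; uniform random-effect scale(s) and correlation; normal (or
    bivariate normal) random intercepts.  Returns ``-inf`` outside any
    support.
    """
    lp = float(
        np.sum(stats.norm.logpdf(state.beta, scale=priors.coef_sd))
        + np.sum(stats.norm.logpdf(state.gamma, scale=priors.coef_sd))
    )
    if spec.misclass is Misclass.unknown:
        lp += float(
            stats.beta.logpdf(state.se, *priors.se_beta)
            + stats.beta.logpdf(state.sp, *priors.sp_beta)
        )
    if spec.effects in (Effects.random_common_variance, Effects.random_shared):
        if not 0.0 < state.sigma < priors.sigma_upper:
            return -np.inf
        lp += -np.log(priors.sigma_upper)
        lp += float(np.sum(stats.norm.logpdf(state.e_lambda, scale=state.sigma)))
        if spec.effects is Effects.random_common_variance:
            lp += float(np.sum(stats.norm.logpdf(state.e_mu, scale=state.sigma)))
    elif spec.effects is Effects.random_correlated:
        if not (
            0.0 < state.sigma1 < priors.sigma1_upper
            and 0.0 < state.sigma2 < priors.sigma2_upper
            and -1.0 < state.rho < 1.0
        ):
            return -np.inf
        lp += -np.log(priors.sigma1_upper) - np.log(priors.sigma2_upper) - np.log(2.0)
        lp += _bvn_logpdf(state.e_lambda, state.e_mu, state.sigma1, state.sigma2, state.rho)
    return lp
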