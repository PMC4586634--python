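"""Blockwise adaptive random-walk Metropolis sampling for all model variants.

The sampler targets the marginal observed-data likelihood (latent true
counts integrated out analytically) times the joint prior, so no latent
count augmentation is needed.  Parameter blocks: the two coefficient
vectors, (se, sp) jointly on the logit scale, the random-effect scale
parameters, and the per-cluster random-intercept pairs.  Proposal scales
adapt toward a 20-40% acceptance rate during burn-in only and are frozen
afterwards to preserve detailed balance.

In cut mode (Monte Carlo sensitivity analysis) se and sp are redrawn from
their priors every iteration with no Metropolis correction, so their
marginal "posterior" is exactly the prior while the remaining parameters
adapt to each drawn pair.

Two structural moves supplement the plain random-walk blocks.  When every
unit in a cluster shares a covariate pattern the likelihood constrains
only the cluster-level predictors, leaving the split between coefficients
and random intercepts prior-driven; a translation move shifts the
coefficient vector and compensates the intercepts so the predictors (and
hence the likelihood) are unchanged.  Likewise the data pin the two
observed mixture rates rather than (se, sp) themselves, so a compensated
move proposes (se, sp) and solves for the random intercepts that keep
every cluster's mixture rates fixed, with the exact Jacobian of that
deterministic transform in the acceptance ratio.  Without these moves the
over-parameterized corrected models mix far too slowly to be usable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import arviz as az
import numpy as np
import pandas as pd

from .model import (
    Effects,
    Misclass,
    ModelSpec,
    ObservedDataset,
    ParameterState,
    StructuralError,
)
from .priors import PriorSpec

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "PosteriorSummary",
    "initialize_chains",
    "fit",
    "summarize",
]

_ADAPT_BATCH = 25
_TARGET_ACCEPT = 0.3


@dataclass
class McmcSettings:
    n_chains: int = 4
    n_burn: int = 5000
    n_keep: int = 5000
    thin: int = 1
    seed: int = 0
    proposal_scales: dict = field(default_factory=dict)
    cut_se_sp: bool = False
    structural_moves: bool = True  # likelihood-invariant translation moves

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.thin < 1 or self.n_keep < 1 or self.n_burn < 0:
            raise StructuralError("invalid MCMC settings")
        if self.n_keep * self.thin + self.n_burn < 1000:
            warnings.warn(
                "fewer than 1000 total iterations per chain; summaries may "
                "be unreliable",
                stacklevel=2,
            )


@dataclass
class PosteriorDraws:
    """Retained draws, one row per kept iteration (chain-major)."""

    names: list
    draws: np.ndarray  # (n_chains * n_keep, n_params)
    chain: np.ndarray  # chain id per row
    meta: dict

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    @property
    def n_chains(self) -> int:
        return int(self.chain.max()) + 1

    def by_chain(self) -> np.ndarray:
        """Draws reshaped to (n_chains, n_keep, n_params)."""
        n_keep = self.draws.shape[0] // self.n_chains
        return self.draws.reshape(self.n_chains, n_keep, -1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.names)
        df.insert(0, "chain", self.chain)
        df.insert(1, "iteration", np.tile(
            np.arange(self.draws.shape[0] // self.n_chains), self.n_chains
        ))
        return df


@dataclass
class PosteriorSummary:
    """Posterior mean, equal-tailed interval, R-hat and ESS per parameter."""

    table: pd.DataFrame
    level: float = 0.95

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _param_names(spec: ModelSpec, K: int) -> list:
    q = spec.n_coef
    names = [f"beta{j}" for j in range(q)] + [f"gamma{j}" for j in range(q)]
    if spec.misclass is not Misclass.none:
        names += ["se", "sp"]
    if spec.effects in (Effects.random_common_variance, Effects.random_shared):
        names += ["sigma"]
    elif spec.effects is Effects.random_correlated:
        names += ["sigma1", "sigma2", "rho"]
    if spec.effects is Effects.random_shared:
        names += [f"e_{k}" for k in range(K)]
    elif spec.has_random_effects:
        names += [f"e_lambda_{k}" for k in range(K)]
        names += [f"e_mu_{k}" for k in range(K)]
    return names


def _check_se_sp_inputs(spec: ModelSpec, priors: PriorSpec) -> None:
    if spec.misclass is Misclass.known and (
        priors.se_fixed is None or priors.sp_fixed is None
    ):
        raise StructuralError(
            "known-misclassification model needs se_fixed and sp_fixed"
        )


def initialize_chains(
    spec: ModelSpec,
    priors: PriorSpec,
    data: ObservedDataset,
    settings: McmcSettings,
) -> list:
    """Overdispersed, deterministic starting states.

    Coefficients start from N(0, sd 0.5); unknown se/sp are drawn from
    their priors and redrawn until se + sp > 1 (the identifiability
    constraint excluding the label-swapped mirror solution); random-effect
    scales start in Unif(0.05, 1).
    """
    _check_se_sp_inputs(spec, priors)
    q = spec.n_coef
    K = data.n_clusters if spec.has_random_effects else 0
    if spec.has_random_effects and data.cluster is None:
        raise StructuralError("random-effects model requires cluster labels")
    states = []
    for c in range(settings.n_chains):
        rng = np.random.default_rng([settings.seed, c, 0])
        beta = rng.normal(0.0, 0.5, size=q)
        gamma = rng.normal(0.0, 0.5, size=q)
        se, sp = 1.0, 1.0
        if spec.misclass is Misclass.known:
            se, sp = priors.se_fixed, priors.sp_fixed
        elif spec.misclass is Misclass.unknown:
            for attempt in range(1000):
                se = rng.beta(*priors.se_beta)
                sp = rng.beta(*priors.sp_beta)
                if se + sp > 1.0:
                    break
            else:
                raise StructuralError(
                    "could not draw se + sp > 1 from the priors in 1000 "
                    "tries; priors concentrate on worse-than-random "
                    "classification"
                )
        kw = {}
        if spec.effects in (Effects.random_common_variance, Effects.random_shared):
            kw["sigma"] = min(rng.uniform(0.05, 1.0), 0.9 * priors.sigma_upper)
        elif spec.effects is Effects.random_correlated:
            kw["sigma1"] = min(rng.uniform(0.05, 1.0), 0.9 * priors.sigma1_upper)
            kw["sigma2"] = min(rng.uniform(0.05, 1.0), 0.9 * priors.sigma2_upper)
            kw["rho"] = rng.uniform(-0.5, 0.5)
        if spec.effects is Effects.random_shared:
            kw["e_lambda"] = rng.normal(0.0, 0.1, size=K)
        elif spec.has_random_effects:
            kw["e_lambda"] = rng.normal(0.0, 0.1, size=K)
            kw["e_mu"] = rng.normal(0.0, 0.1, size=K)
        states.append(
            ParameterState(beta=beta, gamma=gamma, se=se, sp=sp, **kw)
        )
    return states


class _ChainSampler:
    """One chain of the blockwise Metropolis sampler (internal)."""

    def __init__(self, spec, priors, data, settings, start, rng, prior_only):
        self.spec = spec
        self.priors = priors
        self.rng = rng
        self.prior_only = prior_only
        self.D = data.design
        self.t = data.t
        self.w1 = data.w1.astype(float)
        self.w2 = data.w2.astype(float)
        self.re = spec.has_random_effects
        self.shared = spec.effects is Effects.random_shared
        self.k = data.cluster if self.re else None
        self.K = data.n_clusters if self.re else 0
        self.q = spec.n_coef
        self.structural = settings.structural_moves
        self.update_sesp = (
            spec.misclass is Misclass.unknown and not settings.cut_se_sp
        )
        self.cut = spec.misclass is Misclass.unknown and settings.cut_se_sp

        self.beta = start.beta.copy()
        self.gamma = start.gamma.copy()
        self.se = float(start.se)
        self.sp = float(start.sp)
        if spec.misclass is Misclass.none:
            self.se = self.sp = 1.0
        self.sigma = float(start.sigma) if start.sigma > 0 else 0.5
        self.sigma1 = float(start.sigma1) if start.sigma1 > 0 else 0.5
        self.sigma2 = float(start.sigma2) if start.sigma2 > 0 else 0.5
        self.rho = float(start.rho)
        self.elam = start.e_lambda.copy() if self.re else np.zeros(0)
        self.emu = start.e_mu.copy() if self.re else np.zeros(0)
        if self.re and self.elam.shape[0] != self.K:
            self.elam = np.zeros(self.K)
        if self.re and not self.shared and self.emu.shape[0] != self.K:
            self.emu = np.zeros(self.K)

        # cluster-constant design => full-coefficient translation moves
        self.cluster_design = None
        if self.re:
            P = np.zeros((self.K, self.q))
            ok = True
            for k in range(self.K):
                rows = self.D[self.k == k]
                if not np.all(rows == rows[0]):
                    ok = False
                    break
                P[k] = rows[0]
            if ok:
                self.cluster_design = P
            self.first_idx = np.array(
                [int(np.argmax(self.k == kk)) for kk in range(self.K)]
            )

        scales = dict(settings.proposal_scales)
        self.s_beta = scales.get("beta", 0.05)
        self.s_gamma = scales.get("gamma", 0.05)
        self.s_sesp = scales.get("se_sp", 0.3)
        self.s_sigma = scales.get("sigma", 0.2)
        self.s_re = scales.get("random_effects", 0.05)
        self.s_shift_beta = scales.get("shift", 0.1)
        self.s_shift_gamma = scales.get("shift", 0.1)
        self.s_sesp_shift = scales.get("se_sp_shift", 0.3)
        self.s_ridge = scales.get("se_sp_ridge", 0.2)
        self.acc = {b: 0 for b in (
            "beta", "gamma", "se_sp", "sigma", "random_effects",
            "shift_beta", "shift_gamma", "se_sp_shift", "se_sp_ridge",
        )}
        self.tries = {b: 0 for b in self.acc}
        self.total_acc = {b: 0 for b in self.acc}
        self.total_tries = {b: 0 for b in self.acc}

        self.eta_b = self.D @ self.beta
        self.eta_g = self.D @ self.gamma
        self._refresh_rates()
        self.ll = self._ll(self.lam, self.mu, self.se, self.sp)
        if not np.isfinite(self.ll):
            raise StructuralError("non-finite posterior at initialization")

    # likelihood without constants: sum w1 log r1 + w2 log r2 - t (lam+mu)
    def _ll_vec(self, lam, mu, se, sp):
        r1 = lam * se + mu * (1.0 - sp)
        r2 = lam * (1.0 - se) + mu * sp
        with np.errstate(divide="ignore", invalid="ignore"):
            return (
                self.w1 * np.log(r1) + self.w2 * np.log(r2)
                - self.t * (lam + mu)
            )

    def _ll(self, lam, mu, se, sp):
        if self.prior_only:
            return 0.0
        v = self._ll_vec(lam, mu, se, sp)
        s = v.sum()
        return s if np.isfinite(s) else -np.inf

    def _refresh_rates(self):
        el = self.elam[self.k] if self.re else 0.0
        em = el if self.shared else (self.emu[self.k] if self.re else 0.0)
        with np.errstate(over="ignore"):
            self.lam = np.exp(self.eta_b + el)
            self.mu = np.exp(self.eta_g + em)

    def _mh(self, block, log_alpha):
        self.tries[block] += 1
        ok = np.isfinite(log_alpha) and (
            log_alpha >= 0.0 or np.log(self.rng.random()) < log_alpha
        )
        if ok:
            self.acc[block] += 1
        return ok

    def _update_beta(self):
        prop = self.beta + self.s_beta * self.rng.standard_normal(self.q)
        eta = self.D @ prop
        with np.errstate(over="ignore"):
            lam = np.exp(eta + (self.elam[self.k] if self.re else 0.0))
        ll = self._ll(lam, self.mu, self.se, self.sp)
        dprior = (self.beta @ self.beta - prop @ prop) / (2.0 * self.priors.coef_sd**2)
        if self._mh("beta", ll - self.ll + dprior):
            self.beta, self.eta_b, self.lam, self.ll = prop, eta, lam, ll

    def _update_gamma(self):
        prop = self.gamma + self.s_gamma * self.rng.standard_normal(self.q)
        eta = self.D @ prop
        if self.shared:
            em = self.elam[self.k]
        else:
            em = self.emu[self.k] if self.re else 0.0
        with np.errstate(over="ignore"):
            mu = np.exp(eta + em)
        ll = self._ll(self.lam, mu, self.se, self.sp)
        dprior = (self.gamma @ self.gamma - prop @ prop) / (2.0 * self.priors.coef_sd**2)
        if self._mh("gamma", ll - self.ll + dprior):
            self.gamma, self.eta_g, self.mu, self.ll = prop, eta, mu, ll

    def _sesp_logprior(self, se, sp):
        # beta log-density plus the logit-scale Jacobian log(p(1-p))
        a1, b1 = self.priors.se_beta
        a2, b2 = self.priors.sp_beta
        return (
            a1 * np.log(se) + b1 * np.log1p(-se)
            + a2 * np.log(sp) + b2 * np.log1p(-sp)
        )

    def _update_sesp(self):
        z = self.rng.standard_normal(2)
        l_se = np.log(self.se) - np.log1p(-self.se) + self.s_sesp * z[0]
        l_sp = np.log(self.sp) - np.log1p(-self.sp) + self.s_sesp * z[1]
        se = 1.0 / (1.0 + np.exp(-l_se))
        sp = 1.0 / (1.0 + np.exp(-l_sp))
        if se <= 0.0 or se >= 1.0 or sp <= 0.0 or sp >= 1.0:
            self.tries["se_sp"] += 1
            return
        ll = self._ll(self.lam, self.mu, se, sp)
        dprior = self._sesp_logprior(se, sp) - self._sesp_logprior(self.se, self.sp)
        if self._mh("se_sp", ll - self.ll + dprior):
            self.se, self.sp, self.ll = se, sp, ll

    def _gibbs_sesp(self):
        """Augmented conjugate update of (se, sp).

        Each observed count is a sum of two independent thinned Poissons:
        w1 = (kept cause-of-interest) + (crossed-over other-cause) with
        rates t*lam*se and t*mu*(1-sp).  Conditional on the rates, the
        split is binomial; conditional on the split, se and sp have beta
        full conditionals.  The latent splits are drawn and discarded,
        leaving an exact Gibbs move on the marginal space.
        """
        p1 = self.lam * self.se / (self.lam * self.se + self.mu * (1.0 - self.sp))
        n11 = self.rng.binomial(self.w1.astype(np.int64), p1)
        u2 = self.w1 - n11
        p2 = self.mu * self.sp / (self.mu * self.sp + self.lam * (1.0 - self.se))
        n22 = self.rng.binomial(self.w2.astype(np.int64), p2)
        u1 = self.w2 - n22
        a1, b1 = self.priors.se_beta
        a2, b2 = self.priors.sp_beta
        self.se = float(self.rng.beta(a1 + n11.sum(), b1 + u1.sum()))
        self.sp = float(self.rng.beta(a2 + n22.sum(), b2 + u2.sum()))
        self.ll = self._ll(self.lam, self.mu, self.se, self.sp)

    def _sesp_ridge_move(self):
        """Joint (se, sp, intercepts) move along the likelihood ridge.

        The data pin the mixture rates, so a change of se demands a
        compensating change of lambda; to first order lambda scales as
        1/se (and mu as 1/sp).  Proposing (se, sp) on the logit scale and
        translating the intercepts by log(se/se') and log(sp/sp') is a
        pure translation in (logit se, logit sp, beta0, gamma0) space —
        unit Jacobian, symmetric — that travels along the ridge instead
        of fighting it.  Valid for every model with unknown (se, sp),
        including fixed effects.
        """
        z = self.rng.standard_normal(2)
        l_se = np.log(self.se) - np.log1p(-self.se) + self.s_ridge * z[0]
        l_sp = np.log(self.sp) - np.log1p(-self.sp) + self.s_ridge * z[1]
        se = 1.0 / (1.0 + np.exp(-l_se))
        sp = 1.0 / (1.0 + np.exp(-l_sp))
        self.tries["se_sp_ridge"] += 1
        if not (0.0 < se < 1.0 and 0.0 < sp < 1.0):
            return
        db0 = np.log(self.se) - np.log(se)
        dg0 = np.log(self.sp) - np.log(sp)
        lam = self.lam * np.exp(db0)
        mu = self.mu * np.exp(dg0)
        ll = self._ll(lam, mu, se, sp)
        b0, g0 = self.beta[0], self.gamma[0]
        dprior = (
            self._sesp_logprior(se, sp)
            - self._sesp_logprior(self.se, self.sp)
            + (b0**2 - (b0 + db0) ** 2 + g0**2 - (g0 + dg0) ** 2)
            / (2.0 * self.priors.coef_sd**2)
        )
        self.tries["se_sp_ridge"] -= 1  # _mh re-counts
        if self._mh("se_sp_ridge", ll - self.ll + dprior):
            self.se, self.sp = float(se), float(sp)
            self.beta = self.beta.copy()
            self.gamma = self.gamma.copy()
            self.beta[0] += db0
            self.gamma[0] += dg0
            self.eta_b = self.eta_b + db0
            self.eta_g = self.eta_g + dg0
            self.lam, self.mu, self.ll = lam, mu, ll

    def _cut_draw(self):
        self.se = float(self.rng.beta(*self.priors.se_beta))
        self.sp = float(self.rng.beta(*self.priors.sp_beta))
        self.ll = self._ll(self.lam, self.mu, self.se, self.sp)

    def _shift_move(self, which):
        """Translate coefficients against intercepts; likelihood-invariant.

        Per-unit predictors eta_i = x_i'beta + e_k(i) are unchanged, so only
        the coefficient and random-intercept priors enter the ratio.
        """
        P = self.cluster_design
        block = f"shift_{which}"
        scale = self.s_shift_beta if which == "beta" else self.s_shift_gamma
        if P is None:
            # covariates vary within clusters: only the overall level is
            # flat, so translate the intercept alone
            P = np.zeros((self.K, self.q))
            P[:, 0] = 1.0
            delta = np.zeros(self.q)
            delta[0] = scale * self.rng.standard_normal()
        else:
            delta = scale * self.rng.standard_normal(self.q)
        if self.shared:
            # one intercept serves both streams: shift both coefficient
            # vectors together against it
            beta_p = self.beta + delta
            gamma_p = self.gamma + delta
            e_prop = self.elam - P @ delta
            dprior = (
                self.beta @ self.beta - beta_p @ beta_p
                + self.gamma @ self.gamma - gamma_p @ gamma_p
            ) / (2.0 * self.priors.coef_sd**2)
            dre = self._re_logprior_sum(e_prop, None) - self._re_logprior_sum(
                self.elam, None
            )
            if self._mh(block, dprior + float(np.sum(dre))):
                self.beta, self.gamma, self.elam = beta_p, gamma_p, e_prop
                self.eta_b = self.D @ beta_p
                self.eta_g = self.D @ gamma_p
            return
        if which == "beta":
            coef, e = self.beta, self.elam
        else:
            coef, e = self.gamma, self.emu
        prop = coef + delta
        e_prop = e - P @ delta
        dprior = (coef @ coef - prop @ prop) / (2.0 * self.priors.coef_sd**2)
        if which == "beta":
            dre = self._re_logprior_sum(e_prop, self.emu) - self._re_logprior_sum(
                self.elam, self.emu
            )
        else:
            dre = self._re_logprior_sum(self.elam, e_prop) - self._re_logprior_sum(
                self.elam, self.emu
            )
        if self._mh(block, dprior + float(np.sum(dre))):
            if which == "beta":
                self.beta, self.elam = prop, e_prop
                self.eta_b = self.D @ prop
            else:
                self.gamma, self.emu = prop, e_prop
                self.eta_g = self.D @ prop

    def _sesp_shift_move(self):
        """Propose (se, sp) and compensate the random intercepts so every
        cluster's two observed mixture rates are unchanged (likelihood-
        invariant).  Requires a cluster-constant design.

        Deterministic-transform MH: the per-cluster map (e_lam, e_mu) ->
        (e_lam', e_mu') at fixed mixture rates has Jacobian
        lam * mu * (se + sp - 1) / (lam' * mu' * (se' + sp' - 1)).
        """
        if self.cluster_design is None:
            return
        z = self.rng.standard_normal(2)
        l_se = np.log(self.se) - np.log1p(-self.se) + self.s_sesp_shift * z[0]
        l_sp = np.log(self.sp) - np.log1p(-self.sp) + self.s_sesp_shift * z[1]
        se = 1.0 / (1.0 + np.exp(-l_se))
        sp = 1.0 / (1.0 + np.exp(-l_sp))
        dpp = se + sp - 1.0
        self.tries["se_sp_shift"] += 1
        if not (0.0 < se < 1.0 and 0.0 < sp < 1.0) or dpp <= 0.0:
            return
        d = self.se + self.sp - 1.0
        if d <= 0.0:
            return
        # cluster-level rates (any unit in the cluster is representative)
        lam_k = self.lam[self.first_idx]
        mu_k = self.mu[self.first_idx]
        a = lam_k * self.se + mu_k * (1.0 - self.sp)
        b = lam_k * (1.0 - self.se) + mu_k * self.sp
        lam_new = (a * sp - b * (1.0 - sp)) / dpp
        mu_new = (b * se - a * (1.0 - se)) / dpp
        if np.any(lam_new <= 0.0) or np.any(mu_new <= 0.0):
            return
        elam = self.elam + np.log(lam_new) - np.log(lam_k)
        emu = self.emu + np.log(mu_new) - np.log(mu_k)
        log_jac = float(
            np.sum(np.log(lam_k) + np.log(mu_k) - np.log(lam_new) - np.log(mu_new))
            + self.K * (np.log(d) - np.log(dpp))
        )
        dprior = (
            self._sesp_logprior(se, sp)
            - self._sesp_logprior(self.se, self.sp)
            + float(
                np.sum(
                    self._re_logprior_sum(elam, emu)
                    - self._re_logprior_sum(self.elam, self.emu)
                )
            )
        )
        self.tries["se_sp_shift"] -= 1  # _mh re-counts
        if self._mh("se_sp_shift", dprior + log_jac):
            self.se, self.sp = float(se), float(sp)
            self.elam, self.emu = elam, emu
            self.lam = lam_new[self.k]
            self.mu = mu_new[self.k]
            self.ll = self._ll(self.lam, self.mu, self.se, self.sp)

    def _re_logprior_sum(self, elam, emu):
        if self.shared:
            return -(elam**2) / (2.0 * self.sigma**2)
        if self.spec.effects is Effects.random_common_variance:
            return -(elam**2 + emu**2) / (2.0 * self.sigma**2)
        s1, s2, r = self.sigma1, self.sigma2, self.rho
        a, b = elam / s1, emu / s2
        return -(a * a - 2.0 * r * a * b + b * b) / (2.0 * (1.0 - r * r))

    def _update_sigma(self):
        if self.spec.effects is not Effects.random_correlated:
            prop = self.sigma + self.s_sigma * self.rng.standard_normal()
            self.tries["sigma"] += 1
            if not 0.0 < prop < self.priors.sigma_upper:
                return
            if self.shared:
                S = float(self.elam @ self.elam)
                n_re = self.K
            else:
                S = float(self.elam @ self.elam + self.emu @ self.emu)
                n_re = 2 * self.K
            la = (
                -n_re * (np.log(prop) - np.log(self.sigma))
                - S / (2.0 * prop**2) + S / (2.0 * self.sigma**2)
            )
            if np.isfinite(la) and (la >= 0 or np.log(self.rng.random()) < la):
                self.sigma = prop
                self.acc["sigma"] += 1
        else:
            z = self.rng.standard_normal(3)
            s1 = self.sigma1 + self.s_sigma * z[0]
            s2 = self.sigma2 + self.s_sigma * z[1]
            r = self.rho + self.s_sigma * z[2]
            self.tries["sigma"] += 1
            if not (
                0.0 < s1 < self.priors.sigma1_upper
                and 0.0 < s2 < self.priors.sigma2_upper
                and -1.0 < r < 1.0
            ):
                return
            def lp(s1_, s2_, r_):
                a, b = self.elam / s1_, self.emu / s2_
                quad = (a * a - 2.0 * r_ * a * b + b * b).sum() / (1.0 - r_ * r_)
                return (
                    -self.K * (np.log(s1_) + np.log(s2_) + 0.5 * np.log1p(-r_ * r_))
                    - 0.5 * quad
                )
            la = lp(s1, s2, r) - lp(self.sigma1, self.sigma2, self.rho)
            if np.isfinite(la) and (la >= 0 or np.log(self.rng.random()) < la):
                self.sigma1, self.sigma2, self.rho = s1, s2, r
                self.acc["sigma"] += 1

    def _update_re(self):
        elam = self.elam + self.s_re * self.rng.standard_normal(self.K)
        if self.shared:
            emu = self.emu
            with np.errstate(over="ignore"):
                lam = np.exp(self.eta_b + elam[self.k])
                mu = np.exp(self.eta_g + elam[self.k])
        else:
            emu = self.emu + self.s_re * self.rng.standard_normal(self.K)
            with np.errstate(over="ignore"):
                lam = np.exp(self.eta_b + elam[self.k])
                mu = np.exp(self.eta_g + emu[self.k])
        if self.prior_only:
            dll = np.zeros(self.K)
        else:
            dv = self._ll_vec(lam, mu, self.se, self.sp) - self._ll_vec(
                self.lam, self.mu, self.se, self.sp
            )
            dv = np.where(np.isfinite(dv), dv, -np.inf)
            dll = np.bincount(self.k, weights=dv, minlength=self.K)
        la = dll + self._re_logprior_sum(elam, emu) - self._re_logprior_sum(
            self.elam, self.emu
        )
        with np.errstate(invalid="ignore"):
            accept = np.log(self.rng.random(self.K)) < la
        accept &= np.isfinite(la)
        self.tries["random_effects"] += self.K
        n_acc = int(accept.sum())
        self.acc["random_effects"] += n_acc
        if n_acc:
            self.elam = np.where(accept, elam, self.elam)
            if not self.shared:
                self.emu = np.where(accept, emu, self.emu)
            mask = accept[self.k]
            self.lam = np.where(mask, lam, self.lam)
            self.mu = np.where(mask, mu, self.mu)
            self.ll = self._ll(self.lam, self.mu, self.se, self.sp)

    def _adapt(self, batch_index):
        delta = min(0.25, 2.0 / np.sqrt(batch_index + 1.0))
        for block, attr in (
            ("beta", "s_beta"),
            ("gamma", "s_gamma"),
            ("se_sp", "s_sesp"),
            ("sigma", "s_sigma"),
            ("random_effects", "s_re"),
            ("shift_beta", "s_shift_beta"),
            ("shift_gamma", "s_shift_gamma"),
            ("se_sp_shift", "s_sesp_shift"),
            ("se_sp_ridge", "s_ridge"),
        ):
            if self.tries[block] == 0:
                continue
            rate = self.acc[block] / self.tries[block]
            setattr(
                self,
                attr,
                getattr(self, attr) * np.exp(delta * (rate - _TARGET_ACCEPT)),
            )
            self.total_acc[block] += self.acc[block]
            self.total_tries[block] += self.tries[block]
            self.acc[block] = 0
            self.tries[block] = 0

    def step(self):
        self._update_beta()
        self._update_gamma()
        if self.re and self.structural:
            self._shift_move("beta")
            if not self.shared:
                self._shift_move("gamma")
        # (se, sp) stay frozen at their se+sp>1 starting values for the
        # first half of burn-in: the rate models must orient themselves
        # before the classifier parameters move, otherwise a chain can
        # wander into the label-swapped mirror mode and stick there
        if self.update_sesp and self.sesp_on:
            self._update_sesp()
            if self.structural:
                self._sesp_ridge_move()
            if not self.prior_only:
                self._gibbs_sesp()
            if self.re and self.structural and not self.shared:
                self._sesp_shift_move()
        elif self.cut:
            self._cut_draw()
        if self.re:
            self._update_sigma()
            self._update_re()

    def run(self, settings):
        n_burn, n_keep, thin = settings.n_burn, settings.n_keep, settings.thin
        out = np.empty((n_keep, self._n_out()))
        self.sesp_on = n_burn == 0
        for i in range(n_burn):
            self.sesp_on = i >= n_burn // 2
            self.step()
            if (i + 1) % _ADAPT_BATCH == 0:
                self._adapt((i + 1) // _ADAPT_BATCH)
        self.sesp_on = True
        for b in self.acc:
            self.acc[b] = 0
            self.tries[b] = 0
        j = 0
        for i in range(n_keep * thin):
            self.step()
            if (i + 1) % thin == 0:
                out[j] = self._collect()
                j += 1
        for b in self.acc:
            self.total_acc[b] += self.acc[b]
            self.total_tries[b] += self.tries[b]
        return out

    def _n_out(self):
        n = 2 * self.q
        if self.spec.misclass is not Misclass.none:
            n += 2
        if self.spec.effects in (Effects.random_common_variance, Effects.random_shared):
            n += 1
        elif self.spec.effects is Effects.random_correlated:
            n += 3
        if self.shared:
            n += self.K
        elif self.re:
            n += 2 * self.K
        return n

    def _collect(self):
        parts = [self.beta, self.gamma]
        if self.spec.misclass is not Misclass.none:
            parts.append([self.se, self.sp])
        if self.spec.effects in (Effects.random_common_variance, Effects.random_shared):
            parts.append([self.sigma])
        elif self.spec.effects is Effects.random_correlated:
            parts.append([self.sigma1, self.sigma2, self.rho])
        if self.shared:
            parts.append(self.elam)
        elif self.re:
            parts.extend([self.elam, self.emu])
        return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])

    def acceptance_rates(self):
        return {
            b: (self.total_acc[b] / self.total_tries[b])
            for b in self.total_acc
            if self.total_tries[b] > 0
        }


def fit(
    spec: ModelSpec,
    priors: PriorSpec,
    data: ObservedDataset,
    settings: McmcSettings,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Sample the posterior for one model on one dataset.

    ``prior_only=True`` switches the likelihood term off so the sampler
    targets the prior alone (a validation hook: posterior moments must then
    reproduce prior moments).
    """
    _check_se_sp_inputs(spec, priors)
    if spec.has_random_effects and data.cluster is None:
        raise StructuralError("random-effects model requires cluster labels")
    if spec.p != data.p:
        raise StructuralError(
            f"spec.p={spec.p} does not match data covariate count {data.p}"
        )
    starts = initialize_chains(spec, priors, data, settings)
    K = data.n_clusters if spec.has_random_effects else 0
    names = _param_names(spec, K)
    chains = []
    acc = []
    for c, start in enumerate(starts):
        rng = np.random.default_rng([settings.seed, c, 1])
        sampler = _ChainSampler(spec, priors, data, settings, start, rng, prior_only)
        chains.append(sampler.run(settings))
        acc.append(sampler.acceptance_rates())
    draws = np.vstack(chains)
    chain_id = np.repeat(np.arange(settings.n_chains), settings.n_keep)
    meta = {
        "settings": settings,
        "spec": spec,
        "acceptance_rates": acc,
        "prior_only": prior_only,
    }
    return PosteriorDraws(names=names, draws=draws, chain=chain_id, meta=meta)


def summarize(draws: PosteriorDraws, level: float = 0.95) -> PosteriorSummary:
    """Posterior mean, equal-tailed interval, split-chain R-hat and ESS.

    Intervals are empirical quantiles with linear interpolation; R-hat and
    ESS are rank-normalized split-chain diagnostics.  A constant chain is
    flagged with NaN diagnostics rather than an error.
    """
    if draws.draws.shape[0] < 100:
        raise StructuralError("need at least 100 retained draws to summarize")
    if not 0.0 < level < 1.0:
        raise StructuralError("level must lie in (0, 1)")
    arr = draws.by_chain()  # (chains, draws, params)
    alpha = (1.0 - level) / 2.0
    mean = arr.mean(axis=(0, 1))
    lower = np.quantile(draws.draws, alpha, axis=0)
    upper = np.quantile(draws.draws, 1.0 - alpha, axis=0)
    diag = arr
    if diag.shape[0] == 1:
        # a single chain is split into halves for the diagnostics
        half = diag.shape[1] // 2
        diag = np.stack([diag[0, :half], diag[0, half:2 * half]])
    ds = az.convert_to_dataset(
        diag, dims={"x": ["param"]}, coords={"param": draws.names}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)["x"].values
        ess = az.ess(ds)["x"].values
    constant = arr.std(axis=(0, 1)) == 0.0
    rhat = np.where(constant, np.nan, rhat)
    ess = np.where(constant, np.nan, ess)
    table = pd.DataFrame(
        {
            "mean": mean,
            "lower": lower,
            "upper": upper,
            "rhat": rhat,
            "ess": ess,
            "degenerate": constant,
        },
        index=pd.Index(draws.names, name="parameter"),
    )
    return PosteriorSummary(table=table, level=level)
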