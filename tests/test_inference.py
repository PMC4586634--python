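"""Sampler behaviour: initialization, posterior correctness, summaries."""

import numpy as np
import pytest
from scipy import stats

from miscount import (
    McmcSettings,
    ModelSpec,
    ObservedDataset,
    PosteriorDraws,
    PriorSpec,
    StructuralError,
    fit,
    initialize_chains,
    summarize,
)
from miscount.simulate import Design, TruthConfig, generate_dataset, make_design


def _settings(**kw):
    base = dict(n_chains=2, n_burn=300, n_keep=300, seed=1)
    base.update(kw)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return McmcSettings(**base)


class TestInitializeChains:
    def test_same_seed_gives_identical_states(self, small_dataset, fixed_spec,
                                              tight_priors):
        s = _settings(n_chains=3)
        a = initialize_chains(fixed_spec, tight_priors, small_dataset, s)
        b = initialize_chains(fixed_spec, tight_priors, small_dataset, s)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.beta, sb.beta)
            assert sa.se == sb.se and sa.sp == sb.sp

    def test_identifiability_constraint_holds(self, small_dataset, fixed_spec):
        # even diffuse priors must start on the better-than-random side
        pri = PriorSpec(se_beta=(2.0, 1.5), sp_beta=(1.5, 2.0))
        states = initialize_chains(fixed_spec, pri, small_dataset,
                                   _settings(n_chains=8))
        for st in states:
            assert st.se + st.sp > 1.0

    def test_known_values_used_directly(self, small_dataset):
        spec = ModelSpec(effects="fixed", misclass="known", p=0)
        pri = PriorSpec(se_fixed=0.7, sp_fixed=0.8)
        states = initialize_chains(spec, pri, small_dataset, _settings())
        assert all(st.se == 0.7 and st.sp == 0.8 for st in states)

    def test_worse_than_random_priors_raise(self, small_dataset, fixed_spec):
        pri = PriorSpec(se_beta=(1.0, 60.0), sp_beta=(1.0, 60.0))
        with pytest.raises(StructuralError, match="worse-than-random"):
            initialize_chains(fixed_spec, pri, small_dataset, _settings())

    def test_missing_fixed_values_raise(self, small_dataset):
        spec = ModelSpec(effects="fixed", misclass="known", p=0)
        with pytest.raises(StructuralError):
            initialize_chains(spec, PriorSpec(), small_dataset, _settings())


class TestFit:
    def test_same_seed_is_bit_identical(self, small_dataset, fixed_spec,
                                        tight_priors):
        s = _settings(n_chains=1, n_burn=150, n_keep=120)
        a = fit(fixed_spec, tight_priors, small_dataset, s)
        b = fit(fixed_spec, tight_priors, small_dataset, s)
        assert np.array_equal(a.draws, b.draws)

    def test_random_effects_need_clusters(self, tight_priors):
        data = ObservedDataset(w1=np.array([1]), w2=np.array([1]),
                               t=np.array([1.0]), x=np.array([0.0]),
                               z=np.empty((1, 0)))
        spec = ModelSpec(effects="random_shared", misclass="unknown", p=0)
        with pytest.raises(StructuralError, match="cluster"):
            fit(spec, tight_priors, data, _settings())

    def test_prior_only_recovers_prior_moments(self, small_dataset,
                                               fixed_spec, tight_priors):
        # with the likelihood switched off the sampler must reproduce the
        # prior: beta moments for (se, sp), N(0, coef_sd) for coefficients
        s = _settings(n_chains=2, n_burn=500, n_keep=1500, seed=2)
        d = fit(fixed_spec, tight_priors, small_dataset, s, prior_only=True)
        se_mean, se_sd = stats.beta.mean(45, 5), stats.beta.std(45, 5)
        sp_mean, sp_sd = stats.beta.mean(40, 10), stats.beta.std(40, 10)
        assert d["se"].mean() == pytest.approx(se_mean, abs=3 * se_sd / 10)
        assert d["sp"].mean() == pytest.approx(sp_mean, abs=3 * sp_sd / 10)
        assert d["se"].std() == pytest.approx(se_sd, rel=0.25)
        # coefficients: very diffuse, so allow generous Monte Carlo slack
        assert abs(d["beta1"].mean()) < 3.0
        assert d["beta1"].std() == pytest.approx(10.0, rel=0.4)

    def test_cut_mode_se_draws_match_prior(self, small_dataset, tight_priors):
        spec = ModelSpec(effects="fixed", misclass="unknown", p=0)
        s = _settings(n_chains=1, n_burn=200, n_keep=5000, seed=4,
                      cut_se_sp=True)
        d = fit(spec, tight_priors, small_dataset, s)
        ks = stats.kstest(d["se"], stats.beta(45, 5).cdf).statistic
        assert ks < 0.05
        ks2 = stats.kstest(d["sp"], stats.beta(40, 10).cdf).statistic
        assert ks2 < 0.05

    def test_naive_recovery_on_clean_data(self):
        # perfect classification, many events: posterior concentrates on
        # the generating coefficients
        base = make_design(1, 16)
        design = Design(x=base.x, z=base.z, cluster=base.cluster)
        truth = TruthConfig(
            beta_true=np.array([-1.0, 0.5]),
            gamma_true=np.array([-2.0, -0.3]),
            design=design, se_true=1.0, sp_true=1.0, person_time=500.0,
        )
        data = generate_dataset(truth, seed=6)
        spec = ModelSpec(effects="fixed", misclass="none", p=0)
        d = fit(spec, PriorSpec(), data, _settings(n_chains=1, n_burn=800,
                                                   n_keep=1200, seed=7))
        for name, true_val in (("beta1", 0.5), ("gamma1", -0.3)):
            post = d[name]
            assert abs(post.mean() - true_val) < 3 * post.std()

    def test_known_misclass_is_limit_of_degenerate_priors(self):
        # beta priors collapsing onto the fixed values reproduce the
        # known-misclassification posterior
        rng = np.random.default_rng(20)
        x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        t = np.full(8, 60.0)
        lam = np.exp(-0.5 + 0.4 * x)
        mu = np.exp(-1.0 - 0.2 * x)
        data = ObservedDataset(
            w1=rng.poisson(t * (0.85 * lam + 0.25 * mu)),
            w2=rng.poisson(t * (0.15 * lam + 0.75 * mu)),
            t=t, x=x, z=np.empty((8, 0)),
        )
        known = ModelSpec(effects="fixed", misclass="known", p=0)
        unknown = ModelSpec(effects="fixed", misclass="unknown", p=0)
        pri_known = PriorSpec(se_fixed=0.85, sp_fixed=0.75)
        big = 4e6
        pri_degen = PriorSpec(se_beta=(0.85 * big, 0.15 * big),
                              sp_beta=(0.75 * big, 0.25 * big))
        s = _settings(n_chains=1, n_burn=1500, n_keep=3000, seed=8)
        d1 = fit(known, pri_known, data, s)
        d2 = fit(unknown, pri_degen, data, s)
        for name in ("beta1", "gamma1"):
            mc = 3 * (d1[name].std() + d2[name].std()) / np.sqrt(200.0)
            assert d1[name].mean() == pytest.approx(d2[name].mean(),
                                                    abs=max(mc, 0.02))

    def test_posterior_matches_independent_ensemble_sampler(self):
        # dual route: the blockwise Metropolis posterior against an
        # affine-invariant ensemble sampler driving an independently
        # written, vectorized log-density of the same model
        import emcee

        rng = np.random.default_rng(10)
        x = np.array([0.0, 0, 0, 1, 1, 1])
        t = np.full(6, 30.0)
        lam0 = np.exp(-0.5 + 0.4 * x)
        mu0 = np.exp(-1.0 - 0.2 * x)
        w1 = rng.poisson(t * (0.9 * lam0 + 0.2 * mu0))
        w2 = rng.poisson(t * (0.1 * lam0 + 0.8 * mu0))
        data = ObservedDataset(w1=w1, w2=w2, t=t, x=x, z=np.empty((6, 0)))
        spec = ModelSpec(effects="fixed", misclass="unknown", p=0)
        pri = PriorSpec(se_beta=(45.0, 5.0), sp_beta=(40.0, 10.0))

        def logpost(theta):
            theta = np.atleast_2d(theta)
            b0, b1, g0, g1, lse, lsp = theta.T
            se = 1.0 / (1.0 + np.exp(-lse))
            sp = 1.0 / (1.0 + np.exp(-lsp))
            lam = np.exp(b0[:, None] + b1[:, None] * x)
            mu = np.exp(g0[:, None] + g1[:, None] * x)
            r1 = lam * se[:, None] + mu * (1 - sp[:, None])
            r2 = lam * (1 - se[:, None]) + mu * sp[:, None]
            ll = (w1 * np.log(t * r1) + w2 * np.log(t * r2)
                  - t * (lam + mu)).sum(axis=1)
            lp = -(b0**2 + b1**2 + g0**2 + g1**2) / 200.0
            # beta density on the logit scale: a log se + b log(1-se)
            lp = lp + 45 * np.log(se) + 5 * np.log1p(-se)
            lp = lp + 40 * np.log(sp) + 10 * np.log1p(-sp)
            return ll + lp

        ndim, nwalk = 6, 32
        p0 = np.column_stack([
            rng.normal(-0.5, 0.1, nwalk), rng.normal(0.3, 0.1, nwalk),
            rng.normal(-1.0, 0.1, nwalk), rng.normal(-0.2, 0.1, nwalk),
            rng.normal(2.2, 0.2, nwalk), rng.normal(1.4, 0.2, nwalk),
        ])
        sampler = emcee.EnsembleSampler(nwalk, ndim, logpost, vectorize=True)
        sampler.random_state = np.random.RandomState(2718).get_state()
        sampler.run_mcmc(p0, 6000, progress=False)
        chain = sampler.get_chain(discard=2000, flat=True)
        ref_b1 = chain[:, 1].mean()
        ref_se = (1.0 / (1.0 + np.exp(-chain[:, 4]))).mean()

        d = fit(spec, pri, data, _settings(n_chains=2, n_burn=2000,
                                           n_keep=10000, seed=12))
        assert d["beta1"].mean() == pytest.approx(ref_b1, abs=0.04)
        assert d["se"].mean() == pytest.approx(ref_se, abs=0.015)


class TestSummarize:
    def _draws(self, arr, n_chains=1):
        arr = np.asarray(arr, float)
        if arr.ndim == 1:
            arr = arr[:, None]
        chain = np.repeat(np.arange(n_chains), arr.shape[0] // n_chains)
        return PosteriorDraws(names=["theta"], draws=arr, chain=chain,
                              meta={})

    def test_constant_chain_flagged_degenerate(self):
        s = summarize(self._draws(np.full(400, 3.14)))
        row = s["theta"]
        assert row["mean"] == pytest.approx(3.14)
        assert row["lower"] == row["upper"] == pytest.approx(3.14)
        assert bool(row["degenerate"])

    def test_equal_tailed_quantile_rule(self):
        s = summarize(self._draws(np.arange(1.0, 1001.0)))
        row = s["theta"]
        assert row["lower"] == pytest.approx(25.975)
        assert row["upper"] == pytest.approx(975.025)

    def test_two_chains_from_same_distribution_converge(self):
        rng = np.random.default_rng(3)
        s = summarize(self._draws(rng.normal(size=2000), n_chains=2))
        assert s["theta"]["rhat"] < 1.05
        lo, hi = s["theta"]["lower"], s["theta"]["upper"]
        assert lo <= s["theta"]["mean"] <= hi

    def test_too_few_draws_rejected(self):
        with pytest.raises(StructuralError):
            summarize(self._draws(np.arange(50.0)))

    def test_draw_export_round_trip(self, small_dataset, fixed_spec,
                                    tight_priors):
        d = fit(fixed_spec, tight_priors, small_dataset,
                _settings(n_chains=2, n_burn=100, n_keep=150))
        df = d.to_dataframe()
        assert list(df["chain"].unique()) == [0, 1]
        assert df.shape[0] == 300
        assert np.array_equal(df[d.names].to_numpy(), d.draws)
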