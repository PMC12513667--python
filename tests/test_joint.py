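"""Joint model: trajectory functionals, likelihood closed forms, sampler
contracts (determinism, conjugacy, quadrature stability, prior vagueness)."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from bpjoint.joint import (
    AssociationSpec,
    JointModelSpec,
    MCMCSettings,
    PosteriorDraws,
    SubjectHazard,
    eta_eval,
    run_mcmc,
    subject_loglik,
    summarize_fit,
)
from bpjoint.simulate import GeneratorConfig, simulate_cohort
from bpjoint.splines import NaturalCubicSplineBasis

from conftest import scaled_generator, scaled_model_spec

BASIS = NaturalCubicSplineBasis([40.0, 80.0], boundary=(0.0, 120.0))


class TestEtaEval:
    def test_zero_parameters_give_zero(self):
        info = {"basis": BASIS, "w": np.zeros(3)}
        for mode in ("value", "slope", "area"):
            assert eta_eval(17.0, np.zeros(7), np.zeros(4), info, mode) == 0.0

    def test_linear_trajectory_closed_forms(self):
        # eta(t) = a + c * t via the (linear, scaled) first basis column
        a, c_raw = 2.0, -0.5
        scale = BASIS.design([120.0])[0, 0] / 120.0  # N1(t) = scale * t
        beta = np.array([a, c_raw / scale, 0.0, 0.0])
        info = {"basis": BASIS, "w": ()}
        t = 37.0
        assert eta_eval(t, beta, np.zeros(4), info, "value") == pytest.approx(
            a + c_raw * t, abs=1e-9)
        assert eta_eval(t, beta, np.zeros(4), info, "slope") == pytest.approx(
            c_raw, abs=1e-12)
        assert eta_eval(t, beta, np.zeros(4), info, "area") == pytest.approx(
            a * t + c_raw * t**2 / 2, abs=1e-8)

    def test_area_matches_adaptive_quadrature(self):
        rng = np.random.default_rng(5)
        beta = rng.normal(size=6)
        b = rng.normal(size=4) * 0.3
        w = rng.normal(size=2)
        info = {"basis": BASIS, "w": w}
        t = 17.3
        num, _ = quad(lambda s: eta_eval(s, beta, b, info, "value"), 0, t,
                      limit=400, epsabs=1e-12, epsrel=1e-12)
        assert eta_eval(t, beta, b, info, "area") == pytest.approx(num, abs=1e-8)


def _one_subject_data(T=24.0, delta=1.0, times=(0.0, 3.0, 6.0)):
    return {
        "times_sbp": np.array(times), "y_sbp": np.array([14.1, 14.0, 13.8]),
        "times_dbp": np.array(times), "y_dbp": np.array([9.2, 9.1, 9.0]),
        "w_long": np.zeros(8), "w_surv": np.zeros(2), "T": T, "delta": delta,
    }


def _params(beta0=(14.0, 9.0), alpha=(), lam=0.01, gamma=(0.0, 0.0)):
    beta = [np.r_[beta0[0], np.zeros(3 + 8)], np.r_[beta0[1], np.zeros(3 + 8)]]
    return {
        "basis": BASIS, "beta": beta, "b": [np.zeros(4), np.zeros(4)],
        "sigma2": [0.36, 0.25], "gamma": np.array(gamma),
        "alpha": np.array(alpha), "log_lambda": np.log([lam]),
        "cutpoints": np.array([120.0]), "quad_points": 15,
    }


class TestSubjectLoglik:
    def test_exponential_survival_closed_form(self):
        spec = JointModelSpec(association=AssociationSpec("none"),
                              surv_covariates=["age_group", "dm"])
        sd = _one_subject_data()
        params = _params()
        _, surv = subject_loglik(sd, params, spec)
        lam, T = 0.01, 24.0
        assert surv == pytest.approx(np.log(lam) - lam * T, abs=1e-10)

    def test_constant_value_association_closed_form(self):
        spec = JointModelSpec(
            association=AssociationSpec("current_value", centering=(12.0, 9.2)),
            surv_covariates=["age_group", "dm"])
        a = (0.9, 0.0)
        sd = _one_subject_data()
        params = _params(alpha=a)
        _, surv = subject_loglik(sd, params, spec)
        lam, T = 0.01, 24.0
        rate = lam * np.exp(a[0] * (14.0 - 12.0) + a[1] * (9.0 - 9.2))
        assert surv == pytest.approx(np.log(rate) - rate * T, abs=1e-8)

    def test_longitudinal_part_is_gaussian_density(self):
        spec = JointModelSpec(association=AssociationSpec("none"),
                              surv_covariates=["age_group", "dm"])
        sd = _one_subject_data()
        params = _params()
        long_part, _ = subject_loglik(sd, params, spec)
        expect = (stats.norm.logpdf(sd["y_sbp"], 14.0, 0.6).sum()
                  + stats.norm.logpdf(sd["y_dbp"], 9.0, 0.5).sum())
        assert long_part == pytest.approx(expect, abs=1e-10)


class TestQuadrature:
    def test_doubling_points_changes_nothing(self):
        cfg = GeneratorConfig()
        basis = cfg.basis()
        rng = np.random.default_rng(3)
        for _ in range(5):
            b = rng.multivariate_normal(np.zeros(8), cfg.resolved_D())
            w = np.zeros(8)
            hz15 = SubjectHazard(basis, [np.array(cfg.beta_sbp), np.array(cfg.beta_dbp)],
                                 [b[:4], b[4:]], w, 0.3, cfg.resolved_alpha(),
                                 cfg.association_spec(), cfg.resolved_cutpoints(),
                                 np.log(np.array(cfg.baseline_heights)), 15)
            hz30 = SubjectHazard(basis, [np.array(cfg.beta_sbp), np.array(cfg.beta_dbp)],
                                 [b[:4], b[4:]], w, 0.3, cfg.resolved_alpha(),
                                 cfg.association_spec(), cfg.resolved_cutpoints(),
                                 np.log(np.array(cfg.baseline_heights)), 30)
            for T in (10.0, 55.5, 119.0):
                assert abs(hz15.cumulative(T) - hz30.cumulative(T)) < 1e-6


@pytest.fixture(scope="module")
def tiny_fit_inputs():
    cohort, _ = simulate_cohort(scaled_generator(77, n_subjects=40))
    spec = scaled_model_spec()
    return cohort, spec


class TestSampler:
    def test_zero_iterations_gives_empty_draws(self, tiny_fit_inputs):
        cohort, spec = tiny_fit_inputs
        settings = MCMCSettings(chains=2, total_iterations=0, burn_in=0,
                                thin=1, seed=1, quadrature_points=5)
        draws = run_mcmc(cohort, spec, settings)
        assert draws.n_retained_per_chain == 0
        assert draws.pointwise_loglik.shape[1] == 0

    def test_same_seed_is_bitwise_reproducible(self, tiny_fit_inputs):
        cohort, spec = tiny_fit_inputs
        settings = MCMCSettings(chains=2, total_iterations=60, burn_in=20,
                                thin=2, seed=5, quadrature_points=5)
        a = run_mcmc(cohort, spec, settings)
        b = run_mcmc(cohort, spec, settings)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])
        np.testing.assert_array_equal(a.pointwise_loglik, b.pointwise_loglik)

    def test_retained_draw_count_contract(self, tiny_fit_inputs):
        cohort, spec = tiny_fit_inputs
        settings = MCMCSettings(chains=1, total_iterations=50, burn_in=13,
                                thin=7, seed=2, quadrature_points=5)
        draws = run_mcmc(cohort, spec, settings)
        assert draws.n_retained_per_chain == (50 - 13) // 7

    def test_sigma2_gibbs_matches_conjugate_posterior(self, tiny_fit_inputs):
        # isolate the conjugate residual-variance update: with eta fixed,
        # draws must average to the closed-form inverse-gamma mean
        from bpjoint.joint import _Chain, _FitData, _default_init

        cohort, spec = tiny_fit_inputs
        data = _FitData(cohort, spec, 5)
        init = _default_init(data, spec, cohort)
        settings = MCMCSettings(chains=1, total_iterations=10, burn_in=5,
                                thin=1, seed=3, quadrature_points=5)
        ch = _Chain(data, spec, settings, init, np.random.default_rng(12))
        r = data.y[0] - ch.eta[0]
        shape = 1.0 + 0.5 * len(r)
        scale = 0.005 + 0.5 * float(r @ r)
        expect = scale / (shape - 1)
        draws = []
        for _ in range(4000):
            ch.update_sigma2()
            draws.append(ch.sigma2[0])
            ch.sigma2 = [init["sigma2"][0], init["sigma2"][1]]
        mc_se = expect / np.sqrt(shape - 2) / np.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(expect, abs=4 * mc_se)

    def test_gamma_posterior_matches_survival_only_sampler(self):
        # alpha fixed at zero: the joint sampler's gamma posterior must agree
        # with an independent piecewise-exponential Bayesian fit
        overlaps = 0
        seeds = 3
        for s in range(seeds):
            cohort, _ = simulate_cohort(scaled_generator(
                500 + s, n_subjects=120, association_structure="none",
                alpha=(), baseline_heights=(1.2e-3,)))
            spec = scaled_model_spec("none")
            settings = MCMCSettings(chains=2, total_iterations=1500,
                                    burn_in=500, thin=2, seed=s,
                                    quadrature_points=5)
            draws = run_mcmc(cohort, spec, settings)
            joint_g = draws.flat()["gamma[age_group[ge65]]"].reshape(-1)
            ref = _survival_only_gamma_sampler(cohort, seed=s)
            lo1, hi1 = np.percentile(joint_g, [2.5, 97.5])
            lo2, hi2 = np.percentile(ref, [2.5, 97.5])
            if max(lo1, lo2) < min(hi1, hi2):
                overlaps += 1
        assert overlaps == seeds

    def test_prior_vagueness_contract(self):
        # x10 prior variance: posterior means of alpha move < 10% relative
        from bpjoint.joint import PriorSpec
        from dataclasses import replace

        cohort, _ = simulate_cohort(scaled_generator(901, n_subjects=100))
        settings = MCMCSettings(chains=2, total_iterations=3500, burn_in=1000,
                                thin=2, seed=7, quadrature_points=5)
        spec1 = scaled_model_spec()
        spec2 = replace(spec1, priors=PriorSpec(fixed_effect_spread=0.0001))
        m = {}
        for name, spec in (("base", spec1), ("wide", spec2)):
            summ = summarize_fit(run_mcmc(cohort, spec, settings))
            rows = [r for r in summ.index if r.startswith("alpha_") and "value" in r]
            m[name] = summ.loc[rows, "mean"].to_numpy()
        rel = np.abs(m["wide"] - m["base"]) / np.maximum(np.abs(m["base"]), 0.2)
        assert np.all(rel < 0.10)


def _survival_only_gamma_sampler(cohort, seed, n_iter=4000):
    """Small MH sampler for the piecewise-exponential PH model (oracle)."""
    from bpjoint.lmm import covariate_matrix
    from conftest import SURV_COVS_SCALED

    out = cohort.outcomes.sort_values("subject_id")
    T = out["followup_m"].to_numpy(float)
    delta = out["event"].to_numpy(float)
    W, _ = covariate_matrix(cohort.baseline, SURV_COVS_SCALED)
    W = W.loc[out["subject_id"]].to_numpy(float)
    cuts = np.quantile(T[delta == 1], [1/6, 2/6, 3/6, 4/6, 5/6])
    edges = np.concatenate([[0.0], cuts, [T.max()]])
    # exposure of subject i in interval j
    A = np.clip(np.minimum(T[:, None], edges[1:]) - edges[:-1], 0, None)
    ev_int = np.minimum(np.searchsorted(edges[1:], T), len(edges) - 2)
    rng = np.random.default_rng(seed)
    g = np.zeros(W.shape[1])
    step = 0.3
    keep = []
    for it in range(n_iter):
        # conjugate lambda | gamma
        risk = np.exp(W @ g)
        lam = rng.gamma(0.01 + np.bincount(ev_int, delta, len(edges) - 1),
                        1.0 / (0.01 + A.T @ risk))
        # MH gamma | lambda
        def lp(gv):
            r = np.exp(W @ gv)
            return float(delta @ (np.log(lam)[ev_int] + W @ gv)
                         - (A @ lam) @ r - 0.5 * 0.001 * gv @ gv)
        prop = g + step * rng.standard_normal(len(g))
        if np.log(rng.uniform()) < lp(prop) - lp(g):
            g = prop
        if it >= n_iter // 4:
            keep.append(g[0])
    return np.array(keep)


class TestSummaries:
    def _draws(self, arr, label="gamma[x]"):
        name = "gamma"
        return PosteriorDraws(
            params={name: arr[:, :, None]}, param_labels={name: [label]},
            pointwise_loglik=np.zeros((arr.shape[0], arr.shape[1], 1)),
            pointwise_loglik_at_mean=np.zeros(1), acceptance={}, meta={})

    def test_degenerate_constant_chain(self):
        arr = np.full((2, 50), 3.14)
        s = summarize_fit(self._draws(arr))
        assert s.loc["gamma[x]", "mean"] == pytest.approx(3.14)
        assert s.loc["gamma[x]", "cri_low"] == s.loc["gamma[x]", "cri_high"]

    def test_normal_sample_quantiles(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((2, 5000))
        s = summarize_fit(self._draws(arr))
        assert s.loc["gamma[x]", "cri_low"] == pytest.approx(-1.96, abs=0.08)
        assert s.loc["gamma[x]", "cri_high"] == pytest.approx(1.96, abs=0.08)

    def test_hazard_ratio_transform_is_exact(self):
        arr = np.full((2, 50), np.log(4.64))
        s = summarize_fit(self._draws(arr))
        assert s.loc["gamma[x]", "ahr"] == pytest.approx(4.64, abs=1e-12)

    def test_single_draw_fatal(self):
        arr = np.full((1, 1), 1.0)
        with pytest.raises(ValueError):
            summarize_fit(self._draws(arr))
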