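"""Descriptive survival layer: incidence, KM, log-rank, Cox and PH diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from bpjoint.survival import (
    cox_fit,
    km_at,
    km_estimate,
    logrank_test,
    person_years_and_incidence,
    ph_diagnostics,
    bivariable_screen,
)


def _outcomes(times, events):
    return pd.DataFrame({"subject_id": [f"S{i}" for i in range(len(times))],
                         "followup_m": times, "event": events})


class TestIncidence:
    def test_published_arithmetic(self):
        # 58 events over 2322.83 person-years among 408 subjects
        times = np.full(408, 2322.83 * 12 / 408)
        events = np.r_[np.ones(58), np.zeros(350)]
        r = person_years_and_incidence(_outcomes(times, events))
        assert r.person_years == pytest.approx(2322.83, abs=1e-9)
        assert round(r.rate_per_100py, 1) == 2.5
        assert round(r.proportion_pct, 2) == 14.22

    def test_zero_events(self):
        r = person_years_and_incidence(_outcomes([12.0, 24.0], [0, 0]))
        assert r.rate_per_100py == 0.0
        assert r.ci95[0] == 0.0 < r.ci95[1]

    def test_exact_poisson_interval_formula(self):
        # 10 subjects x 12 months = 10 PY, 1 event -> 10 per 100 PY
        r = person_years_and_incidence(
            _outcomes([12.0] * 10, [1] + [0] * 9))
        assert r.rate_per_100py == pytest.approx(10.0)
        low = 100 * stats.chi2.ppf(0.025, 2) / 2 / 10
        high = 100 * stats.chi2.ppf(0.975, 4) / 2 / 10
        assert r.ci95 == pytest.approx((low, high))
        assert r.ci95[0] < r.rate_per_100py < r.ci95[1]

    def test_empty_table_fatal(self):
        with pytest.raises(ValueError):
            person_years_and_incidence(_outcomes([], []))


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate(_outcomes([2.0, 4.0, 6.0], [1, 0, 1]))
        assert km_at(curve, 1.9) == 1.0
        assert km_at(curve, 2.0) == pytest.approx(2 / 3)
        assert km_at(curve, 6.0) == pytest.approx(0.0)
        assert np.all(np.diff(curve.survival) <= 0)

    def test_all_censored_is_unity(self):
        curve = km_estimate(_outcomes([5.0, 9.0, 12.0], [0, 0, 0]))
        assert km_at(curve, 100.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 60)
        curve = km_estimate(_outcomes(t, np.ones(60, dtype=int)))
        for q in [2.0, 5.0, 15.0]:
            assert km_at(curve, q) == pytest.approx(np.mean(t > q), abs=1e-12)

    def test_exponential_milestone(self):
        rng = np.random.default_rng(11)
        n = 10000
        t = rng.exponential(1 / 0.02, n)
        curve = km_estimate(_outcomes(t, np.ones(n, dtype=int)))
        p = np.exp(-0.48)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(km_at(curve, 24.0) - p) < 3 * se

    def test_negative_times_fatal(self):
        with pytest.raises(ValueError):
            km_estimate(_outcomes([-1.0, 3.0], [1, 0]))


class TestLogrank:
    def test_identical_groups_give_zero(self):
        out = _outcomes([2, 4, 6, 2, 4, 6], [1, 0, 1, 1, 0, 1])
        chi2, df, p = logrank_test(out, ["a"] * 3 + ["b"] * 3)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        out = _outcomes(rng.exponential(10, 40), rng.integers(0, 2, 40))
        g = np.array(["a"] * 20 + ["b"] * 20)
        chi2a, _, _ = logrank_test(out, g)
        swapped = np.where(g == "a", "b", "a")
        chi2b, _, _ = logrank_test(out, swapped)
        assert chi2a == pytest.approx(chi2b, rel=1e-12)

    def test_matches_hand_risk_set_tabulation(self):
        # 6 subjects, two groups, no ties across groups
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 1, 0, 1])
        groups = np.array(["a", "b", "a", "b", "a", "b"])
        chi2, _, _ = logrank_test(_outcomes(times, events), groups)
        # observed-minus-expected over risk sets for group a
        O_E, V = 0.0, 0.0
        for t in times[events == 1]:
            at_risk = times >= t
            n, n_a = at_risk.sum(), (at_risk & (groups == "a")).sum()
            d = ((times == t) & (events == 1)).sum()
            d_a = ((times == t) & (events == 1) & (groups == "a")).sum()
            O_E += d_a - d * n_a / n
            if n > 1:
                V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        assert chi2 == pytest.approx(O_E**2 / V, rel=1e-9)

    def test_single_group_fatal(self):
        with pytest.raises(ValueError):
            logrank_test(_outcomes([1, 2], [1, 1]), ["a", "a"])


def _efron_neg_loglik(beta, T, E, X):
    """Hand-written Efron partial likelihood (independent oracle)."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    ll = 0.0
    for t in np.unique(T[E == 1]):
        tied = (T == t) & (E == 1)
        d = tied.sum()
        risk = T >= t
        r_all = np.exp(eta[risk]).sum()
        r_tied = np.exp(eta[tied]).sum()
        ll += eta[tied].sum()
        for j in range(d):
            ll -= np.log(r_all - j / d * r_tied)
    return -ll


class TestCox:
    def test_symmetric_groups_give_zero_coef(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        x = pd.DataFrame({"g": [0, 0, 0, 0, 1, 1, 1, 1]}, dtype=float)
        f = cox_fit(_outcomes(np.array(times, float), events), x)
        assert abs(f.coef["g"]) < 1e-6

    def test_eight_subject_oracle(self):
        T = np.array([3.0, 5.0, 5.0, 7.0, 9.0, 11.0, 13.0, 16.0])
        E = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        X = np.array([[1.0], [0.0], [1.0], [1.0], [0.0], [1.0], [0.0], [0.0]])
        f = cox_fit(_outcomes(T, E), pd.DataFrame(X, columns=["x"]))
        res = minimize(_efron_neg_loglik, [0.0], args=(T, E, X),
                       method="BFGS", options={"gtol": 1e-12})
        assert f.coef["x"] == pytest.approx(res.x[0], abs=1e-6)
        assert f.loglik == pytest.approx(-res.fun, abs=1e-6)
        assert np.allclose(f.hr, np.exp(f.coef))

    def test_score_vanishes_at_optimum(self):
        T = np.array([3.0, 5.0, 5.0, 7.0, 9.0, 11.0, 13.0, 16.0])
        E = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        X = np.array([[1.0], [0.0], [1.0], [1.0], [0.0], [1.0], [0.0], [0.0]])
        f = cox_fit(_outcomes(T, E), pd.DataFrame(X, columns=["x"]))
        h = 1e-6
        grad = (_efron_neg_loglik(f.coef.to_numpy() + h, T, E, X)
                - _efron_neg_loglik(f.coef.to_numpy() - h, T, E, X)) / (2 * h)
        assert abs(grad) < 1e-5

    def test_recovers_true_log_hazard_ratio(self):
        # binary covariate, true log-HR = log(4.64), exponential PH data
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        truth = np.log(4.64)
        T = rng.exponential(1 / (0.01 * np.exp(truth * x)))
        C = rng.exponential(80, n)
        out = _outcomes(np.minimum(T, C), (T <= C).astype(int))
        f = cox_fit(out, pd.DataFrame({"x": x}))
        assert abs(f.coef["x"] - truth) < 3 * f.se["x"]

    def test_breslow_matches_efron_without_ties(self):
        rng = np.random.default_rng(9)
        n = 80
        x = rng.normal(size=n)
        T = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        out = _outcomes(T, np.ones(n, dtype=int))
        fe = cox_fit(out, pd.DataFrame({"x": x}), ties="efron")
        fb = cox_fit(out, pd.DataFrame({"x": x}), ties="breslow")
        assert fb.coef["x"] == pytest.approx(fe.coef["x"], abs=1e-4)
        assert fb.martingale.sum() == pytest.approx(0.0, abs=1e-6)

    def test_constant_covariate_fatal(self):
        out = _outcomes([1.0, 2.0, 3.0], [1, 1, 0])
        with pytest.raises(ValueError, match="constant"):
            cox_fit(out, pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    def test_no_events_fatal(self):
        out = _outcomes([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="events"):
            cox_fit(out, pd.DataFrame({"x": [0.0, 1.0]}))


class TestPHDiagnostics:
    def test_martingale_residuals_sum_to_zero(self):
        rng = np.random.default_rng(15)
        n = 200
        x = rng.normal(size=n)
        T = rng.exponential(1 / (0.05 * np.exp(0.4 * x)))
        C = rng.exponential(30, n)
        out = _outcomes(np.minimum(T, C), (T <= C).astype(int))
        f = cox_fit(out, pd.DataFrame({"x": x}))
        d = ph_diagnostics(f)
        assert abs(d["martingale_sum"]) < 1e-6
        assert set(d["per_covariate"]) == {"x"}
        assert 0 <= d["global"]["p"] <= 1

    def test_detects_time_varying_effect(self):
        # effect flips sign at the median time: strong PH violation
        rejections = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            n = 1000
            x = rng.integers(0, 2, n).astype(float)
            lam_early = 0.08 * np.exp(1.2 * x)
            t1 = rng.exponential(1 / lam_early)
            med = 8.0
            lam_late = 0.08 * np.exp(-1.2 * x)
            t2 = med + rng.exponential(1 / lam_late)
            T = np.where(t1 < med, t1, t2)
            out = _outcomes(T, np.ones(n, dtype=int))
            f = cox_fit(out, pd.DataFrame({"x": x}))
            if ph_diagnostics(f)["global"]["p"] < 0.05:
                rejections += 1
        assert rejections >= int(0.8 * reps) - 4  # power claim ~80%


def test_bivariable_screen_flags_threshold():
    rng = np.random.default_rng(21)
    n = 300
    strong = rng.integers(0, 2, n).astype(float)
    noise = rng.normal(size=n)
    T = rng.exponential(1 / (0.02 * np.exp(1.0 * strong)))
    C = rng.exponential(60, n)
    out = _outcomes(np.minimum(T, C), (T <= C).astype(int))
    tab = bivariable_screen(out, pd.DataFrame({"strong": strong, "noise": noise}))
    assert bool(tab.loc[tab.covariate == "strong", "selected"].iloc[0])
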