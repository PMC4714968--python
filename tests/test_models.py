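"""Regression engines against analytic values and independent maximizers.

Each engine is checked against an independently written negative
log-likelihood maximized by a generic scipy optimizer (the Weibull engine,
itself scipy-based, is instead checked against lifelines), plus the model
collapse identities and parameter-recovery simulations at the effect scales
of the study's headline loci.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from ibdpheno import (fit_binary_logistic, fit_linear,
                      fit_multinomial_logistic, fit_ordinal_logistic,
                      fit_weibull_aft, inverse_normal_transform, meta_fixed)


# ---------------------------------------------------------------------------
# independent likelihood oracles (generic numeric maximization)

def _logistic_nll(params, y, Z):
    eta = Z @ params
    return float(np.sum(np.logaddexp(0, eta) - y * eta))


def _ordinal_nll(params, codes, g, k):
    # params: [beta, theta_1, log-increments...]
    beta = params[0]
    th = np.concatenate([[params[1]], params[1] + np.cumsum(np.exp(params[2:]))])
    eta = beta * g

    def F(x):
        return 1.0 / (1.0 + np.exp(-x))

    ll = 0.0
    for i, c in enumerate(codes):
        lo = F(th[c - 1] - eta[i]) if c > 0 else 0.0
        hi = F(th[c] - eta[i]) if c < k - 1 else 1.0
        ll += np.log(max(hi - lo, 1e-300))
    return -ll


def _mnlogit_nll(params, codes, Z, k):
    # params laid out per non-reference category: (k-1) x n_cols
    P = params.reshape(k - 1, Z.shape[1])
    eta = np.column_stack([np.zeros(Z.shape[0]), Z @ P.T])
    eta -= eta.max(axis=1, keepdims=True)
    logp = eta - np.log(np.exp(eta).sum(axis=1))[:, None]
    return -float(logp[np.arange(len(codes)), codes].sum())


def _maximize(nll, x0, args):
    res = optimize.minimize(nll, x0, args=args, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000, "maxfev": 20000})
    return optimize.minimize(nll, res.x, args=args, method="Nelder-Mead",
                             options={"xatol": 1e-12, "fatol": 1e-14,
                                      "maxiter": 20000, "maxfev": 20000})


# ---------------------------------------------------------------------------
# inverse-normal transform

class TestInverseNormal:
    def test_three_point_example(self):
        out = inverse_normal_transform([3, 1, 2])
        exp = stats.norm.ppf([(3 - 0.5) / 3, (1 - 0.5) / 3, (2 - 0.5) / 3])
        np.testing.assert_allclose(out, exp, atol=1e-12)
        np.testing.assert_allclose(out, [0.96742157, -0.96742157, 0.0],
                                   atol=1e-6)

    def test_rank_invariance_under_monotone_rescale(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(2, size=50)
        np.testing.assert_allclose(inverse_normal_transform(y),
                                   inverse_normal_transform(np.exp(3 * y)),
                                   atol=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([1.0, 1.0, 1.0])

    def test_lognormal_becomes_symmetric(self):
        rng = np.random.default_rng(1)
        y = rng.lognormal(size=1000)
        z = inverse_normal_transform(y)
        assert abs(stats.skew(z)) < 0.05
        assert abs(z.mean()) < 0.01 and abs(z.std() - 1) < 0.05


# ---------------------------------------------------------------------------
# linear

class TestLinear:
    def test_exact_fit(self):
        g = np.array([0.0, 1, 2, 0, 1, 2])
        res = fit_linear(2 * g, g)
        assert res.primary.beta == pytest.approx(2.0, abs=1e-10)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        n = 150
        y = rng.standard_normal(n)
        ps = []
        for _ in range(400):
            g = rng.binomial(2, 0.3, n).astype(float)
            ps.append(fit_linear(y, g).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_recovery_at_nod2_age_scale(self):
        # beta = -0.16 SD/allele at MAF 0.024 (the large-frameshift age effect)
        rng = np.random.default_rng(3)
        n = 15000
        g = rng.binomial(2, 0.024, n).astype(float)
        y = -0.16 * g + rng.standard_normal(n)
        res = fit_linear(y, g)
        assert abs(res.primary.beta - (-0.16)) < 3 * res.primary.se

    def test_collinear_design_errors(self):
        g = np.array([0.0, 1, 2, 0, 1, 2])
        X = pd.DataFrame({"dup": g})
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(np.arange(6.0), g, X)


# ---------------------------------------------------------------------------
# binary logistic

class TestBinaryLogistic:
    def test_balanced_table_beta_zero(self):
        y = np.array([0.0, 0, 1, 1] * 10)
        g = np.array([0.0, 1, 0, 1] * 10)
        res = fit_binary_logistic(y, g)
        assert res.primary.beta == pytest.approx(0.0, abs=1e-8)

    def test_matches_generic_optimizer(self):
        rng = np.random.default_rng(4)
        n = 40
        g = rng.binomial(2, 0.4, n).astype(float)
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * g - 0.3 * x)))).astype(float)
        res = fit_binary_logistic(y, g, pd.DataFrame({"x": x}))
        Z = np.column_stack([np.ones(n), g, x])
        best = _maximize(_logistic_nll, np.zeros(3), (y, Z))
        assert abs(res.primary.beta - best.x[1]) < 1e-4
        assert abs(res.intercepts["const"] - best.x[0]) < 1e-4

    def test_recovery_at_extent_scale(self):
        # OR 0.70 at MAF 0.116, n=10000 (extensive-colitis effect scale)
        rng = np.random.default_rng(5)
        n = 10000
        g = rng.binomial(2, 0.116, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.1 + np.log(0.70) * g)))
             ).astype(float)
        res = fit_binary_logistic(y, g)
        assert abs(res.primary.beta - np.log(0.70)) < 3 * res.primary.se

    def test_perfect_separation_flagged(self):
        y = np.array([0.0, 0, 0, 1, 1, 1])
        g = np.array([0.0, 0, 0, 2, 2, 2])
        res = fit_binary_logistic(y, g)
        assert not res.converged and res.note


# ---------------------------------------------------------------------------
# ordinal (proportional odds)

class TestOrdinalLogistic:
    def test_collapses_to_binary_on_two_categories(self):
        rng = np.random.default_rng(6)
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y01 = (rng.random(n) < 1 / (1 + np.exp(-(0.4 * g - 0.1)))).astype(float)
        yc = np.where(y01 > 0, "B2", "B1")
        res_o = fit_ordinal_logistic(yc, g, order=("B1", "B2"))
        res_b = fit_binary_logistic(y01, g)
        assert abs(res_o.primary.beta - res_b.primary.beta) < 1e-6

    def test_matches_generic_optimizer(self):
        # non-separable toy: mixed categories at every genotype
        y = np.array(["B1", "B2", "B1", "B3", "B2", "B3", "B1", "B3"], object)
        g = np.array([0.0, 0, 1, 1, 2, 2, 2, 0])
        res = fit_ordinal_logistic(y, g)
        codes = np.array([0, 1, 0, 2, 1, 2, 0, 2])
        best = _maximize(_ordinal_nll, np.array([0.0, -0.5, 0.0]),
                         (codes, g, 3))
        assert abs(res.primary.beta - best.x[0]) < 1e-4
        th_oracle = [best.x[1], best.x[1] + np.exp(best.x[2])]
        assert abs(res.intercepts["theta_1"] - th_oracle[0]) < 1e-4
        assert abs(res.intercepts["theta_2"] - th_oracle[1]) < 1e-4

    def test_recovery_at_behaviour_scale(self):
        # proportional OR 1.31 at MAF 0.024, n=15000
        rng = np.random.default_rng(7)
        n = 15000
        g = rng.binomial(2, 0.024, n).astype(float)
        lat = np.log(1.31) * g + rng.logistic(size=n)
        y = np.array(["B1", "B2", "B3"], object)[np.digitize(lat, [0.6, 1.8])]
        res = fit_ordinal_logistic(y, g)
        assert abs(res.primary.beta - np.log(1.31)) < 3 * res.primary.se

    def test_cutpoints_increasing(self):
        rng = np.random.default_rng(8)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        y = np.array(["B1", "B2", "B3"], object)[rng.choice(3, n, p=[.5, .3, .2])]
        res = fit_ordinal_logistic(y, g)
        assert res.intercepts["theta_1"] < res.intercepts["theta_2"]


# ---------------------------------------------------------------------------
# multinomial

class TestMultinomialLogistic:
    def test_collapses_to_binary_on_two_categories(self):
        rng = np.random.default_rng(9)
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y01 = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * g)))).astype(float)
        yc = np.where(y01 > 0, "L1", "L2")
        res_m = fit_multinomial_logistic(yc, g, reference="L2")
        res_b = fit_binary_logistic(y01, g)
        assert abs(res_m.effects["L1_vs_L2"].beta - res_b.primary.beta) < 1e-6

    def test_matches_generic_optimizer(self):
        rng = np.random.default_rng(10)
        n = 60
        g = rng.binomial(2, 0.4, n).astype(float)
        probs = np.column_stack([np.ones(n), np.exp(0.4 * g - 0.2),
                                 np.exp(-0.3 * g + 0.1)])
        probs /= probs.sum(axis=1, keepdims=True)
        cats = np.array(["L2", "L1", "L3"], object)
        y = np.array([cats[rng.choice(3, p=p)] for p in probs], object)
        res = fit_multinomial_logistic(y, g, reference="L2")
        codes = pd.Categorical(y, categories=["L2", "L1", "L3"]).codes
        Z = np.column_stack([np.ones(n), g])
        best = _maximize(_mnlogit_nll, np.zeros(4), (codes, Z, 3))
        P = best.x.reshape(2, 2)
        assert abs(res.effects["L1_vs_L2"].beta - P[0, 1]) < 1e-4
        assert abs(res.effects["L3_vs_L2"].beta - P[1, 1]) < 1e-4
        assert res.loglik == pytest.approx(-best.fun, abs=1e-6)

    def test_recovery_at_location_scale(self):
        # ileal-vs-colonic OR 2.50 at MAF 0.024, n=12000
        rng = np.random.default_rng(11)
        n = 12000
        g = rng.binomial(2, 0.024, n).astype(float)
        probs = np.column_stack([np.ones(n), np.exp(np.log(2.5) * g - 0.2),
                                 np.exp(0.4 + 0.5 * np.log(2.5) * g)])
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        codes = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
        y = np.array(["L2", "L1", "L3"], object)[codes]
        res = fit_multinomial_logistic(y, g, reference="L2")
        eff = res.effects["L1_vs_L2"]
        assert abs(eff.beta - np.log(2.5)) < 3 * eff.se

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            fit_multinomial_logistic(np.array(["L1", "L3"] * 10, object),
                                     np.zeros(20), reference="L2")


# ---------------------------------------------------------------------------
# Weibull AFT

class TestWeibullAFT:
    def test_exponential_closed_form(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4)
        res = fit_weibull_aft(t, e, fix_shape=1.0)
        # rate MLE = n_events / total time  ->  mu = -log(rate)
        assert res.intercepts["mu"] == pytest.approx(np.log(t.sum() / 4),
                                                     abs=1e-6)

    def test_matches_lifelines(self):
        from lifelines import WeibullAFTFitter

        rng = np.random.default_rng(12)
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        t_true = 8 * np.exp(0.4 * g) * rng.weibull(1.4, n)
        cens = rng.uniform(3, 20, n)
        t = np.minimum(t_true, cens)
        e = (t_true <= cens).astype(float)
        res = fit_weibull_aft(t, e, g)
        laf = WeibullAFTFitter().fit(
            pd.DataFrame({"T": t, "E": e, "g": g}), "T", "E")
        assert abs(res.effects["aft_per_allele"].beta
                   - laf.params_[("lambda_", "g")]) < 1e-4
        assert abs(res.shape - np.exp(laf.params_[("rho_", "Intercept")])) < 1e-4
        assert abs(res.effects["aft_per_allele"].se
                   - laf.standard_errors_[("lambda_", "g")]) < 1e-3

    def test_log_hr_recovery(self):
        # HR 1.31 per allele, ~40% censoring, n=10000
        rng = np.random.default_rng(13)
        n = 10000
        k = 1.3
        g = rng.binomial(2, 0.2, n).astype(float)
        lam = 12 * np.exp(-np.log(1.31) * g / k)
        t_true = lam * rng.weibull(k, n)
        cens = rng.exponential(12, n)
        t = np.minimum(t_true, cens)
        e = (t_true <= cens).astype(float)
        assert 0.3 < 1 - e.mean() < 0.55
        res = fit_weibull_aft(t, e, g)
        eff = res.effects["log_hr_per_allele"]
        assert abs(eff.beta - np.log(1.31)) < 3 * eff.se

    def test_all_censored_errors(self):
        with pytest.raises(ValueError, match="event"):
            fit_weibull_aft([1.0, 2.0], [0.0, 0.0])


# ---------------------------------------------------------------------------
# meta-analysis

class TestMetaFixed:
    def _mk(self, beta, se, vid="v"):
        from ibdpheno.models import AssocResult, ContrastEffect
        return AssocResult(variant_id=vid, model="linear",
                           effects={"b": ContrastEffect(beta, se)},
                           p=0.5, n_used=10, converged=True)

    def test_identical_pair(self):
        m = meta_fixed([self._mk(0.1, 0.1), self._mk(0.1, 0.1)])
        assert m.beta == pytest.approx(0.1)
        assert m.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-6)

    def test_symmetric_cancellation(self):
        m = meta_fixed([self._mk(0.2, 0.05), self._mk(-0.2, 0.05)])
        assert m.beta == pytest.approx(0.0, abs=1e-12)

    def test_cd_uc_pooling_formula(self):
        # the 3p21 age-at-diagnosis pooling arithmetic
        m = meta_fixed([self._mk(-0.07, 0.01), self._mk(-0.06, 0.01)])
        assert m.beta == pytest.approx(-0.065)
        assert m.se == pytest.approx(0.00707, abs=1e-4)
        inputs = [2 * stats.norm.sf(abs(b / s)) for b, s in m.inputs]
        assert m.p < min(inputs)

    def test_mismatched_ids_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            meta_fixed([self._mk(0.1, 0.1, "a"), self._mk(0.1, 0.1, "b")])

    def test_pooled_se_bounded_by_min_input(self):
        m = meta_fixed([self._mk(0.0, 0.02), self._mk(0.1, 0.3)])
        assert m.se <= 0.02


def test_wald_and_lrt_agree_for_moderate_effects():
    rng = np.random.default_rng(14)
    n = 5000
    g = rng.binomial(2, 0.3, n).astype(float)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.15 * g - 0.2)))).astype(float)
    wald = fit_binary_logistic(y, g, p_method="wald")
    lrt = fit_binary_logistic(y, g, p_method="lrt")
    ratio = wald.p / lrt.p
    assert 1 / 1.5 < ratio < 1.5
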