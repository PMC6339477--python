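"""The binomial random-intercept model: likelihood, inference, R², prediction."""

import shutil
import subprocess
import sys

import numpy as np
import pytest
from scipy.special import expit

from fptrack.glmm import (GlmmFit, ModelData, fit_binomial_glmm, marginal_loglik,
                          nakagawa_r2, predict_search_probability,
                          LOGIT_RESIDUAL_VAR)


def simulate_model_data(rng, n_groups=15, n_per=450,
                        beta=(-2.247, 0.065, -0.050, -0.002), sigma=1.0) -> ModelData:
    """Draw directly from the generating model on 0–20 rank covariates."""
    beta = np.asarray(beta)
    n = n_groups * n_per
    X = np.column_stack([np.ones(n)] + [rng.uniform(0, 20, n) for _ in range(len(beta) - 1)])
    g = np.repeat(np.arange(n_groups), n_per)
    a = rng.normal(0.0, sigma, n_groups)
    y = (rng.random(n) < expit(X @ beta + a[g])).astype(float)
    return ModelData(y, X, g, ["intercept", "sst_rank", "turbidity_rank", "chla_rank"])


class TestNoRandomEffectLimit:
    def test_matches_statsmodels_logit(self, rng):
        import statsmodels.api as sm

        data = simulate_model_data(rng, n_groups=8, n_per=150, sigma=0.0)
        fit = fit_binomial_glmm(data, constrain_sigma_zero=True)
        oracle = sm.Logit(data.y, data.X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-4)
        np.testing.assert_allclose(fit.se, oracle.bse, rtol=1e-3)

    def test_free_fit_shrinks_to_logistic_when_groups_identical(self, rng):
        data = simulate_model_data(rng, n_groups=10, n_per=200, sigma=0.0)
        constrained = fit_binomial_glmm(data, constrain_sigma_zero=True)
        free = fit_binomial_glmm(data)
        assert free.sigma2_alpha < 0.05
        np.testing.assert_allclose(free.beta, constrained.beta, atol=0.02)


class TestMarginalLikelihood:
    def test_laplace_close_to_full_quadrature(self, rng):
        data = simulate_model_data(rng, n_groups=10, n_per=200, sigma=0.8)
        f1 = fit_binomial_glmm(data, quadrature_nodes=1)
        f25 = fit_binomial_glmm(data, quadrature_nodes=25)
        assert abs(f1.loglik - f25.loglik) < 0.5
        np.testing.assert_allclose(f1.beta, f25.beta, atol=0.02)

    def test_optimum_beats_null_model(self, rng):
        data = simulate_model_data(rng, n_groups=8, n_per=120, sigma=0.8)
        fit = fit_binomial_glmm(data)
        null = ModelData(data.y, data.X[:, :1], data.group, ["intercept"])
        nfit = fit_binomial_glmm(null)
        assert fit.loglik >= nfit.loglik

    def test_score_vanishes_at_reported_optimum(self, rng):
        data = simulate_model_data(rng, n_groups=8, n_per=120, sigma=0.8)
        fit = fit_binomial_glmm(data)
        gidx, ng = data.group_index()
        theta = np.append(fit.beta, 0.5 * np.log(fit.sigma2_alpha))
        # standardised central-difference score per parameter
        grad = np.empty(len(theta))
        for i in range(len(theta)):
            h = 1e-5 * (1 + abs(theta[i]))
            tp = theta.copy(); tp[i] += h
            tm = theta.copy(); tm[i] -= h
            grad[i] = (marginal_loglik(tp[:-1], tp[-1], data.y, data.X, gidx, ng)
                       - marginal_loglik(tm[:-1], tm[-1], data.y, data.X, gidx, ng)) / (2 * h)
        assert np.max(np.abs(grad)) / len(data.y) < 1e-5

    def test_matches_lme4_reference(self, rng, tmp_path):
        """Independent cross-check against R lme4 glmer with nAGQ=25."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        data = simulate_model_data(rng, n_groups=6, n_per=120, sigma=0.8,
                                   beta=(-1.0, 0.08, -0.06, 0.0))
        csv = tmp_path / "d.csv"
        np.savetxt(csv, np.column_stack([data.y, data.X[:, 1:], data.group]),
                   delimiter=",", header="y,x1,x2,x3,g", comments="")
        script = tmp_path / "ref.R"
        script.write_text(
            f"d <- read.csv('{csv}')\n"
            "suppressMessages(library(lme4))\n"
            "m <- glmer(y ~ x1 + x2 + x3 + (1|g), data=d, family=binomial, nAGQ=25)\n"
            "cat(fixef(m), sqrt(diag(vcov(m))), VarCorr(m)$g[1], logLik(m), sep=',')\n"
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             timeout=300)
        assert res.returncode == 0, res.stderr
        ref = np.fromstring(res.stdout.strip(), sep=",")
        fit = fit_binomial_glmm(data)
        np.testing.assert_allclose(fit.beta, ref[:4], atol=1e-3)
        np.testing.assert_allclose(fit.se, ref[4:8], rtol=0.02)
        assert fit.sigma2_alpha == pytest.approx(ref[8], abs=1e-2)
        assert fit.loglik == pytest.approx(ref[9], abs=1e-3)

    def test_rank_deficient_design_raises(self, rng):
        data = simulate_model_data(rng, n_groups=4, n_per=50)
        X = np.column_stack([data.X, data.X[:, 1]])
        with pytest.raises(ValueError):
            fit_binomial_glmm(ModelData(data.y, X, data.group, data.colnames + ["dup"]))


class TestNakagawaR2:
    def _fit(self, beta, sigma2, X):
        return GlmmFit(np.asarray(beta), np.ones(len(beta)), np.ones(len(beta)),
                       np.ones(len(beta)), sigma2, 0.0, None, None, True,
                       ["intercept"] + [f"x{i}" for i in range(len(beta) - 1)])

    def test_closed_form_values(self, rng):
        # engineer fixed-effect variance exactly 1 with known sigma2 = 2
        x = rng.normal(size=400)
        x = (x - x.mean()) / x.std()
        X = np.column_stack([np.ones(400), x])
        data = ModelData(np.zeros(400), X, np.zeros(400, dtype=int), ["intercept", "x"])
        r2m, r2c = nakagawa_r2(self._fit([0.0, 1.0], 2.0, X), data)
        assert r2m == pytest.approx(1.0 / (3.0 + LOGIT_RESIDUAL_VAR), abs=1e-3)
        assert r2c == pytest.approx(3.0 / (3.0 + LOGIT_RESIDUAL_VAR), abs=1e-3)

    def test_zero_fixed_effects_zero_marginal(self, rng):
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        data = ModelData(np.zeros(100), X, np.zeros(100, dtype=int), ["intercept", "x"])
        r2m, _ = nakagawa_r2(self._fit([0.5, 0.0], 1.0, X), data)
        assert r2m == 0.0

    def test_zero_variance_collapses(self, rng):
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        data = ModelData(np.zeros(100), X, np.zeros(100, dtype=int), ["intercept", "x"])
        r2m, r2c = nakagawa_r2(self._fit([0.0, 0.7], 0.0, X), data)
        assert r2m == pytest.approx(r2c)


class TestPredict:
    def _fit(self, beta):
        k = len(beta)
        return GlmmFit(np.asarray(beta), np.ones(k), np.ones(k), np.ones(k), 0.5, 0.0,
                       None, None, True,
                       ["intercept", "sst_rank", "turbidity_rank", "chla_rank"][:k])

    def test_all_ranks_zero_is_intercept_probability(self):
        fit = self._fit([-2.247, 0.065, -0.050, -0.002])
        p = predict_search_probability(fit, {"sst": 0.0, "turbidity": 0.0, "chla": 0.0})
        assert p == pytest.approx(expit(-2.247), abs=1e-6)
        assert p == pytest.approx(0.0956, abs=5e-4)

    def test_monotone_in_positive_coefficient(self):
        fit = self._fit([-2.247, 0.065, -0.050, -0.002])
        ps = [predict_search_probability(fit, {"sst": s}) for s in np.linspace(0, 20, 9)]
        assert np.all(np.diff(ps) > 0)

    def test_null_model_is_half(self):
        assert predict_search_probability(self._fit([0.0, 0.0, 0.0, 0.0]), {}) == 0.5
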