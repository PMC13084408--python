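"""Gamma log-link mixed model: recovery, oracles, deletion tests."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
import statsmodels.api as sm

from burstlink.glmm import (DESIGN_COLUMNS, GammaMixedModel,
                            simulate_gamma_glmm)

from _oracles import gamma_glm_irls

BETA_TRUE = np.array([np.log(180.0), 0.03, -0.04, -0.06, 0.01, 0.0])


@pytest.fixture(scope="module")
def fitted():
    d = simulate_gamma_glmm(BETA_TRUE, 50, 40, re_sd=0.1, shape=12, seed=1)
    m = GammaMixedModel.from_dataframe(d)
    return m, m.fit()


class TestModelValidation:
    def test_nonpositive_response_rejected(self):
        d = simulate_gamma_glmm(BETA_TRUE, 5, 10, 0.1, 10, seed=0)
        d.loc[0, "reaction_time_ms"] = -1.0
        with pytest.raises(ValueError):
            GammaMixedModel.from_dataframe(d)

    def test_single_group_rejected(self):
        d = simulate_gamma_glmm(BETA_TRUE, 1, 40, 0.0, 10, seed=0)
        with pytest.raises(ValueError):
            GammaMixedModel.from_dataframe(d)

    def test_design_is_zscored(self, fitted):
        m, _ = fitted
        for j in (1, 2, 3):
            assert m.exog[:, j].mean() == pytest.approx(0.0, abs=1e-8)
            assert m.exog[:, j].std() == pytest.approx(1.0, abs=1e-8)


class TestFitting:
    def test_intercept_only_matches_log_mean(self):
        # closed form: Gamma MLE of the log-mean is log(ybar)
        rng = np.random.default_rng(7)
        y = rng.gamma(10, 20.0, size=500)
        m = GammaMixedModel(y, np.ones((500, 1)),
                            np.zeros(500, dtype=int), ["Intercept"])
        r = m.fit(include_random=False)
        assert r.params[0] == pytest.approx(np.log(y.mean()), abs=1e-3)

    def test_collapsed_limit_matches_irls_oracle(self):
        d = simulate_gamma_glmm(BETA_TRUE, 30, 30, re_sd=0.0, shape=10, seed=2)
        m = GammaMixedModel.from_dataframe(d)
        r = m.fit(include_random=False)
        beta_irls = gamma_glm_irls(m.endog, m.exog)
        np.testing.assert_allclose(r.params, beta_irls, atol=1e-4)
        # and against statsmodels' independent Gamma GLM implementation
        glm = sm.GLM(m.endog, m.exog,
                     family=sm.families.Gamma(sm.families.links.Log())).fit()
        np.testing.assert_allclose(r.params, glm.params, atol=1e-5)

    def test_zero_variance_boundary(self):
        d = simulate_gamma_glmm(BETA_TRUE, 30, 30, re_sd=0.0, shape=10, seed=2)
        m = GammaMixedModel.from_dataframe(d)
        with_re = m.fit(include_random=True)
        without = m.fit(include_random=False)
        assert with_re.re_sd < 0.05
        np.testing.assert_allclose(with_re.params, without.params, atol=1e-3)

    def test_recovery_within_wald_bands(self, fitted):
        _, r = fitted
        assert r.converged
        assert np.all(np.abs(r.params - BETA_TRUE) < 3 * r.bse)
        assert r.shape == pytest.approx(12.0, rel=0.15)
        assert r.re_sd == pytest.approx(0.1, abs=0.04)

    def test_aic_consistency(self, fitted):
        _, r = fitted
        assert r.aic == pytest.approx(2 * r.k_params - 2 * r.llf)
        assert r.k_params == 8  # 6 fixed + RE sd + shape

    def test_scale_invariance_of_zscored_fit(self):
        d = simulate_gamma_glmm(BETA_TRUE, 20, 25, re_sd=0.1, shape=10, seed=5)
        r1 = GammaMixedModel.from_dataframe(d).fit()
        d2 = d.copy()
        d2["latency_ms"] *= 37.0   # rescaling is absorbed by z-scoring
        d2["strength"] *= 0.01
        r2 = GammaMixedModel.from_dataframe(d2).fit()
        np.testing.assert_allclose(r1.params, r2.params, atol=1e-5)

    def test_summary_mentions_all_terms(self, fitted):
        _, r = fitted
        text = r.summary()
        for name in DESIGN_COLUMNS:
            assert name in text


class TestSingleTermDeletion:
    def test_df_accounting(self, fitted):
        _, r = fitted
        assert r.single_term_deletion("latency")["df"] == 2
        assert r.single_term_deletion("strength")["df"] == 2
        assert r.single_term_deletion("contrast")["df"] == 3

    def test_strong_term_detected(self, fitted):
        _, r = fitted
        out = r.single_term_deletion("contrast")
        assert out["p"] < 1e-4
        assert out["aic_reduced"] > r.aic

    def test_unknown_term_rejected(self, fitted):
        _, r = fitted
        with pytest.raises(ValueError):
            r.single_term_deletion("prestim")

    def test_noise_term_increases_aic_in_most_runs(self):
        # adding/removing a pure-noise predictor: the reduced (true) model
        # should usually win on AIC
        beta_null = BETA_TRUE.copy()
        beta_null[1] = beta_null[4] = 0.0  # latency truly absent
        wins = 0
        for seed in range(10):
            d = simulate_gamma_glmm(beta_null, 25, 20, 0.08, 10, seed=seed)
            r = GammaMixedModel.from_dataframe(d).fit()
            wins += r.single_term_deletion("latency")["aic_reduced"] < r.aic
        assert wins >= 6


class TestGlmerCrossCheck:
    def test_fixed_effects_match_lme4(self, tmp_path):
        """Independent cross-check of the Laplace fit against R's glmer."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the glmer cross-check")
        d = simulate_gamma_glmm([np.log(180), 0.05, -0.06, -0.08, 0.02, -0.01],
                                30, 25, re_sd=0.15, shape=10, seed=3)
        m = GammaMixedModel.from_dataframe(d)
        r = m.fit()
        csv = tmp_path / "d.csv"
        np.savetxt(csv, np.column_stack([m.endog, m.exog[:, 1], m.exog[:, 2],
                                         m.exog[:, 3], m.group_idx]),
                   delimiter=",", header="y,lat,str,con,g", comments="")
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ lat*con + str*con + (1|g), data=d,
                       family=Gamma(link="log"),
                       control=glmerControl(optimizer="bobyqa"))
            fe <- fixef(m)
            cat(fe["(Intercept)"], fe["lat"], fe["str"], fe["con"],
                fe["lat:con"], fe["con:str"], sep=",")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        r_beta = np.array([float(v) for v in out.stdout.strip().split(",")])
        np.testing.assert_allclose(r.params, r_beta, atol=0.015)
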