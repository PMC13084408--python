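"""Spearman records, population tests, reliability, fast/slow summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from burstlink import (SimConfig, compute_feature_table, correlate_features,
                       fastslow_normalized_summary, generate_session,
                       population_tests, reliability_summary,
                       spearman_feature_rt)
from burstlink.stats import _exact_rho_null, mannwhitney_z


class TestSpearman:
    def test_perfect_monotone(self):
        rec = spearman_feature_rt([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rec.rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        rec = spearman_feature_rt([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert rec.rho == pytest.approx(-1.0)

    def test_all_zero_prestim_convention(self):
        rec = spearman_feature_rt([0, 0, 0, 0], [100, 120, 110, 130],
                                  zero_convention=True)
        assert rec.rho == 0.0 and rec.zero_assigned

    def test_degenerate_inputs_dropped(self):
        assert spearman_feature_rt([1, 1, 1], [1, 2, 3]) is None
        assert spearman_feature_rt([1, 2], [1, 2]) is None

    def test_nan_features_dropped_pairwise(self):
        rec = spearman_feature_rt([1, np.nan, 3, 4, 5], [10, 0, 30, 40, 50])
        assert rec.n_trials == 4 and rec.rho == pytest.approx(1.0)

    def test_exact_p_matches_enumeration(self):
        # for n <= 9 the two-sided p is the exact permutation tail
        x = [3, 1, 4, 1.5, 5, 9]
        y = [2, 7, 1, 8, 2.5, 8.2]
        rec = spearman_feature_rt(x, y)
        null = _exact_rho_null(6)
        assert rec.p == pytest.approx(
            np.mean(np.abs(null) >= abs(rec.rho) - 1e-12))
        # perfect correlation at n=5: p = 2/5! * 2 tails = 2*1/120
        rec5 = spearman_feature_rt([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert rec5.p == pytest.approx(2 / 120)

    def test_exact_null_is_symmetric_unbiased(self):
        null = _exact_rho_null(7)
        assert len(null) == 5040
        assert null.mean() == pytest.approx(0.0, abs=1e-12)
        assert null.max() == 1.0 and null.min() == -1.0


class TestMannWhitney:
    def test_z_matches_normal_approximation(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.8, 1, 35)
        u, z, p = mannwhitney_z(a, b)
        # cross-check against scipy's asymptotic p (continuity-corrected,
        # so agreement is close but not exact)
        p_scipy = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic").pvalue
        assert p == pytest.approx(p_scipy, rel=0.15)
        assert (z > 0) == (u > len(a) * len(b) / 2)


class TestPopulationTests:
    def test_bonferroni_arithmetic(self):
        recs = pd.DataFrame({
            "feature": ["strength"] * 40,
            "contrast": np.repeat([10, 20, 50, 100], 10),
            "polarity": ["dark"] * 40,
            "rho": np.tile(np.linspace(0.25, 0.35, 10), 4),
        })
        out = population_tests(recs).groups
        assert np.allclose(out["p_bonferroni"],
                           np.minimum(1.0, out["p"] * 4))

    def test_null_records_rarely_significant(self):
        # symmetric-about-zero correlation samples: signed-rank should be
        # non-significant in >= 93/100 simulations at alpha = 0.05
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            recs = pd.DataFrame({
                "feature": "strength", "contrast": 50, "polarity": "dark",
                "rho": r.normal(0.0, 0.15, 30)})
            p = population_tests(recs).groups["p"].iloc[0]
            hits += p > 0.05
        assert hits >= 93

    def test_shifted_records_strongly_significant(self, rng):
        recs = pd.DataFrame({
            "feature": "strength", "contrast": 50, "polarity": "dark",
            "rho": 0.3 + rng.normal(0, 0.02, 40)})
        assert population_tests(recs).groups["p"].iloc[0] < 1e-3

    def test_zero_values_disregarded_with_reduced_n(self):
        recs = pd.DataFrame({
            "feature": "prestim", "contrast": 50, "polarity": "dark",
            "rho": [0.0] * 10 + [0.2, 0.3, 0.25, 0.1, 0.15]})
        g = population_tests(recs).groups.iloc[0]
        assert g["n"] == 15 and g["n_effective"] == 5

    def test_between_group_comparison(self, rng):
        recs = pd.DataFrame({
            "area": ["SC"] * 30 + ["V1"] * 30,
            "feature": "strength", "contrast": 50, "polarity": "dark",
            "rho": np.r_[rng.normal(-0.2, 0.1, 30), rng.normal(0.0, 0.1, 30)]})
        out = population_tests(recs, group_by=("area", "feature"),
                               between="area")
        assert out.between is not None
        assert out.between["p"].iloc[0] < 0.001


class TestReliability:
    def test_constant_feature_zero_sd(self):
        df = pd.DataFrame({"neuron_id": [0] * 5, "contrast": 50,
                           "polarity": "dark", "latency_ms": [60.0] * 5})
        out = reliability_summary(df, "latency_ms")
        assert out["mean_sd"].iloc[0] == 0.0

    def test_two_point_sd(self):
        df = pd.DataFrame({"neuron_id": [0, 0], "contrast": 50,
                           "polarity": "dark", "latency_ms": [50.0, 60.0]})
        out = reliability_summary(df, "latency_ms")
        assert out["mean_sd"].iloc[0] == pytest.approx(np.sqrt(50.0))

    def test_larger_jitter_recovered_as_larger_sd(self):
        sds = {}
        for name, sd in (("SC", 8.0), ("V1", 16.0)):
            cfg = SimConfig(n_neurons=6, n_trials_per_condition=40,
                            contrasts=(100,), polarities=("dark",), seed=41,
                            burst_latency_sd=sd, include_delayed_task=False)
            f = compute_feature_table(generate_session(cfg))
            sds[name] = reliability_summary(f, "latency_ms")["mean_sd"].iloc[0]
        assert sds["V1"] > sds["SC"]


class TestCorrelateFeatures:
    def test_signs_match_programmed_couplings(self):
        cfg = SimConfig(n_neurons=8, n_trials_per_condition=40,
                        contrasts=(50,), polarities=("dark",), seed=42,
                        include_delayed_task=False)
        f = compute_feature_table(generate_session(cfg))
        recs = correlate_features(f)
        by_feat = recs.groupby("feature")["rho"].mean()
        assert by_feat["latency"] > 0    # later burst -> later saccade
        assert by_feat["strength"] < 0   # stronger burst -> earlier saccade

    def test_type_one_error_calibrated_under_null(self):
        # zero coupling: the per-neuron strength-RT test should fire at
        # roughly its nominal 5% rate
        sig = []
        for seed in range(25):
            cfg = SimConfig.v1_like(n_neurons=8, n_trials_per_condition=40,
                                    contrasts=(50,), polarities=("dark",),
                                    seed=500 + seed)
            f = compute_feature_table(generate_session(cfg))
            recs = correlate_features(f, feature_names=("strength",))
            sig.extend((recs["p"] < 0.05).tolist())
        assert np.mean(sig) == pytest.approx(0.05, abs=0.035)


class TestFastSlow:
    def test_coupled_session_fast_third_peaks_higher(self):
        cfg = SimConfig(n_neurons=10, n_trials_per_condition=42,
                        contrasts=(50,), polarities=("dark",), seed=43,
                        include_delayed_task=False)
        out = fastslow_normalized_summary(generate_session(cfg))
        w = (out["times"] >= 40) & (out["times"] < 110)
        assert out["fast_mean"][w].max() > out["slow_mean"][w].max()

    def test_uncoupled_session_thirds_similar(self):
        cfg = SimConfig.v1_like(n_neurons=10, n_trials_per_condition=42,
                                contrasts=(50,), polarities=("dark",), seed=44)
        out = fastslow_normalized_summary(generate_session(cfg))
        w = (out["times"] >= 30) & (out["times"] < 120)
        diff = abs(out["fast_mean"][w].max() - out["slow_mean"][w].max())
        assert diff < 0.1  # normalised units

    def test_too_few_trials_rejected(self, sc_session):
        sub = sc_session
        small = type(sub)(trials=sub.trials.head(5),
                          spikes=sub.spikes, neurons=sub.neurons)
        with pytest.raises(ValueError):
            fastslow_normalized_summary(small)
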