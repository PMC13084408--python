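"""Burst-feature extraction: threshold, latency detector, strength, prestim."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstlink import (SimConfig, burst_strength, compute_feature_table,
                       detect_latency, detection_threshold, generate_session,
                       latency_inclusion, prestim_state)
from burstlink.features import EpochConfig
from burstlink.rates import RateTrace, estimate_rate

from _oracles import brute_force_latency


class TestDetectionThreshold:
    def test_zero_variance(self):
        assert detection_threshold([10.0, 10.0, 10.0]) == 10.0

    def test_two_sd_arithmetic(self):
        assert detection_threshold([8.0, 10.0, 12.0]) == pytest.approx(14.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            detection_threshold([5.0])

    def test_threshold_sits_two_sds_above_mean(self, rng):
        x = rng.poisson(10, size=40).astype(float)
        theta = detection_threshold(x)
        assert (theta - x.mean()) / x.std(ddof=1) == pytest.approx(2.0)


def _trace(rate, t_start=0.0):
    return RateTrace(t_start=t_start, rate=np.asarray(rate, float))


class TestDetectLatency:
    def test_flat_subthreshold_returns_none(self):
        trace = _trace(np.full(200, 5.0))
        assert detect_latency(trace, [60.0], 10.0, (40, 110)) is None

    def test_burst_onset_at_first_burst_spike(self, kernel):
        # silence, then a dense burst from 60 ms; threshold well below the
        # burst rate -> onset at the first burst spike
        spikes = np.arange(60.0, 110.0, 2.0)
        trace = estimate_rate(spikes, kernel, 0, 200)
        lat = detect_latency(trace, spikes, 15.0, (40, 110))
        assert lat == 60.0
        assert lat == brute_force_latency(trace.rate, trace.t_start, spikes,
                                          15.0, (40, 110))

    @staticmethod
    def _dipped_rate(dip_ms):
        # subthreshold baseline, burst onset at 60, a dip before the peak
        rate = np.full(200, 2.0)
        rate[60:70] = 30.0
        rate[70:70 + dip_ms] = 2.0
        rate[70 + dip_ms:100] = 50.0  # peak after the dip
        return rate

    def test_short_dip_is_walked_through(self):
        # a 3 ms subthreshold dip between burst onset and peak is ignored
        # by the backward walk (run < 5 ms)
        rate = self._dipped_rate(3)
        spikes = np.arange(55.0, 100.0, 1.0)
        lat = detect_latency(_trace(rate), spikes, 10.0, (40, 110))
        assert lat == brute_force_latency(rate, 0.0, spikes, 10.0, (40, 110))
        assert lat < 70.0  # stopped before the dip, at burst onset

    def test_long_dip_stops_the_walk(self):
        rate = self._dipped_rate(6)
        spikes = np.arange(55.0, 100.0, 1.0)
        lat = detect_latency(_trace(rate), spikes, 10.0, (40, 110))
        assert lat == brute_force_latency(rate, 0.0, spikes, 10.0, (40, 110))
        assert lat >= 75.0  # walk terminated at the dip, not at burst onset

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            detect_latency(_trace(np.ones(100)), [], 1.0, (50, 50))

    def test_oracle_equivalence_on_random_trials(self, kernel):
        """Implementation == brute-force enumeration on 500 synthetic trials."""
        rng = np.random.default_rng(2024)
        n_checked = 0
        for i in range(500):
            base = rng.uniform(2, 30)
            amp = rng.uniform(0, 300)
            lat_true = rng.uniform(45, 95)
            n_base = rng.poisson(base * 0.8)
            spikes = np.sort(np.concatenate([
                rng.uniform(-200, 600, n_base),
                lat_true + rng.exponential(10, rng.poisson(amp * 0.02)),
            ]))
            trace = estimate_rate(spikes, kernel, -200, 600)
            theta = rng.uniform(5, 80)
            win = (40.0, 110.0)
            got = detect_latency(trace, spikes, theta, win)
            want = brute_force_latency(trace.rate, trace.t_start, spikes,
                                       theta, win)
            assert got == want, f"trial {i}: {got} != {want}"
            n_checked += 1
        assert n_checked == 500

    def test_latency_shift_equivariance(self, kernel, rng):
        spikes = np.sort(np.concatenate([rng.uniform(-100, 500, 20),
                                         60 + rng.exponential(8, 40)]))
        trace = estimate_rate(spikes, kernel, -200, 600)
        lat = detect_latency(trace, spikes, 30.0, (40, 110))
        delta = 17.0
        trace2 = estimate_rate(spikes + delta, kernel, -200 + delta, 600 + delta)
        lat2 = detect_latency(trace2, spikes + delta, 30.0, (40 + delta, 110 + delta))
        assert lat is not None
        assert lat2 == pytest.approx(lat + delta)


class TestBurstStrength:
    def test_zero_count_minus_baseline(self):
        assert burst_strength([], (50, 110), 1.5) == -1.5

    def test_count_arithmetic(self):
        spikes = np.linspace(55, 105, 7)
        assert burst_strength(spikes, (50, 110), 2.0) == 5.0

    def test_window_half_open(self):
        assert burst_strength([50.0, 110.0], (50, 110), 0.0) == 1.0


class TestPrestimState:
    def test_window_membership(self):
        assert prestim_state([-60.0, -10.0, -3.0, 5.0]) == 2

    def test_empty(self):
        assert prestim_state([]) == 0


class TestLatencyInclusion:
    @pytest.mark.parametrize("n_detected,n_total,expected", [
        (24, 40, True),    # exactly 60%
        (23, 40, False),   # 57.5%
        (0, 40, False),
        (40, 40, True),
    ])
    def test_sixty_percent_rule(self, n_detected, n_total, expected):
        detected = np.r_[np.ones(n_detected), np.zeros(n_total - n_detected)]
        assert latency_inclusion(detected) is expected


class TestEpochDefaults:
    @pytest.mark.parametrize("area,group,lat_win,str_win", [
        ("SC", "low", (40, 110), (50, 110)),
        ("SC", "high", (40, 100), (40, 100)),
        ("V1", "low", (30, 105), (35, 120)),
        ("V1", "high", (30, 95), (30, 115)),
    ])
    def test_windows(self, area, group, lat_win, str_win):
        cfg = EpochConfig.default(area, group)
        assert cfg.latency_search_window == lat_win
        assert cfg.strength_window == str_win
        assert cfg.baseline_window == (-50.0, 0.0)
        # SC strength epochs are 60 ms, V1 epochs 85 ms
        dur = str_win[1] - str_win[0]
        assert dur == (60 if area == "SC" else 85)


class TestFeatureTable:
    def test_mean_latency_tracks_programmed(self):
        cfg = SimConfig(n_neurons=2, n_trials_per_condition=60,
                        contrasts=(50,), polarities=("dark",), seed=21,
                        include_delayed_task=False)
        f = compute_feature_table(generate_session(cfg))
        mu = cfg.burst_latency_mean[50]
        # detected onsets sit at the first burst spike, slightly after the
        # programmed latent onset
        assert f["latency_ms"].mean() == pytest.approx(mu, abs=6.0)
        assert f["detected"].mean() > 0.9

    def test_strength_monotone_in_amplitude(self):
        means = []
        for scale in (1.0, 2.0):
            amp = {50: 200.0 * scale}
            cfg = SimConfig(n_neurons=1, n_trials_per_condition=300,
                            contrasts=(50,), polarities=("dark",), seed=22,
                            burst_amp_mean=amp, include_delayed_task=False)
            f = compute_feature_table(generate_session(cfg))
            means.append(f["strength"].mean())
        assert means[1] > means[0]

    def test_latencies_lie_in_search_window(self, sc_session):
        f = compute_feature_table(sc_session)
        det = f[np.isfinite(f["latency_ms"])]
        for (c, _), g in det.groupby(["contrast", "polarity"]):
            grp = "low" if c == 20 else "high"
            w = EpochConfig.default("SC", grp).latency_search_window
            assert g["latency_ms"].between(w[0], w[1]).all()
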