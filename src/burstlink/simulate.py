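"""Synthetic electrophysiology sessions with known ground truth.

Generates the data streams the analysis stages consume: an immediate
visually-guided saccade task (trial table + spike events), an optional
delayed-saccade block used for the visuomotor index, laminar LFPs with a
known current sink, and biphasic mean spike waveforms of known
trough-to-peak width.

The generative model per neuron and trial is deliberately simple and fully
parameterised so that every downstream estimate can be checked against the
programmed truth:

* latent trial features — burst onset latency ``L_t ~ N(mu_L(c, pol), sd_L)``,
  burst amplitude ``A_t ~ N(mu_A(c), sd_A)`` (truncated at 0) and baseline
  rate ``B_t ~ N(b, sd_b)`` (truncated at 0);
* reaction time ``RT_t = rt_intercept + slope log2(c_max / c) +
  bL (L_t - mu_L) - bA (A_t - mu_A) - bB (B_t - b) + eps_t`` with mean-zero
  right-skewed (shifted-Gamma) noise, truncated below at ``L_t + 20`` ms so
  the saccade never precedes the visual burst; the contrast term makes
  low-contrast saccades slower;
* spikes from an inhomogeneous Poisson process with intensity
  ``lam(tau) = B_t + A_t s(tau - L_t) + M s(tau - RT_t)`` where
  ``s`` is a unit-peak rise/decay burst shape and ``M`` the saccade-locked
  motor amplitude (0 for purely visual neurons and for the V1-like profile).

Positive ``coupling_latency`` therefore programs a positive latency-RT
correlation, and positive ``coupling_strength`` / ``coupling_baseline``
program negative strength-RT / baseline-RT correlations, matching the sign
conventions of the analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SessionBundle",
    "generate_session",
    "generate_laminar_lfp",
    "generate_waveform",
    "burst_shape",
]

TRIAL_WINDOW_MS = (-200.0, 600.0)  # recording window around stimulus onset

# default contrast-dependent burst parameters (Weber-contrast % -> value)
_SC_AMP_MEAN = {10: 250.0, 20: 350.0, 50: 480.0, 100: 560.0}
_SC_LAT_MEAN = {10: 85.0, 20: 75.0, 50: 62.0, 100: 52.0}
_V1_AMP_MEAN = {10: 200.0, 20: 280.0, 50: 380.0, 100: 440.0}
_V1_LAT_MEAN = {10: 78.0, 20: 70.0, 50: 58.0, 100: 48.0}


def burst_shape(tau: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak rise/decay burst shape s(tau) for tau >= 0, 0 otherwise.

    s(tau) = (1 - e^(-tau/tau_rise)) e^(-tau/tau_decay), normalised so that
    its maximum (at tau* = tau_rise ln(1 + tau_decay/tau_rise)) equals 1.
    """
    tau = np.asarray(tau, dtype=float)
    t_star = tau_rise * np.log1p(tau_decay / tau_rise)
    peak = (1.0 - np.exp(-t_star / tau_rise)) * np.exp(-t_star / tau_decay)
    out = np.where(
        tau >= 0,
        (1.0 - np.exp(-np.maximum(tau, 0.0) / tau_rise))
        * np.exp(-np.maximum(tau, 0.0) / tau_decay),
        0.0,
    )
    return out / peak


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording session.

    Rates are in spikes/s, times in ms, contrasts in Weber-contrast percent.
    ``coupling_*`` weights map latent trial features onto reaction time
    (ms per unit of the feature).
    """

    n_neurons: int = 20
    n_trials_per_condition: int = 40  # typical session: 35-45 per condition
    contrasts: tuple[int, ...] = (10, 20, 50, 100)
    polarities: tuple[str, ...] = ("dark", "bright")
    area_profile: str = "SC"  # {"SC", "V1"}
    baseline_rate: float = 20.0
    baseline_sd: float = 4.0
    burst_amp_mean: Mapping[int, float] = field(default_factory=lambda: dict(_SC_AMP_MEAN))
    burst_amp_sd: float = 120.0
    burst_latency_mean: Mapping[int, float] = field(default_factory=lambda: dict(_SC_LAT_MEAN))
    burst_latency_sd: float = 8.0
    bright_latency_offset: float = 3.0  # bright stimuli respond slightly later
    tau_rise: float = 5.0
    tau_decay: float = 15.0
    motor_amp: float = 300.0
    coupling_latency: float = 0.20   # beta_L, ms of RT per ms of latency
    coupling_strength: float = 0.068  # beta_A, ms of RT per spikes/s of amplitude
    coupling_baseline: float = 1.0   # beta_B, ms of RT per spikes/s of baseline
    rt_intercept: float = 180.0
    rt_contrast_slope_ms: float = 11.0  # extra RT per halving of contrast
    rt_noise_sd: float = 25.0
    rt_noise_shape: float = 4.0  # Gamma shape of the (shifted) RT noise
    shared_latent_frac: float = 1.0  # fraction of latent SD shared across neurons
    seed: int = 0
    include_delayed_task: bool = True
    n_delay_trials: int = 20
    include_waveforms: bool = False
    include_lfp: bool = False

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 2:
            raise ValueError("n_trials_per_condition must be >= 2")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.area_profile not in ("SC", "V1"):
            raise ValueError(f"unknown area_profile {self.area_profile!r}")
        for name in ("baseline_rate", "baseline_sd", "burst_amp_sd",
                     "burst_latency_sd", "rt_noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("tau_rise", "tau_decay", "rt_intercept", "rt_noise_shape"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for c in self.contrasts:
            if c not in self.burst_amp_mean or c not in self.burst_latency_mean:
                raise ValueError(f"no burst parameters for contrast {c}")
            if self.burst_amp_mean[c] < 0:
                raise ValueError("burst amplitudes must be >= 0")

    @classmethod
    def sc_like(cls, **overrides) -> "SimConfig":
        """SC-like profile: visual-motor neurons with feature-RT coupling."""
        return cls(**overrides)

    @classmethod
    def v1_like(cls, **overrides) -> "SimConfig":
        """V1-like profile: purely visual, no feature-RT coupling."""
        defaults = dict(
            area_profile="V1",
            baseline_rate=10.0,
            baseline_sd=3.0,
            burst_amp_mean=dict(_V1_AMP_MEAN),
            burst_amp_sd=100.0,
            burst_latency_mean=dict(_V1_LAT_MEAN),
            motor_amp=0.0,
            coupling_latency=0.0,
            coupling_strength=0.0,
            coupling_baseline=0.0,
            include_delayed_task=False,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def replace(self, **overrides) -> "SimConfig":
        return replace(self, **overrides)


@dataclass
class SessionBundle:
    """All data streams of one (simulated or loaded) recording session."""

    trials: pd.DataFrame     # trial_id, contrast, polarity, reaction_time_ms, saccade_onset_ms
    spikes: pd.DataFrame     # neuron_id, trial_id, spike_time_ms (stimulus-aligned)
    neurons: pd.DataFrame    # neuron_id, area, ground-truth latent parameters
    delayed_trials: pd.DataFrame | None = None  # trial_id, go_time_ms, saccade_time_ms
    delayed_spikes: pd.DataFrame | None = None
    lfp: np.ndarray | None = None          # channel x time x trial
    lfp_meta: dict | None = None           # spacing_um, fs_hz, t_start_ms, sink_channel
    waveforms: dict[int, np.ndarray] | None = None
    waveform_sampling_us: float = 25.0
    config: SimConfig | None = None

    @property
    def window(self) -> tuple[float, float]:
        return TRIAL_WINDOW_MS


def _rt_noise(rng: np.random.Generator, sd: float, shape: float, size) -> np.ndarray:
    """Mean-zero, right-skewed reaction-time noise (shifted Gamma)."""
    if sd == 0:
        return np.zeros(size)
    scale = sd / np.sqrt(shape)
    return rng.gamma(shape, scale, size=size) - shape * scale


REFRACTORY_MS = 1.0  # absolute refractory period imposed on sampled trains


def _draw_inhomogeneous_spikes(rng, base, amp, lat, motor, motor_t,
                               tau_rise, tau_decay, t0, t1,
                               refractory_ms=REFRACTORY_MS):
    """Thinning sampler for lam(tau) = B + A s(tau-L) + M s(tau-motor_t).

    All per-trial parameter arguments are arrays of equal length; returns
    (trial_index, spike_time) arrays sorted by trial then time.  Negative
    motor amplitudes (suppression) are allowed; the intensity is clipped
    at zero.  An absolute refractory period is imposed afterwards by
    dead-time deletion (keeps the earlier spike of any violating pair), as
    in real single units.
    """
    base = np.asarray(base, float)
    n = len(base)
    dur = (t1 - t0) / 1000.0
    lam_max = base + np.maximum(amp, 0.0) + np.maximum(motor, 0.0)
    counts = rng.poisson(lam_max * dur)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, int), np.empty(0, float)
    trial_idx = np.repeat(np.arange(n), counts)
    t = rng.uniform(t0, t1, size=total)
    lam = (base[trial_idx]
           + amp[trial_idx] * burst_shape(t - lat[trial_idx], tau_rise, tau_decay)
           + motor[trial_idx] * burst_shape(t - motor_t[trial_idx], tau_rise, tau_decay))
    lam = np.maximum(lam, 0.0)
    accept = rng.uniform(0.0, 1.0, size=total) * lam_max[trial_idx] < lam
    trial_idx, t = trial_idx[accept], t[accept]
    order = np.lexsort((t, trial_idx))
    trial_idx, t = trial_idx[order], t[order]
    if refractory_ms > 0 and t.size:
        keep = np.ones(t.size, dtype=bool)
        last = -np.inf
        last_trial = -1
        for i in range(t.size):
            if trial_idx[i] != last_trial:
                last_trial = trial_idx[i]
                last = t[i]
            elif t[i] - last < refractory_ms:
                keep[i] = False
            else:
                last = t[i]
        trial_idx, t = trial_idx[keep], t[keep]
    return trial_idx, t


def generate_session(config: SimConfig) -> SessionBundle:
    """Simulate one session; identical config (incl. seed) gives identical output.

    Per-neuron random substreams are spawned from the config seed, so the
    spikes of neuron ``k`` do not depend on how many neurons precede it.
    """
    v1 = config.area_profile == "V1"
    bL = 0.0 if v1 else config.coupling_latency
    bA = 0.0 if v1 else config.coupling_strength
    bB = 0.0 if v1 else config.coupling_baseline
    motor_amp = 0.0 if v1 else config.motor_amp

    rng0 = np.random.default_rng(np.random.SeedSequence(config.seed))
    t0, t1 = TRIAL_WINDOW_MS

    conditions = [(c, p) for p in config.polarities for c in config.contrasts]
    n_cond = len(conditions)
    ntr = config.n_trials_per_condition
    n_trials = n_cond * ntr
    trial_ids = np.arange(n_trials)
    contrast = np.repeat([c for c, _ in conditions], ntr)
    polarity = np.repeat([p for _, p in conditions], ntr)

    # per-neuron structural parameters
    neuron_rows = []
    spike_frames = []
    d_spike_frames = []

    mu_L = np.array([config.burst_latency_mean[c] for c in contrast], float)
    mu_L = mu_L + np.where(polarity == "bright", config.bright_latency_offset, 0.0)
    mu_A = np.array([config.burst_amp_mean[c] for c in contrast], float)

    # Reaction time is a property of the trial, not of any one neuron.  It
    # is driven by session-level latent features (a per-trial excitability
    # drive); each neuron's latents equal the shared drive plus optional
    # private jitter (shared_latent_frac < 1).
    shared_frac = float(np.clip(config.shared_latent_frac, 0.0, 1.0))
    priv = np.sqrt(1.0 - shared_frac**2)
    rng_trial = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    zL_shared = rng_trial.normal(0.0, 1.0, n_trials)
    zA_shared = rng_trial.normal(0.0, 1.0, n_trials)
    zB_shared = rng_trial.normal(0.0, 1.0, n_trials)
    noise = _rt_noise(rng_trial, config.rt_noise_sd, config.rt_noise_shape, n_trials)

    rt = (config.rt_intercept
          + config.rt_contrast_slope_ms * np.log2(np.max(contrast) / contrast)
          + bL * config.burst_latency_sd * zL_shared
          - bA * config.burst_amp_sd * zA_shared
          - bB * config.baseline_sd * zB_shared
          + noise)
    L_shared = mu_L + config.burst_latency_sd * zL_shared
    rt = np.maximum(rt, L_shared + 20.0)  # saccade never precedes the burst

    delayed = config.include_delayed_task and not v1
    if delayed:
        rng_del = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
        nd = config.n_delay_trials
        go_time = rng_del.uniform(500.0, 800.0, nd)
        move_rt = np.maximum(rng_del.normal(200.0, 30.0, nd), 100.0)
        d_sacc = go_time + move_rt
        delayed_trials = pd.DataFrame({
            "trial_id": np.arange(nd),
            "go_time_ms": go_time,
            "saccade_time_ms": d_sacc,
        })
    else:
        delayed_trials = None

    for k in range(config.n_neurons):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3, k)))
        b_n = max(rng.normal(config.baseline_rate, 0.15 * config.baseline_rate), 0.5)

        zL = shared_frac * zL_shared + priv * rng.normal(0.0, 1.0, n_trials)
        zA = shared_frac * zA_shared + priv * rng.normal(0.0, 1.0, n_trials)
        zB = shared_frac * zB_shared + priv * rng.normal(0.0, 1.0, n_trials)
        L = mu_L + config.burst_latency_sd * zL
        A = np.maximum(mu_A + config.burst_amp_sd * zA, 0.0)
        B = np.maximum(b_n + config.baseline_sd * zB, 0.0)

        tr, st = _draw_inhomogeneous_spikes(
            rng, B, A, L, np.full(n_trials, motor_amp), rt,
            config.tau_rise, config.tau_decay, t0, t1)
        spike_frames.append(pd.DataFrame({
            "neuron_id": k, "trial_id": trial_ids[tr], "spike_time_ms": st}))

        if delayed:
            rngd = np.random.default_rng(np.random.SeedSequence((config.seed, 4, k)))
            nd = config.n_delay_trials
            Ld = np.maximum(rngd.normal(np.mean(list(config.burst_latency_mean.values())),
                                        config.burst_latency_sd, nd), 20.0)
            Ad = np.maximum(rngd.normal(np.mean(list(config.burst_amp_mean.values())),
                                        config.burst_amp_sd, nd), 0.0)
            Bd = np.maximum(rngd.normal(b_n, config.baseline_sd, nd), 0.0)
            trd, std = _draw_inhomogeneous_spikes(
                rngd, Bd, Ad, Ld, np.full(nd, motor_amp), d_sacc,
                config.tau_rise, config.tau_decay, t0, float(np.max(d_sacc) + 300.0))
            d_spike_frames.append(pd.DataFrame({
                "neuron_id": k, "trial_id": trd, "spike_time_ms": std}))

        neuron_rows.append({
            "neuron_id": k,
            "area": config.area_profile,
            "baseline_rate": b_n,
            "motor_amp": motor_amp,
            "coupling_latency": bL,
            "coupling_strength": bA,
            "coupling_baseline": bB,
        })

    trials = pd.DataFrame({
        "trial_id": trial_ids,
        "contrast": contrast,
        "polarity": polarity,
        "reaction_time_ms": rt,
        "saccade_onset_ms": rt,
    })
    neurons = pd.DataFrame(neuron_rows)
    spikes = pd.concat(spike_frames, ignore_index=True) if spike_frames else pd.DataFrame(
        columns=["neuron_id", "trial_id", "spike_time_ms"])

    bundle = SessionBundle(
        trials=trials, spikes=spikes, neurons=neurons,
        delayed_trials=delayed_trials,
        delayed_spikes=(pd.concat(d_spike_frames, ignore_index=True)
                        if d_spike_frames else None),
        config=config,
    )

    if config.include_waveforms:
        rngw = np.random.default_rng(np.random.SeedSequence((config.seed, 5)))
        widths = np.where(rngw.uniform(size=config.n_neurons) < 0.4,
                          rngw.normal(200.0, 25.0, config.n_neurons),
                          rngw.normal(450.0, 50.0, config.n_neurons))
        widths = np.clip(widths, 120.0, 600.0)
        bundle.waveforms = {
            k: generate_waveform(widths[k], seed=int(1000 + k))
            for k in range(config.n_neurons)
        }
        bundle.neurons["waveform_width_us"] = widths

    if config.include_lfp:
        n_ch = 16
        sink = 7
        lfp = generate_laminar_lfp(sink_channel=sink, n_channels=n_ch,
                                   spacing_um=50.0, noise_sd=0.0,
                                   seed=int(config.seed) + 17)
        bundle.lfp = lfp
        bundle.lfp_meta = {"spacing_um": 50.0, "fs_hz": 1000.0,
                           "t_start_ms": -50.0, "sink_channel": sink}
    return bundle


def generate_laminar_lfp(sink_channel: int, n_channels: int, spacing_um: float,
                         noise_sd: float, seed: int, n_trials: int = 10,
                         duration_ms: float = 300.0, t_start_ms: float = -50.0,
                         sink_amp: float = 1.0) -> np.ndarray:
    """Forward-model a laminar LFP with a known stimulus-driven current sink.

    A dipole-balanced current-source-density depth profile (sink of
    amplitude ``-2 sink_amp`` at ``sink_channel``, sources ``+sink_amp`` on
    its two neighbours) is integrated twice over depth to a potential
    profile, modulated by a 0-100 ms post-stimulus temporal envelope, and
    corrupted with white Gaussian noise.  The returned array is
    channel x time x trial at 1 kHz; channel 0 is the most superficial.

    The construction inverts exactly under the second-spatial-difference
    CSD estimator: with ``noise_sd = 0`` the strongest recovered sink is at
    ``sink_channel``.
    """
    if n_channels < 5:
        raise ValueError("need at least 5 channels")
    if not (1 <= sink_channel <= n_channels - 2):
        raise ValueError("sink channel must not be an edge channel "
                         "(second spatial difference undefined there)")
    h2 = (spacing_um / 100.0) ** 2  # arbitrary-unit depth scaling
    csd = np.zeros(n_channels)
    csd[sink_channel] = -2.0 * sink_amp
    csd[sink_channel - 1] = sink_amp
    csd[sink_channel + 1] = sink_amp
    # integrate -csd twice over depth: phi[i-1] - 2 phi[i] + phi[i+1] = -csd[i] h^2
    phi = np.zeros(n_channels)
    for i in range(1, n_channels - 1):
        phi[i + 1] = -csd[i] * h2 + 2.0 * phi[i] - phi[i - 1]
    phi -= phi.mean()

    n_t = int(round(duration_ms))
    t = np.arange(n_t, dtype=float) + t_start_ms
    envelope = burst_shape(t, 10.0, 30.0)  # transient confined to ~0-100 ms
    signal = phi[:, None] * envelope[None, :]
    rng = np.random.default_rng(seed)
    lfp = signal[:, :, None] + rng.normal(0.0, noise_sd,
                                          size=(n_channels, n_t, n_trials))
    return lfp


def generate_waveform(trough_to_peak_us: float, sampling_period_us: float = 25.0,
                      polarity: str = "negative", seed: int | None = None,
                      noise_sd: float = 0.0) -> np.ndarray:
    """Biphasic mean spike waveform with a programmed trough-to-peak width.

    A negative Gaussian trough at 600 us followed by a positive Gaussian
    peak ``trough_to_peak_us`` later, sampled over [0, 1800] us.  Lobe
    widths scale with (and stay well below) the separation so the sampled
    extrema sit within half a sample of the programmed positions.
    """
    if trough_to_peak_us <= 0 or sampling_period_us <= 0:
        raise ValueError("widths and sampling period must be positive")
    if trough_to_peak_us < 2.0 * sampling_period_us:
        raise ValueError("trough_to_peak narrower than 2 samples")
    t = np.arange(0.0, 1800.0 + 0.5 * sampling_period_us, sampling_period_us)
    t_trough = 600.0
    s1 = min(60.0, trough_to_peak_us / 4.0)
    s2 = min(90.0, trough_to_peak_us / 3.0)
    w = (-np.exp(-0.5 * ((t - t_trough) / s1) ** 2)
         + 0.5 * np.exp(-0.5 * ((t - t_trough - trough_to_peak_us) / s2) ** 2))
    if polarity == "positive":
        w = -w
    elif polarity != "negative":
        raise ValueError(f"unknown polarity {polarity!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        w = w + rng.normal(0.0, noise_sd, size=w.shape)
    return w
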