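# burstlink

Trial-by-trial analysis linking single-neuron visual response features to
saccadic reaction-time variability, for extracellular recordings from the
superior colliculus (SC) and primary visual cortex (V1) during immediate
visually-guided saccades — together with a fully parameterised synthetic
session generator that makes every stage of the analysis verifiable
against known ground truth.

## Who this is for

Systems/computational neuroscientists asking how much of the variability
in saccadic reaction time (SRT) is explained, trial by trial, by when a
visual burst starts, how strong it is, and how active the neuron was just
before the stimulus — and wanting a tested, reusable implementation of
that whole measurement chain rather than one-off analysis scripts.

## The measurement chain

For each neuron, trial and stimulus condition (Weber contrast × luminance
polarity):

1. **Causal-kernel firing rate.** Spike times are convolved with an
   asymmetric rise–decay kernel, `k(τ) ∝ (1 − e^(−τ/τ_r)) e^(−τ/τ_d)` for
   `τ ≥ 0` (defaults τ_r = 1 ms, τ_d = 20 ms, unit area), which never blurs
   activity backwards in time — essential when the quantity of interest is
   a response *onset*.
2. **Single-trial onset latency.** Find the rate peak inside an area- and
   contrast-specific search window (SC: 40–110 / 40–100 ms; V1: 30–105 /
   30–95 ms for low / high contrasts), then walk backward until the rate
   has been below θ = mean + 2·SD of the across-trial pre-stimulus rate
   for at least 5 consecutive ms; the first spike past that subthreshold
   run is the trial's visual response onset. A neuron enters latency
   analyses for a condition only if the onset is detectable on ≥ 60% of
   trials.
3. **Burst strength and pre-stimulus state.** Strength is the spike count
   in a fixed epoch (SC: 60 ms; V1: 85 ms, contrast-dependent start) minus
   the across-trial mean count in the 50 ms baseline; the pre-stimulus
   state is the spike count in the final 50 ms before stimulus onset.
4. **Correlation and population statistics.** Per neuron × condition,
   Spearman ρ between each feature and SRT (exact permutation p for
   n ≤ 9); populations are tested with Wilcoxon signed-rank against zero
   (zeros disregarded), Mann–Whitney U between groups, and Bonferroni
   correction across contrasts.
5. **Gamma mixed model.** `SRT ~ latency × contrast + strength × contrast
   + (1 | neuron)`, Gamma family with log link, all predictors z-scored,
   fitted by a Laplace-approximate maximum-likelihood engine written for
   this package (vectorised Newton inner solve per neuron, quasi-Newton
   outer optimisation over fixed effects, log RE-SD and log shape), with
   Wald tests, single-term-deletion likelihood-ratio tests (df = 2 for
   latency/strength, 3 for contrast) and AIC.
6. **Neuron typing and anatomy.** ISI quality control (< 1.5% of ISIs
   below 0.8 ms), visual / visual-motor classification from four task
   windows (Kruskal–Wallis + rank post-hocs), the visuomotor index
   VMI = (V − M)/(V + M) from a delayed-saccade block with sliding-bin
   summaries, current-source-density input-layer identification from
   laminar LFPs, and spike-waveform trough-to-peak typing (narrow < 350 µs
   after cubic upsampling to 5 µs) behind an AUROC ≥ 0.95 quality gate.

Because the original recordings are not publicly deposited, the package
ships a generator (`burstlink.simulate`) that produces sessions with this
exact statistical structure — inhomogeneous-Poisson spike trains whose
burst latency/amplitude/baseline covary with reaction time through
configurable couplings, saccade-locked motor bursts, laminar LFPs with a
known current sink, and waveforms of known width — so that every stage
can be tested by parameter recovery.

## Worked example

Twenty-five simulated SC-like neurons (one session each, 40 trials per
condition, default couplings), correlated and fitted:

```python
import pandas as pd
from burstlink import (SimConfig, generate_session, compute_feature_table,
                       correlate_features)
from burstlink.glmm import GammaMixedModel

cfg = SimConfig(n_neurons=1, n_trials_per_condition=40, seed=7)
feats = pd.concat([
    compute_feature_table(generate_session(cfg.replace(seed=100 + k)))
      .assign(neuron_id=k)
    for k in range(25)], ignore_index=True)

recs = correlate_features(feats)
print(recs.groupby("feature")["rho"].agg(["mean", "median", "count"]))

d = feats[feats.polarity == "dark"].dropna(subset=["latency_ms"])
print(GammaMixedModel.from_dataframe(d).fit().summary())
```

prints

```
            mean  median  count
feature
latency   0.0782  0.0729    200
prestim  -0.0485 -0.0510    200
strength -0.1789 -0.1996    200
Gamma log-link mixed model (Laplace approximation)
  observations: 3799   groups: 25
  logLik: -17726.29   AIC: 35468.58   converged: True
  random-intercept SD: 0.0041   Gamma shape: 57.958

  term                          coef        SE        z           p
  Intercept                   5.2784    0.0032  1660.67           0
  latency_z                   0.0069    0.0037     1.84      0.0652
  strength_z                 -0.0293    0.0028   -10.43    1.73e-25
  contrast_z                 -0.0452    0.0037   -12.07    1.55e-33
  latency_z:contrast_z       -0.0004    0.0033    -0.13       0.893
  strength_z:contrast_z       0.0062    0.0027     2.33      0.0196
```

Read: later burst onsets go with later saccades (mean latency ρ ≈ +0.08),
stronger bursts with earlier saccades (mean strength ρ ≈ −0.18, median
−0.20), and in the mixed model higher contrast and stronger bursts both
shorten log reaction time, with neuron identity absorbed by the random
intercept. These are the programmed couplings of the generator being
recovered by the full measurement chain.

A command-line interface mirrors the stages
(`burstlink simulate | rates | features | classify | correlate | laminar |
waveforms | pipeline | validate`); `burstlink pipeline --config run.yaml`
runs a configured, logged, fully deterministic end-to-end analysis.

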