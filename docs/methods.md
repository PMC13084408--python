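# Methods

This note documents the models and numerical procedures implemented in
`burstlink`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the design choices made where the
procedure admitted more than one reasonable reading.

## Rate estimation

Single-trial firing rates are estimated by convolving spike trains with a
causal rise–decay kernel `k(τ) ∝ (1 − e^(−τ/τ_rise)) e^(−τ/τ_decay)`,
`τ ≥ 0`, on a 1 ms grid. Defaults are τ_rise = 1 ms and τ_decay = 20 ms — a
postsynaptic-potential-like kernel standard in single-trial latency work;
both constants are configurable and logged, and a sensitivity check on the
detector (oracle equivalence holds for any kernel) is part of the suite.
The kernel is truncated once 99.9% of its mass is retained and
renormalised to unit area, so convolution preserves spike count.

Discretization: the weight of lag bin *j* is the exact integral of the
continuous kernel over [*j*, *j*+1) ms, and each spike is assigned to the
grid point at or immediately after it (ceil). This combination keeps the
estimate strictly causal — the rate is exactly zero at every grid time
strictly before the first spike — while giving the natural limits (as
τ_rise → 0 the lag-0 weight tends to 1 ms/τ_decay). Rate traces are exactly
linear in the spike train and equivariant under integer time shifts.

## Single-trial onset latency

Within an area- and contrast-group-specific search window (SC low/high
contrasts: 40–110 / 40–100 ms; V1: 30–105 / 30–95 ms), the detector finds
the earliest time of the maximum rate (ties broken to the earliest — the
only deterministic choice). If that maximum is below the threshold
θ = mean + 2·SD (sample SD) of the per-trial mean pre-stimulus rates of
the condition, the trial has no detectable burst. Otherwise it walks
backward from the peak to the latest grid time `t_c` at which the rate has
been strictly below θ at 5 or more consecutive 1 ms samples ending at
`t_c`; shorter subthreshold dips do not stop the walk (they act as a noise
guard, verified against a brute-force enumeration oracle). The reported
onset is the earliest spike whose causal grid bin lies at or after `t_c`
(equivalently, the spike is later than `t_c` − 1 ms), restricted to
[window start, peak time]; restricting candidates to the search window
keeps every defined latency inside it. The across-trial threshold SD is
taken over per-trial mean pre-stimulus rates (not pooled bins); this is
configurable.

Three further conventions: strength epochs are half-open [start, end) so
adjacent epochs never double-count a spike; the 60% latency-inclusion rule
is evaluated per condition (contrast × polarity), not pooled, which is why
neuron counts can differ across contrasts; and a neuron with no
pre-stimulus activity at all is assigned a zero pre-stimulus–RT
correlation rather than being dropped.

## Correlations and population statistics

Feature–RT associations are Spearman correlations (average ranks for
ties); nothing in the chain assumes linearity. Two-sided p-values are
exact (full enumeration of the n! pairings, cached per n) for n ≤ 9 and
use the t approximation otherwise. Population tests are non-parametric
throughout: Wilcoxon signed-rank against zero with the reduced-sample
convention (exact zeros disregarded; the effective n is reported
alongside the nominal n), and Mann–Whitney U between groups with a
tie-corrected normal approximation and no continuity correction (so
reported z-values match common statistics-package conventions). Bonferroni
correction multiplies raw p-values by the number of contrast levels.
Two-sided alternatives are used everywhere.

Across-trial reliability is the sample SD of a feature across trials
within a session, per neuron, summarised as mean ± SEM across neurons;
the same operator applied to reaction time gives the behavioral
variability summary. The fast/slow population summary normalises each
neuron's trial-averaged rate trace to its peak within the area's visual
epoch (zero-peak neurons dropped), splits trials into the fastest and
slowest floor(n/3) by RT (stable sort, ties by trial order — symmetric
and deterministic), and averages the normalised traces across neurons.

## The Gamma log-link mixed model

Reaction time is modelled as `RT_ij ~ Gamma(α, μ_ij)` with
`log μ_ij = x_ij'β + u_i`, `u_i ~ N(0, σ²)` per neuron. The design is the
fully crossed latency/strength-by-contrast model with an intercept; the
three predictors are z-scored over the fitted rows, and contrast enters
as a z-scored numeric percentage (10/20/50/100). Separate fits are run
per luminance polarity.

The fitting engine is this package's own: the marginal likelihood is
approximated by a Laplace expansion around the conditional mode of each
random intercept. Because the intercepts enter one-dimensionally and the
conditional log-density is strictly concave, the inner modes are found by
a damped Newton iteration vectorised across neurons (warm-started between
outer steps); the outer problem optimises (β, log σ, log α) jointly by
BFGS on the per-observation mean negative log-likelihood (gradient
tolerance 1e−7, with a Nelder–Mead polish if BFGS stalls). The Gamma
shape is estimated jointly with everything else rather than profiled.
Standard errors come from the numerical Hessian at the optimum; Wald
z = β/SE with two-sided normal p-values. AIC counts 6 fixed effects plus
the RE-SD and the shape (k = 8). Single-term deletion removes a predictor
together with all its interactions and refits, giving likelihood-ratio
χ² with df = 2 (latency or strength) or 3 (contrast). σ → 0 is a smooth
boundary: the fit then reproduces an independent plain Gamma-GLM (IRLS)
solution to 1e−4, and the full fit is cross-checked against lme4's
`glmer` in the test suite.

## Neuron typing, CSD, waveforms

Functional classification compares per-trial mean rates in a visual
window (40–95 ms post stimulus), pre-motor (−25–0 ms re saccade),
post-motor (0–65 ms re saccade) and baseline (50 ms pre stimulus) window.
The phrase "multiple-comparison Kruskal–Wallis test" is implemented as a
Kruskal–Wallis omnibus test (α = 0.05) gating pairwise two-sided
Mann–Whitney post-hocs Bonferroni-corrected over the six window pairs;
the post-hoc procedure is configurable since more than one reading is
defensible. "Visual" requires visual > baseline (significant); "motor"
requires post-motor vs baseline and pre-motor vs post-motor significant
with mean pre-motor below post-motor and above baseline; the labels
combine to visual / visual-motor / motor-only / unclassified.

The VMI uses delayed-task epochs: V = mean rate 50–100 ms post target
minus the −100..−1 ms baseline; M = peak kernel rate within ±25 ms of
saccade onset minus the pre-go baseline (−100..−1 ms before the go
signal). VMI = (V − M)/(V + M), clipped to [−1, 1]; significant motor
suppression (motor-epoch rates below pre-go baseline, Mann–Whitney at
α = 0.05) forces +1; V + M = 0 is undefined and the neuron is dropped
from binning. Note the peak-based M has a positive small-sample bias, so
purely visual neurons sit high on the VMI axis but below +1 unless the
suppression rule fires. Sliding bins have half-width 0.1 and step 0.05
(a neuron lands in 3–5 bins; empty bins are reported with n = 0).

CSD is the negated second spatial difference of the trial-averaged,
stimulus-aligned LFP, signed so synaptic input (a sink) is negative; the
input layer is the interior channel with the most negative mean CSD over
0–100 ms post stimulus. At ≤ 50 µm spacing the input channel ± 1 separates
superficial from deep; at coarser spacings the identified channel alone
does. LFP preprocessing uses zero-phase (forward–backward) Butterworth
filtering, split into separate high-pass (0.7 Hz) and low-pass stages
(300 Hz, then 100 Hz for CSD) — a single band-pass with a sub-Hz corner
is numerically fragile at kHz rates, and the high-pass stage is padded
over ~3 time constants to keep its edge transients out of the analysis
interval. The corners are package defaults, configurable, not asserted
to be any particular laboratory's choice.

Waveform quality is the AUROC between snippet amplitudes in a pre-spike
interval (first 20% of samples) and a spike interval (±0.2 ms around the
mean-waveform trough) — interval definitions are package choices, as is
the multimodality screen: 1- vs 2-component Gaussian mixtures compared by
BIC with a separation requirement, keeping the largest mode (ties broken
to the larger mean amplitude). Widths are measured after cubic
interpolation from 25 µs to a 5 µs grid as trough to largest subsequent
positive peak — invariant to amplitude scaling and time shifts — and
dichotomised at 350 µs into narrow- and broad-spiking.

## The synthetic session generator

No generative model is prescribed by the analysis itself, so the
generator uses the simplest latent structure that yields tunable
feature–RT couplings of either sign. Per trial: latency
L ~ N(μ_L(contrast, polarity), σ_L), amplitude A ~ N(μ_A(contrast), σ_A)
truncated at 0, baseline B ~ N(b, σ_b) truncated at 0, and

RT = intercept + slope·log2(c_max/c) + β_L(L − μ_L) − β_A(A − μ_A)
     − β_B(B − b) + ε,

with ε mean-zero shifted-Gamma (shape 4) so the RT marginal is strictly
positive and right-skewed, matching the mixed model's distributional
assumption, and RT truncated below at L + 20 ms so the saccade never
precedes the visual burst. Spikes are drawn by thinning from
λ(τ) = B + A·s(τ − L) + M·s(τ − RT), where s is the unit-peak rise/decay
shape (τ_rise = 5, τ_decay = 15 ms, chosen to resemble transient visual
bursts) and M the saccade-locked motor amplitude; a 1 ms absolute
refractory period is imposed by dead-time deletion, as sorted single
units would show. The V1-like profile zeroes all couplings and the motor
burst. Defaults: 40 trials per condition (sessions of 35–45 are typical),
contrasts {10, 20, 50, 100}%, both polarities, recording window
[−200, +600] ms, SC baseline 20 sp/s, contrast-graded burst amplitudes of
a few hundred sp/s and latencies of ~50–85 ms, RT intercept 180 ms with
25 ms noise SD and 11 ms of extra RT per halving of contrast. The SC-like
couplings (β_L = 0.20 ms/ms, β_A = 0.068 ms/(sp/s), β_B = 1.0 ms/(sp/s))
were fixed once so that a large-n oracle run of the full measurement
chain yields population correlations near +0.10 (latency) and −0.20
(strength) at mid contrast — effect sizes in the range the measurement
chain is meant to resolve.

Neurons within a session share the per-trial latent drive (the
`shared_latent_frac` parameter, default 1): a single behavioral RT can
only covary with many neurons through common trial state. The important
statistical consequence is that correlation estimates of same-session
neurons covary, so population claims are evaluated by pooling neurons
across independent sessions — exactly how multi-session experiments pool
real data — and the package's recovery tests do the same. A session also
carries an optional delayed-saccade block (for VMI), laminar LFPs built
by integrating a known dipole-balanced CSD profile twice over depth
(so CSD estimation inverts it exactly in the noiseless case), and
biphasic waveforms with programmed trough-to-peak widths accurate to
within half a sample.

What the generator does **not** emulate — and hence what passing tests do
not establish about real recordings: bursty/non-Poisson spiking beyond
dead-time, adaptation within trials, correlated noise across the
pre-stimulus and burst epochs, eye-position or microsaccade dynamics,
electrode drift, and spike-sorting contamination beyond the simple
amplitude mixtures used to exercise the waveform screen.

## Numerical conventions and degenerate inputs

All times are serialized in ms with stimulus onset at 0; saccade-aligned
epochs are computed on the fly. Peak ties break to the earliest time;
fast/slow ties break by trial order; the mode filter's 50/50 tie breaks
to the larger-mean mode. Undefined quantities propagate as explicit
signals (None/NaN) rather than sentinel numbers: undetectable latency,
VMI with V + M = 0, width of a waveform with no post-trough peak.
Degenerate statistical inputs (constant features, all-zero pre-stimulus
counts, < 3 paired trials) drop the neuron from that analysis, except for
the documented zero-pre-stimulus convention. Problem sizes in the
verification suite (e.g. a 100,000-trial oracle session, 100-seed
recovery ensembles, 25-neuron worked examples) were chosen to bound each
Monte-Carlo check's sampling error well below its assertion margin.

## Known limitations

* The Laplace approximation shares lme4's first-order accuracy; with few
  neurons or very small Gamma shape the RE-SD estimate is noisy (its
  sampling error dominates any approximation bias in our checks).
* The latency detector's 1 ms grid quantises the subthreshold-run rule;
  sub-millisecond dip geometry is not represented.
* The exact-p Spearman path enumerates permutations only up to n = 9;
  beyond that the t approximation is used, as is conventional.
* `waveform_quality` and `mode_filter` operate on snippet ensembles; the
  generator produces mean waveforms plus Gaussian/mixture snippet noise,
  not full extracellular traces.
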