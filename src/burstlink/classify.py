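"""Unit quality control, visual/visual-motor classification, and the VMI.

A unit passes quality control when fewer than 1.5% of its within-trial
inter-spike intervals violate a 0.8 ms refractory minimum.  Functional
classification compares per-trial firing rates in four windows (visual,
pre-motor, post-motor, baseline) with a Kruskal-Wallis omnibus test
followed by pairwise rank post-hoc comparisons.  The visuomotor index
VMI = (V - M)/(V + M) is computed from delayed-saccade-task epochs and
summarised over neurons in overlapping sliding bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rates import Kernel, build_kernel, estimate_rate
from .simulate import SessionBundle

__all__ = [
    "NeuronProfile",
    "isi_qc",
    "classify_functional",
    "compute_vmi",
    "vmi_binned_summary",
    "functional_window_rates",
    "vmi_from_delayed_task",
    "profile_neurons",
]

MIN_ISI_MS = 0.8
MAX_ISI_VIOLATION = 0.015

VISUAL_WINDOW = (40.0, 95.0)      # re stimulus onset
PREMOTOR_WINDOW = (-25.0, 0.0)    # re saccade onset
POSTMOTOR_WINDOW = (0.0, 65.0)    # re saccade onset
BASELINE_WINDOW = (-50.0, 0.0)    # re stimulus onset


@dataclass
class NeuronProfile:
    neuron_id: int
    qc_pass: bool
    isi_violation_fraction: float
    label: str                      # visual / visual-motor / motor-only / unclassified
    vmi: float | None = None
    vmi_source: str = "delayed-task"


def isi_qc(spike_times_by_trial: list[np.ndarray], min_isi_ms: float = MIN_ISI_MS,
           max_violation: float = MAX_ISI_VIOLATION) -> tuple[bool, float]:
    """Refractory-violation quality gate.

    Fraction of within-trial inter-spike intervals shorter than
    ``min_isi_ms``; the unit passes iff that fraction is strictly below
    ``max_violation`` (default 1.5%).  Units with fewer than two spikes
    pass vacuously with fraction 0.
    """
    n_isi = 0
    n_bad = 0
    for spikes in spike_times_by_trial:
        s = np.sort(np.asarray(spikes, dtype=float))
        if s.size < 2:
            continue
        isi = np.diff(s)
        n_isi += isi.size
        n_bad += int(np.count_nonzero(isi < min_isi_ms))
    if n_isi == 0:
        return True, 0.0
    frac = n_bad / n_isi
    return bool(frac < max_violation), float(frac)


def _pairwise_sig(a, b, alpha, n_comparisons):
    """Two-sided Mann-Whitney post-hoc comparison at a Bonferroni-corrected level."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return False
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return bool(p < alpha / n_comparisons)


def classify_functional(visual: np.ndarray, premotor: np.ndarray,
                        postmotor: np.ndarray, baseline: np.ndarray,
                        alpha: float = 0.05) -> str:
    """Classify a neuron from per-trial mean rates in the four analysis windows.

    A Kruskal-Wallis omnibus test over the four windows gates pairwise
    rank-based post-hoc comparisons (Bonferroni over the 6 window pairs).
    "visual": visual-window activity significantly above baseline.
    "motor": post-motor vs baseline significant, pre-motor vs post-motor
    significant, with mean pre-motor below mean post-motor and above mean
    baseline.  The two labels combine to visual / visual-motor /
    motor-only / unclassified.
    """
    samples = [np.asarray(x, float) for x in (visual, premotor, postmotor, baseline)]
    n = min(len(x) for x in samples)
    if n < 5:
        warnings.warn("fewer than 5 trials: neuron left unclassified", stacklevel=2)
        return "unclassified"
    visual_s, premotor_s, postmotor_s, baseline_s = samples
    try:
        kw_p = stats.kruskal(*samples).pvalue
    except ValueError:  # all values identical
        return "unclassified"
    if not (kw_p < alpha):
        return "unclassified"
    n_comp = 6
    is_visual = (_pairwise_sig(visual_s, baseline_s, alpha, n_comp)
                 and visual_s.mean() > baseline_s.mean())
    is_motor = (_pairwise_sig(postmotor_s, baseline_s, alpha, n_comp)
                and _pairwise_sig(premotor_s, postmotor_s, alpha, n_comp)
                and premotor_s.mean() < postmotor_s.mean()
                and premotor_s.mean() > baseline_s.mean())
    if is_visual and is_motor:
        return "visual-motor"
    if is_visual:
        return "visual"
    if is_motor:
        return "motor-only"
    return "unclassified"


def compute_vmi(visual_measure: float, motor_measure: float,
                motor_suppressed: bool = False) -> float | None:
    """Visuomotor index (V - M)/(V + M) in [-1, +1].

    +1 for a purely visual neuron (no motor response above baseline), -1
    for a purely motor one.  A neuron significantly suppressed in the
    motor epoch is assigned +1.  Returns None when V + M = 0 (index
    undefined; the neuron is dropped from VMI binning).
    """
    if motor_suppressed:
        return 1.0
    total = visual_measure + motor_measure
    if total == 0:
        return None
    vmi = (visual_measure - motor_measure) / total
    return float(np.clip(vmi, -1.0, 1.0))


def vmi_binned_summary(vmis: np.ndarray, values: np.ndarray,
                       half_width: float = 0.1, step: float = 0.05) -> pd.DataFrame:
    """Sliding-bin summary of a per-neuron quantity along the VMI axis.

    Overlapping bins of half-width 0.1 centred at -1.0, -0.95, ..., +1.0;
    a neuron contributes to every bin whose centre is within ``half_width``
    of its VMI.  Returns bin_center, mean, sem, n (empty bins with n = 0).
    """
    vmis = np.asarray(vmis, float)
    values = np.asarray(values, float)
    keep = np.isfinite(vmis) & np.isfinite(values)
    vmis, values = vmis[keep], values[keep]
    centers = np.round(np.arange(-1.0, 1.0 + step / 2, step), 10)
    rows = []
    for c in centers:
        in_bin = np.abs(vmis - c) <= half_width + 1e-12
        vals = values[in_bin]
        rows.append({
            "bin_center": c,
            "mean": vals.mean() if vals.size else np.nan,
            "sem": (vals.std(ddof=1) / np.sqrt(vals.size)
                    if vals.size > 1 else (0.0 if vals.size == 1 else np.nan)),
            "n": int(vals.size),
        })
    return pd.DataFrame(rows)


def _window_rates(spikes_by_trial, align, window):
    """Per-trial mean rates (spikes/s) from counts in a window re an alignment time."""
    w0, w1 = window
    dur = (w1 - w0) / 1000.0
    out = []
    for spikes, a in zip(spikes_by_trial, align):
        s = np.asarray(spikes, float) - a
        out.append(np.count_nonzero((s >= w0) & (s < w1)) / dur)
    return np.array(out)


def functional_window_rates(bundle: SessionBundle, neuron_id: int):
    """Per-trial mean rates in the four classification windows of the main task."""
    spk = bundle.spikes[bundle.spikes["neuron_id"] == neuron_id]
    by_trial = dict(tuple(spk.groupby("trial_id")))
    tids = bundle.trials["trial_id"].to_numpy()
    sacc = bundle.trials["saccade_onset_ms"].to_numpy()
    trains = [by_trial[t]["spike_time_ms"].to_numpy() if t in by_trial else np.empty(0)
              for t in tids]
    zeros = np.zeros(len(tids))
    return dict(
        visual=_window_rates(trains, zeros, VISUAL_WINDOW),
        premotor=_window_rates(trains, sacc, PREMOTOR_WINDOW),
        postmotor=_window_rates(trains, sacc, POSTMOTOR_WINDOW),
        baseline=_window_rates(trains, zeros, BASELINE_WINDOW),
    )


def vmi_from_delayed_task(bundle: SessionBundle, neuron_id: int,
                          kernel: Kernel | None = None,
                          alpha: float = 0.05) -> float | None:
    """VMI of one neuron from the delayed-saccade-task block of a session.

    Visual measure: mean rate 50-100 ms after target onset minus the
    -100..-1 ms pre-target baseline.  Motor measure: peak kernel rate
    within +/-25 ms of saccade onset minus the mean rate in the final
    100 ms before the go signal.  Motor suppression (motor-epoch rates
    significantly below pre-go baseline) forces VMI = +1.
    """
    if bundle.delayed_trials is None or bundle.delayed_spikes is None:
        return None
    if kernel is None:
        kernel = build_kernel()
    spk = bundle.delayed_spikes[bundle.delayed_spikes["neuron_id"] == neuron_id]
    by_trial = dict(tuple(spk.groupby("trial_id")))
    dt = bundle.delayed_trials
    trains = [by_trial[t]["spike_time_ms"].to_numpy() if t in by_trial else np.empty(0)
              for t in dt["trial_id"]]
    go = dt["go_time_ms"].to_numpy()
    sacc = dt["saccade_time_ms"].to_numpy()
    zeros = np.zeros(len(trains))

    vis = _window_rates(trains, zeros, (50.0, 100.0))
    vis_base = _window_rates(trains, zeros, (-100.0, -1.0))
    motor_base = _window_rates(trains, go, (-100.0, -1.0))
    motor_epoch = _window_rates(trains, sacc, (-25.0, 25.0))

    peak = np.empty(len(trains))
    for i, (s, a) in enumerate(zip(trains, sacc)):
        s = s[s < a + 60.0]  # spikes past the local grid cannot contribute
        trace = estimate_rate(s, kernel, a - 60.0, a + 60.0)
        j0 = trace.index_of(a - 25.0)
        j1 = trace.index_of(a + 25.0) + 1
        peak[i] = trace.rate[j0:j1].max()

    V = float(vis.mean() - vis_base.mean())
    M = float(peak.mean() - motor_base.mean())
    suppressed = False
    if np.ptp(np.concatenate([motor_epoch, motor_base])) > 0:
        p = stats.mannwhitneyu(motor_epoch, motor_base,
                               alternative="two-sided").pvalue
        suppressed = bool(p < alpha and motor_epoch.mean() < motor_base.mean())
    return compute_vmi(V, M, motor_suppressed=suppressed)


def profile_neurons(bundle: SessionBundle, alpha: float = 0.05) -> pd.DataFrame:
    """QC, functional label, and VMI for every neuron of a session."""
    rows = []
    for neuron_id in bundle.neurons["neuron_id"]:
        spk = bundle.spikes[bundle.spikes["neuron_id"] == neuron_id]
        trains = [g["spike_time_ms"].to_numpy()
                  for _, g in spk.groupby("trial_id")]
        qc_pass, frac = isi_qc(trains)
        w = functional_window_rates(bundle, int(neuron_id))
        label = classify_functional(w["visual"], w["premotor"], w["postmotor"],
                                    w["baseline"], alpha=alpha)
        vmi = vmi_from_delayed_task(bundle, int(neuron_id), alpha=alpha)
        rows.append({
            "neuron_id": int(neuron_id),
            "qc_pass": qc_pass,
            "isi_violation_fraction": frac,
            "label": label,
            "vmi": np.nan if vmi is None else vmi,
        })
    return pd.DataFrame(rows)
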