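"""Per-trial visual-burst features: onset latency, strength, pre-stimulus state.

The latency detector follows the peak-then-backward-walk rule: find the
peak of the causal-kernel rate trace inside an area- and contrast-specific
search window, walk backward until the rate has been below a
pre-stimulus-derived threshold for at least 5 consecutive milliseconds, and
take the first spike after that subthreshold run as the trial's visual
response onset.  Strength is a baseline-subtracted spike count in a fixed
epoch; the pre-stimulus state is the spike count in the final 50 ms before
stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rates import Kernel, RateTrace, build_kernel, estimate_rate
from .simulate import SessionBundle, TRIAL_WINDOW_MS

__all__ = [
    "EpochConfig",
    "detection_threshold",
    "detect_latency",
    "burst_strength",
    "prestim_state",
    "latency_inclusion",
    "compute_feature_table",
]

MIN_SUBTHRESHOLD_MS = 5       # backward walk stops after >= 5 ms below threshold
BASELINE_WINDOW_MS = (-50.0, 0.0)
DEFAULT_INCLUSION_FRACTION = 0.60

# area x contrast-group epoch defaults (ms relative to stimulus onset)
_LATENCY_WINDOWS = {
    ("SC", "low"): (40.0, 110.0),
    ("SC", "high"): (40.0, 100.0),
    ("V1", "low"): (30.0, 105.0),
    ("V1", "high"): (30.0, 95.0),
}
_STRENGTH_WINDOWS = {
    ("SC", "low"): (50.0, 110.0),   # 60 ms epoch
    ("SC", "high"): (40.0, 100.0),
    ("V1", "low"): (35.0, 120.0),   # 85 ms epoch
    ("V1", "high"): (30.0, 115.0),
}


@dataclass(frozen=True)
class EpochConfig:
    """Analysis epochs for one area and contrast group.

    ``contrast_group`` is "low" (the two lowest contrasts of the session)
    or "high" (the two highest).
    """

    area: str
    contrast_group: str
    latency_search_window: tuple[float, float]
    strength_window: tuple[float, float]
    baseline_window: tuple[float, float] = BASELINE_WINDOW_MS

    @classmethod
    def default(cls, area: str, contrast_group: str) -> "EpochConfig":
        key = (area, contrast_group)
        if key not in _LATENCY_WINDOWS:
            raise ValueError(f"no default epochs for {key}")
        return cls(area=area, contrast_group=contrast_group,
                   latency_search_window=_LATENCY_WINDOWS[key],
                   strength_window=_STRENGTH_WINDOWS[key])


def contrast_group_of(contrast: float, contrasts: list[float]) -> str:
    """Assign a contrast to the "low" (two lowest) or "high" group of its session."""
    ordered = sorted(set(contrasts))
    half = len(ordered) // 2 if len(ordered) > 1 else 1
    return "low" if contrast in ordered[:half] else "high"


def detection_threshold(prestim_trial_means: np.ndarray) -> float:
    """Burst-detection threshold: mean + 2 sample-SD of per-trial pre-stimulus rates."""
    x = np.asarray(prestim_trial_means, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 trials to define a detection threshold")
    return float(x.mean() + 2.0 * x.std(ddof=1))


def detect_latency(trace: RateTrace, spike_times: np.ndarray, threshold: float,
                   window: tuple[float, float],
                   min_subthreshold_ms: int = MIN_SUBTHRESHOLD_MS) -> float | None:
    """Single-trial visual response onset latency, or None if undetectable.

    Steps, all on the 1 ms rate grid:

    1. ``t_peak`` = earliest time of the maximum rate within
       ``[window[0], window[1])``; if that maximum is below ``threshold``
       the trial has no detectable burst.
    2. Walk backward from ``t_peak``: find the latest grid time ``t_c``
       before the peak such that the rate is strictly below ``threshold``
       at every one of the ``min_subthreshold_ms`` consecutive grid samples
       ending at ``t_c``.  A shorter subthreshold dip does not stop the
       walk.  If no such run exists within the trace, return None.
    3. The latency is the earliest spike past the subthreshold run — the
       earliest spike whose causal grid bin (ceil to the ms grid) is at or
       after ``t_c``, i.e. a spike later than ``t_c - 1`` — that also lies
       at or after the window start and no later than ``t_peak``; None if
       no spike qualifies.  Spikes in bin ``t_c`` are included because
       they are the earliest possible contributors to the suprathreshold
       rise (the kernel is strictly causal).
    """
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("empty latency search window")
    i0 = trace.index_of(w0)
    i1 = trace.index_of(w1)
    if i0 < 0 or i1 > len(trace.rate):
        raise ValueError("trace does not cover the latency search window")
    seg = trace.rate[i0:i1]
    if seg.size == 0:
        raise ValueError("empty latency search window")
    peak = seg.max()
    if peak < threshold:
        return None
    ip = i0 + int(np.argmax(seg))  # earliest peak time (tie-break)
    m = int(min_subthreshold_ms)
    below = trace.rate < threshold
    t_c_idx = None
    for j in range(ip - 1, m - 2, -1):
        if below[j - m + 1:j + 1].all():
            t_c_idx = j
            break
    if t_c_idx is None:
        return None
    t_c = trace.t_start + t_c_idx
    t_peak = trace.t_start + ip
    spikes = np.asarray(spike_times, dtype=float)
    cand = spikes[(spikes > t_c - 1) & (spikes >= w0) & (spikes <= t_peak)]
    if cand.size == 0:
        return None
    return float(cand.min())


def burst_strength(spike_times: np.ndarray, strength_window: tuple[float, float],
                   baseline_mean_count: float) -> float:
    """Baseline-subtracted spike count in the visual-response epoch.

    Counts spikes in the half-open window [start, end) and subtracts the
    across-trial mean baseline count; may be negative.
    """
    w0, w1 = strength_window
    if w1 <= w0:
        raise ValueError("malformed strength window")
    spikes = np.asarray(spike_times, dtype=float)
    count = int(np.count_nonzero((spikes >= w0) & (spikes < w1)))
    return count - float(baseline_mean_count)


def prestim_state(spike_times: np.ndarray,
                  window: tuple[float, float] = BASELINE_WINDOW_MS) -> int:
    """Spike count in the final 50 ms before stimulus onset ([-50, 0))."""
    spikes = np.asarray(spike_times, dtype=float)
    return int(np.count_nonzero((spikes >= window[0]) & (spikes < window[1])))


def latency_inclusion(detected: np.ndarray,
                      min_fraction: float = DEFAULT_INCLUSION_FRACTION) -> bool:
    """Whether a neuron/condition enters latency analyses.

    ``detected`` is a boolean per-trial vector; the neuron is included iff
    the detected fraction is at least ``min_fraction`` (default 60%).
    """
    d = np.asarray(detected, dtype=bool)
    if d.size == 0:
        raise ValueError("need at least one trial")
    return bool(d.mean() >= min_fraction)


def _baseline_count(spikes: np.ndarray, window=BASELINE_WINDOW_MS) -> int:
    return int(np.count_nonzero((spikes >= window[0]) & (spikes < window[1])))


def compute_feature_table(bundle: SessionBundle, kernel: Kernel | None = None,
                          area: str | None = None) -> pd.DataFrame:
    """Extract per-trial burst features for every neuron x condition of a session.

    For each neuron and condition (contrast x polarity): estimate per-trial
    rate traces with the causal kernel, derive the detection threshold from
    the condition's pre-stimulus rates, detect per-trial onset latencies,
    count baseline-subtracted strengths and pre-stimulus spikes, and flag
    per-condition latency inclusion.

    Returns a frame with one row per neuron x trial:
    neuron_id, trial_id, contrast, polarity, latency_ms (NaN when
    undetected), strength, prestim_count, detected, included_latency.
    """
    if kernel is None:
        kernel = build_kernel()
    area = area or (bundle.neurons["area"].iloc[0] if len(bundle.neurons) else "SC")
    g0, g1 = TRIAL_WINDOW_MS
    contrasts = sorted(bundle.trials["contrast"].unique())
    trials = bundle.trials.set_index("trial_id")
    rows = []
    spikes_by_neuron = dict(tuple(bundle.spikes.groupby("neuron_id")))
    prestim_dur_s = (BASELINE_WINDOW_MS[1] - BASELINE_WINDOW_MS[0]) / 1000.0

    for neuron_id in bundle.neurons["neuron_id"]:
        nspk = spikes_by_neuron.get(neuron_id)
        by_trial = (dict(tuple(nspk.groupby("trial_id")))
                    if nspk is not None else {})
        for (contrast, polarity), cond in bundle.trials.groupby(
                ["contrast", "polarity"], sort=True):
            cfg = EpochConfig.default(area, contrast_group_of(contrast, contrasts))
            tids = cond["trial_id"].to_numpy()
            spk = [by_trial[t]["spike_time_ms"].to_numpy()
                   if t in by_trial else np.empty(0)
                   for t in tids]
            pre_counts = np.array([_baseline_count(s) for s in spk], float)
            theta = detection_threshold(pre_counts / prestim_dur_s)
            base_mean = pre_counts.mean()
            lat, det = [], []
            for t_id, s in zip(tids, spk):
                trace = estimate_rate(s, kernel, g0, g1,
                                      trial_id=int(t_id), neuron_id=int(neuron_id))
                val = detect_latency(trace, s, theta, cfg.latency_search_window)
                lat.append(np.nan if val is None else val)
                det.append(val is not None)
            included = latency_inclusion(np.array(det))
            for t_id, s, lv, dv, pc in zip(tids, spk, lat, det, pre_counts):
                rows.append({
                    "neuron_id": int(neuron_id),
                    "trial_id": int(t_id),
                    "contrast": contrast,
                    "polarity": polarity,
                    "latency_ms": lv,
                    "strength": burst_strength(s, cfg.strength_window, base_mean),
                    "prestim_count": int(pc),
                    "detected": dv,
                    "included_latency": included,
                })
    out = pd.DataFrame(rows)
    if len(out):
        out["reaction_time_ms"] = trials.loc[
            out["trial_id"], "reaction_time_ms"].to_numpy()
    return out
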