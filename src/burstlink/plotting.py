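"""Report figures for synthetic-run summaries."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_raster", "plot_fastslow", "plot_vmi_curve"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_raster(bundle, neuron_id: int, ax=None):
    """Spike raster of one neuron, trials ordered by reaction time."""
    ax = _get_ax(ax)
    spk = bundle.spikes[bundle.spikes["neuron_id"] == neuron_id]
    order = bundle.trials.sort_values("reaction_time_ms")
    for row, (_, trial) in enumerate(order.iterrows()):
        t = spk.loc[spk["trial_id"] == trial["trial_id"], "spike_time_ms"]
        ax.plot(t, np.full(len(t), row), "|", color="k", ms=3)
        ax.plot(trial["saccade_onset_ms"], row, ".", color="m", ms=4)
    ax.axvline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("time from stimulus onset (ms)")
    ax.set_ylabel("trial (sorted by RT)")
    return ax


def plot_fastslow(summary: dict, ax=None):
    """Population fast/slow-third normalised traces with SEM bands."""
    ax = _get_ax(ax)
    t = summary["times"]
    for key, color, label in (("fast", "tab:blue", "fastest third"),
                              ("slow", "tab:red", "slowest third")):
        m, s = summary[f"{key}_mean"], summary[f"{key}_sem"]
        ax.plot(t, m, color=color, label=label)
        ax.fill_between(t, m - s, m + s, color=color, alpha=0.25, lw=0)
    ax.axvline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("time from stimulus onset (ms)")
    ax.set_ylabel("normalised firing rate")
    ax.legend(frameon=False)
    return ax


def plot_vmi_curve(binned, ax=None):
    """Sliding-bin mean correlation along the visuomotor-index axis."""
    ax = _get_ax(ax)
    filled = binned[binned["n"] > 0]
    ax.errorbar(filled["bin_center"], filled["mean"], yerr=filled["sem"],
                fmt="o-", ms=3, lw=1, capsize=2, color="k")
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("visuomotor index (VMI)")
    ax.set_ylabel("mean correlation with RT")
    return ax
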