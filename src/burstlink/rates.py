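"""Single-trial firing-rate estimation with a causal (asymmetric) kernel.

Spike trains are convolved with a rise-decay kernel that carries no mass at
negative lags, so a response onset can never be smeared earlier in time than
the first spike that produced it.  All rate traces live on a uniform 1 ms
grid of times relative to stimulus onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Kernel", "RateTrace", "build_kernel", "estimate_rate"]

GRID_STEP_MS = 1.0


@dataclass(frozen=True)
class Kernel:
    """Causal rise-decay smoothing kernel on a 1 ms lag grid.

    Attributes
    ----------
    tau_rise, tau_decay : float
        Rise and decay time constants in ms.
    weights : ndarray
        Unit-area weights at lags 0, 1, 2, ... ms.  Weights at negative
        lags are identically zero by construction (strict causality).
    """

    tau_rise: float
    tau_decay: float
    weights: np.ndarray = field(repr=False)

    @property
    def support_length(self) -> int:
        """Kernel support in ms (number of non-negative lags retained)."""
        return len(self.weights)


def build_kernel(tau_rise: float = 1.0, tau_decay: float = 20.0,
                 mass_retained: float = 0.999) -> Kernel:
    """Build a causal rise-decay kernel k(tau) ~ (1 - e^(-tau/tau_rise)) e^(-tau/tau_decay).

    The kernel is evaluated on integer-ms lags tau >= 0, truncated once the
    retained mass exceeds ``mass_retained`` of the total, and renormalised
    to unit area so that convolution preserves spike count.

    Parameters
    ----------
    tau_rise, tau_decay : float
        Time constants in ms; must be strictly positive.

    Raises
    ------
    ValueError
        If either time constant is not strictly positive.
    """
    if not (np.isfinite(tau_rise) and tau_rise > 0):
        raise ValueError(f"tau_rise must be > 0, got {tau_rise}")
    if not (np.isfinite(tau_decay) and tau_decay > 0):
        raise ValueError(f"tau_decay must be > 0, got {tau_decay}")
    # generous upper bound on the support before truncation
    n = int(np.ceil(20.0 * tau_decay + 10.0 * tau_rise)) + 2
    # weight of lag bin j is the exact integral of the continuous kernel
    # over [j, j+1) ms: int (1 - e^(-t/a)) e^(-t/b) dt
    #   = b e^(-t/b) - c e^(-t/c) evaluated at bin edges, c = ab/(a+b)
    a, b = tau_rise, tau_decay
    c = a * b / (a + b)
    edges = np.arange(n + 1, dtype=float)
    anti = -b * np.exp(-edges / b) + c * np.exp(-edges / c)
    w = np.diff(anti)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate kernel (no mass)")
    cum = np.cumsum(w) / total
    cut = int(np.searchsorted(cum, mass_retained)) + 1
    w = w[:cut]
    w = w / w.sum()
    return Kernel(tau_rise=tau_rise, tau_decay=tau_decay, weights=w)


@dataclass
class RateTrace:
    """Per-trial firing rate (spikes/s) on a uniform 1 ms time grid.

    ``rate[i]`` is the rate at time ``t_start + i`` ms relative to stimulus
    onset.
    """

    t_start: float
    rate: np.ndarray
    trial_id: int | None = None
    neuron_id: int | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(len(self.rate), dtype=float)

    def at(self, t: float) -> float:
        """Rate at grid time ``t`` (must lie on the grid)."""
        i = int(round(t - self.t_start))
        if not (0 <= i < len(self.rate)):
            raise IndexError(f"time {t} outside trace grid")
        return float(self.rate[i])

    def index_of(self, t: float) -> int:
        return int(round(t - self.t_start))


def estimate_rate(spike_times: np.ndarray, kernel: Kernel,
                  grid_start: float, grid_stop: float,
                  trial_id: int | None = None,
                  neuron_id: int | None = None) -> RateTrace:
    """Estimate the single-trial firing rate by causal-kernel convolution.

    Each spike is binned to the 1 ms grid point at or immediately after it
    (ceil), so that a spike can never raise the rate at any grid time
    strictly before its own occurrence, and contributes
    ``kernel.weights * 1000`` spikes/s at non-negative lags.  An empty
    spike list yields the all-zero trace.  Spikes before the grid still
    contribute to in-grid lags when within kernel support; spikes after
    ``grid_stop`` cannot influence the trace and trigger a warning.

    Parameters
    ----------
    spike_times : array-like
        Spike times in ms relative to stimulus onset (any order).
    grid_start, grid_stop : float
        Trace covers integer-ms times in [grid_start, grid_stop).
    """
    g0 = int(np.floor(grid_start))
    g1 = int(np.ceil(grid_stop))
    n = g1 - g0
    if n <= 0:
        raise ValueError("empty grid")
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    rate = np.zeros(n, dtype=float)
    if spikes.size == 0:
        return RateTrace(t_start=float(g0), rate=rate,
                         trial_id=trial_id, neuron_id=neuron_id)
    if np.any(spikes >= g1):
        warnings.warn("spikes at or after grid end do not influence the trace",
                      stacklevel=2)
    support = kernel.support_length
    # bin spikes (ceil) to grid indices; keep those whose kernel support
    # overlaps the grid
    idx = np.ceil(spikes).astype(int) - g0
    keep = (idx > -support) & (idx < n)
    idx = idx[keep]
    if idx.size:
        lo = idx.min()
        counts = np.bincount(idx - lo, minlength=n - lo)
        conv = np.convolve(counts, kernel.weights)
        # conv index j corresponds to grid index lo + j
        j0 = max(0, -lo)
        j1 = min(len(conv), n - lo)
        rate[lo + j0:lo + j1] = conv[j0:j1] * 1000.0
    return RateTrace(t_start=float(g0), rate=rate,
                     trial_id=trial_id, neuron_id=neuron_id)
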