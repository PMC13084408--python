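"""Current-source-density analysis of laminar LFPs.

The CSD is the (negated) second spatial difference of the trial-averaged,
stimulus-aligned LFP across uniformly spaced channels; current sinks are
negative.  The input layer is the interior channel with the most negative
mean CSD in the 0-100 ms post-stimulus period, and channels are split into
superficial and deep groups around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["CsdProfile", "csd_from_lfp", "lfp_preprocess"]


@dataclass
class CsdProfile:
    """CSD values on interior channels with the input-layer assignment.

    ``csd`` has shape (n_channels - 2, n_time): row ``i`` is channel
    ``i + 1`` of the LFP array (edge channels have no second difference).
    ``layer_map[ch]`` is "superficial", "input" or "deep"; channel 0 is
    the most superficial.
    """

    csd: np.ndarray
    input_channel: int
    layer_map: dict[int, str]
    spacing_um: float
    t_start_ms: float

    def mean_sink_profile(self, t0: float = 0.0, t1: float = 100.0) -> np.ndarray:
        i0 = int(t0 - self.t_start_ms)
        i1 = int(t1 - self.t_start_ms)
        return self.csd[:, i0:i1].mean(axis=1)


def csd_from_lfp(lfp: np.ndarray, spacing_um: float,
                 t_start_ms: float = 0.0, fs_hz: float = 1000.0,
                 sink_window_ms: tuple[float, float] = (0.0, 100.0),
                 adjacency_max_spacing_um: float = 50.0) -> CsdProfile:
    """Estimate the CSD and identify the input layer.

    Parameters
    ----------
    lfp : ndarray
        channel x time (already trial-averaged) or channel x time x trial
        (averaged across trials here), stimulus-aligned.
    spacing_um : float
        Uniform inter-channel spacing.  At spacings up to 50 um the input
        channel plus one neighbour on each side separates superficial from
        deep; at coarser spacings only the input channel itself does.

    The sign convention makes synaptic input (a current sink) negative:
    csd_i = -(phi_{i-1} - 2 phi_i + phi_{i+1}) / spacing^2.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.ndim == 3:
        lfp = lfp.mean(axis=2)
    if lfp.ndim != 2:
        raise ValueError("lfp must be channel x time (x trial)")
    n_ch = lfp.shape[0]
    if n_ch < 3:
        raise ValueError("need at least 3 channels for a second difference")
    if spacing_um <= 0:
        raise ValueError("spacing must be positive and uniform")
    h2 = (spacing_um / 100.0) ** 2
    csd = -(lfp[:-2] - 2.0 * lfp[1:-1] + lfp[2:]) / h2

    dt_ms = 1000.0 / fs_hz
    i0 = int(round((sink_window_ms[0] - t_start_ms) / dt_ms))
    i1 = int(round((sink_window_ms[1] - t_start_ms) / dt_ms))
    i0 = max(i0, 0)
    i1 = min(i1, csd.shape[1])
    if i1 <= i0:
        raise ValueError("sink window outside the LFP time range")
    mean_csd = csd[:, i0:i1].mean(axis=1)
    input_channel = int(np.argmin(mean_csd)) + 1  # interior -> absolute index

    adj = 1 if spacing_um <= adjacency_max_spacing_um else 0
    input_block = {c for c in range(input_channel - adj, input_channel + adj + 1)
                   if 0 <= c < n_ch}
    layer_map = {}
    for c in range(n_ch):
        if c in input_block:
            layer_map[c] = "input"
        elif c < input_channel:
            layer_map[c] = "superficial"
        else:
            layer_map[c] = "deep"
    return CsdProfile(csd=csd, input_channel=input_channel,
                      layer_map=layer_map, spacing_um=spacing_um,
                      t_start_ms=t_start_ms)


def lfp_preprocess(x: np.ndarray, fs_hz: float,
                   band_hz: tuple[float, float] = (0.7, 300.0),
                   lowpass_hz: float | None = 100.0,
                   order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase band filtering of wideband signals to the LFP band.

    A forward-backward (filtfilt) Butterworth band-pass followed by an
    optional further low-pass; filtering introduces no group delay, so a
    filtered impulse peaks at the impulse sample.
    """
    nyq = fs_hz / 2.0
    lo, hi = band_hz
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq}) Hz")
    if lowpass_hz is not None and not (0 < lowpass_hz < nyq):
        raise ValueError(f"low-pass corner {lowpass_hz} beyond Nyquist {nyq} Hz")
    # separate high-pass and low-pass stages: a single band-pass with a
    # sub-Hz lower corner is numerically fragile at kHz sampling rates
    sos_hp = signal.butter(order, lo, btype="highpass", fs=fs_hz, output="sos")
    sos_lo = signal.butter(order, hi, btype="lowpass", fs=fs_hz, output="sos")
    # pad generously relative to the slow high-pass time constant to keep
    # its edge transients out of the analysed interior
    n = np.asarray(x).shape[axis]
    padlen = int(min(n - 1, 3.0 * fs_hz / lo))
    y = signal.sosfiltfilt(sos_hp, x, axis=axis, padlen=padlen)
    y = signal.sosfiltfilt(sos_lo, y, axis=axis)
    if lowpass_hz is not None:
        sos_lp = signal.butter(order, lowpass_hz, btype="lowpass", fs=fs_hz,
                               output="sos")
        y = signal.sosfiltfilt(sos_lp, y, axis=axis)
    return y
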