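"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def brute_force_latency(rate, t_start, spikes, theta, window, run_ms=5):
    """Exhaustive-enumeration latency detector.

    Enumerates every candidate subthreshold-run end time and every spike,
    applying the documented detection contract directly, without any of the
    scanning shortcuts of the package implementation.
    """
    rate = np.asarray(rate, float)
    times = t_start + np.arange(len(rate))
    w0, w1 = window
    in_win = (times >= w0) & (times < w1)
    if not in_win.any():
        raise ValueError("window outside trace")
    peak_val = rate[in_win].max()
    if peak_val < theta:
        return None
    t_peak = times[in_win & (rate == peak_val)].min()  # earliest peak

    candidates = []
    for tc in times:
        if tc >= t_peak:
            continue
        sample_times = [tc - k for k in range(run_ms)]
        if any(st < times[0] for st in sample_times):
            continue
        if all(rate[int(st - t_start)] < theta for st in sample_times):
            candidates.append(tc)
    if not candidates:
        return None
    tc = max(candidates)
    # spikes whose causal grid bin (ceil) falls at or after tc qualify,
    # i.e. spikes later than tc - 1
    eligible = [s for s in np.asarray(spikes, float)
                if s > tc - 1 and s >= w0 and s <= t_peak]
    return float(min(eligible)) if eligible else None


def gamma_glm_irls(y, X, tol=1e-12, maxiter=200):
    """Plain Gamma log-link GLM fit by iteratively reweighted least squares.

    For the log link the IRLS working weights are constant, so this reduces
    to Newton iterations on the quasi-likelihood score; returns the
    coefficient vector (shape-free, since the Gamma score is independent of
    the shape parameter).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.linalg.lstsq(X, np.log(y), rcond=None)[0]
    for _ in range(maxiter):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        beta_new = np.linalg.lstsq(X, z, rcond=None)[0]
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta
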