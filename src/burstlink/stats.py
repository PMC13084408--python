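"""Per-neuron feature-RT correlations and population-level statistics.

Single-neuron effects are quantified with Spearman rank correlations
between a trial-wise burst feature (onset latency, strength, or
pre-stimulus count) and saccadic reaction time.  Population inference uses
non-parametric tests throughout: Wilcoxon signed-rank against zero within
groups, Mann-Whitney U between groups, with Bonferroni correction across
contrast levels.  Also provides across-trial reliability (SD) summaries
and the peak-normalised fastest/slowest-third population traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .features import _STRENGTH_WINDOWS
from .rates import Kernel, build_kernel, estimate_rate
from .simulate import SessionBundle

__all__ = [
    "CorrelationRecord",
    "PopulationSummary",
    "spearman_feature_rt",
    "correlate_features",
    "population_tests",
    "mannwhitney_z",
    "reliability_summary",
    "fastslow_normalized_summary",
]

EXACT_P_MAX_N = 9


@dataclass
class CorrelationRecord:
    rho: float
    p: float
    n_trials: int
    zero_assigned: bool = False


@dataclass
class PopulationSummary:
    """Per-group signed-rank summaries plus optional between-group U tests."""

    groups: pd.DataFrame
    between: pd.DataFrame | None = None


@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """Null distribution of Spearman rho for sample size n (all n! pairings)."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(permutations(range(n))), dtype=np.int16)
    ranks = base[perms]
    # rho = Pearson correlation of the permuted ranks with the identity ranking
    c = base - base.mean()
    rho = ((ranks - base.mean()) * c).sum(axis=1) / (c**2).sum()
    return rho


def spearman_feature_rt(feature: np.ndarray, rt: np.ndarray,
                        zero_convention: bool = False) -> CorrelationRecord | None:
    """Spearman correlation between a trial-wise feature and reaction time.

    Trials with an undefined feature (NaN) are dropped pairwise.  Ties get
    average ranks.  The two-sided p-value is exact (full enumeration of
    pairings) for n <= 9 and uses the t approximation otherwise.

    With ``zero_convention`` (the pre-stimulus feature), a neuron whose
    feature is zero on every trial is assigned rho = 0 with
    ``zero_assigned = True`` instead of being dropped.  Otherwise, fewer
    than 3 paired trials or zero variance in either variable returns None
    (neuron dropped from the analysis).
    """
    feature = np.asarray(feature, dtype=float)
    rt = np.asarray(rt, dtype=float)
    keep = np.isfinite(feature) & np.isfinite(rt)
    x, y = feature[keep], rt[keep]
    if zero_convention and x.size > 0 and np.all(x == 0):
        return CorrelationRecord(rho=0.0, p=np.nan, n_trials=int(x.size),
                                 zero_assigned=True)
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if n <= EXACT_P_MAX_N:
        null = _exact_rho_null(n)
        # exact enumeration is tie-free; with ties it remains the reference
        # permutation distribution of the rank statistic
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return CorrelationRecord(rho=rho, p=p, n_trials=int(n))


def correlate_features(features: pd.DataFrame,
                       feature_names: tuple[str, ...] = ("latency", "strength", "prestim"),
                       ) -> pd.DataFrame:
    """Per-neuron x condition Spearman correlations of each feature with RT.

    Expects the output of :func:`burstlink.features.compute_feature_table`
    (with its ``reaction_time_ms`` column).  Latency correlations are only
    computed for neuron/conditions that met the 60% inclusion rule.
    """
    col = {"latency": "latency_ms", "strength": "strength",
           "prestim": "prestim_count"}
    rows = []
    for (neuron_id, contrast, polarity), g in features.groupby(
            ["neuron_id", "contrast", "polarity"], sort=True):
        rt = g["reaction_time_ms"].to_numpy()
        for feat in feature_names:
            if feat == "latency" and not bool(g["included_latency"].iloc[0]):
                continue
            rec = spearman_feature_rt(g[col[feat]].to_numpy(), rt,
                                      zero_convention=(feat == "prestim"))
            if rec is None:
                continue
            rows.append({
                "neuron_id": neuron_id, "contrast": contrast,
                "polarity": polarity, "feature": feat,
                "rho": rec.rho, "p": rec.p, "n_trials": rec.n_trials,
                "zero_assigned": rec.zero_assigned,
            })
    return pd.DataFrame(rows)


def mannwhitney_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal approximation, no continuity
    correction.  Returns (U, z, two-sided p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    u = float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum() / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 0.0, 1.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return u, float(z), float(p)


def _signed_rank_vs_zero(values: np.ndarray) -> dict:
    """Wilcoxon signed-rank test of a sample against zero.

    Exact zeros are disregarded (reduced-sample procedure); the reported
    effective n counts the non-zero values entering the test.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    nonzero = v[v != 0]
    out = {"n": int(len(v)), "n_effective": int(len(nonzero)),
           "mean": float(v.mean()) if len(v) else np.nan,
           "median": float(np.median(v)) if len(v) else np.nan,
           "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan}
    if len(nonzero) < 1:
        out.update({"W": np.nan, "z": np.nan, "p": np.nan})
        return out
    try:
        res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=False,
                             method="approx")
        out.update({"W": float(res.statistic), "z": float(res.zstatistic),
                    "p": float(res.pvalue)})
    except ValueError:
        out.update({"W": np.nan, "z": np.nan, "p": np.nan})
    return out


def population_tests(records: pd.DataFrame, value_col: str = "rho",
                     group_by: tuple[str, ...] = ("feature", "contrast", "polarity"),
                     between: str | None = None,
                     bonferroni_over: str = "contrast") -> PopulationSummary:
    """Population test battery over per-neuron correlation records.

    Per group: Wilcoxon signed-rank against zero (zeros disregarded,
    effective n reported) with Bonferroni correction across the levels of
    ``bonferroni_over`` (adjusted p = min(1, p x number of levels)).  With
    ``between`` set to a column (e.g. ``area`` after concatenating areas),
    also runs a Mann-Whitney U test between its two levels inside each
    remaining group, Bonferroni-corrected the same way.
    """
    k = records[bonferroni_over].nunique() if bonferroni_over in records else 1
    g_rows = []
    for keys, g in records.groupby(list(group_by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(group_by, keys))
        row.update(_signed_rank_vs_zero(g[value_col].to_numpy()))
        row["p_bonferroni"] = (min(1.0, row["p"] * k)
                               if np.isfinite(row.get("p", np.nan)) else np.nan)
        g_rows.append(row)
    groups = pd.DataFrame(g_rows)

    between_df = None
    if between is not None:
        levels = sorted(records[between].unique())
        if len(levels) != 2:
            raise ValueError(f"'between' column must have 2 levels, got {levels}")
        other = [c for c in group_by if c != between]
        b_rows = []
        grouped = records.groupby(other, sort=True) if other else [((), records)]
        for keys, g in grouped:
            keys = keys if isinstance(keys, tuple) else (keys,)
            a = g.loc[g[between] == levels[0], value_col].to_numpy()
            b = g.loc[g[between] == levels[1], value_col].to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            u, z, p = mannwhitney_z(a, b)
            row = dict(zip(other, keys))
            row.update({"group_a": levels[0], "group_b": levels[1],
                        "n_a": len(a), "n_b": len(b), "U": u, "z": z, "p": p,
                        "p_bonferroni": min(1.0, p * k)})
            b_rows.append(row)
        between_df = pd.DataFrame(b_rows)
    return PopulationSummary(groups=groups, between=between_df)


def reliability_summary(features: pd.DataFrame, value_col: str,
                        group_by: tuple[str, ...] = ("contrast", "polarity"),
                        ) -> pd.DataFrame:
    """Across-trial reliability: per-neuron SD, averaged over neurons.

    For each neuron (within each group) the sample SD of ``value_col``
    across trials is taken over its defined values (>= 2 required); the
    population summary is the mean and SEM of those SDs across neurons.
    """
    rows = []
    for keys, g in features.groupby(list(group_by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        sds = []
        for _, ng in g.groupby("neuron_id"):
            v = ng[value_col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size >= 2:
                sds.append(v.std(ddof=1))
        sds = np.asarray(sds)
        row = dict(zip(group_by, keys))
        row.update({
            "mean_sd": sds.mean() if sds.size else np.nan,
            "sem_sd": (sds.std(ddof=1) / np.sqrt(sds.size)
                       if sds.size > 1 else np.nan),
            "n_neurons": int(sds.size),
        })
        rows.append(row)
    return pd.DataFrame(rows)


def fastslow_normalized_summary(bundle: SessionBundle, kernel: Kernel | None = None,
                                area: str | None = None,
                                t_range: tuple[float, float] = (-100.0, 300.0),
                                ) -> dict:
    """Peak-normalised population traces for the fastest and slowest RT thirds.

    Each neuron's trial-averaged kernel rate trace is normalised to its
    peak inside the area's visual epoch (neurons with zero peak dropped);
    trials are split into the fastest and slowest floor(n/3) by reaction
    time (stable sort, ties by trial order).  Returns the across-neuron
    mean and SEM of the normalised fast- and slow-third traces.
    """
    if kernel is None:
        kernel = build_kernel()
    area = area or (bundle.neurons["area"].iloc[0] if len(bundle.neurons) else "SC")
    lo = _STRENGTH_WINDOWS[(area, "high")]
    hi = _STRENGTH_WINDOWS[(area, "low")]
    vis_win = (min(lo[0], hi[0]), max(lo[1], hi[1]))  # union visual epoch
    g0, g1 = t_range
    n_t = int(g1 - g0)
    times = g0 + np.arange(n_t)

    tids = bundle.trials["trial_id"].to_numpy()
    rt = bundle.trials["reaction_time_ms"].to_numpy()
    order = np.argsort(rt, kind="stable")
    third = len(tids) // 3
    if third < 2:
        raise ValueError("need at least 6 trials for a fast/slow-third split")
    fast_ids = set(tids[order[:third]])
    slow_ids = set(tids[order[-third:]])

    fast_traces, slow_traces = [], []
    spikes_by_neuron = dict(tuple(bundle.spikes.groupby("neuron_id")))
    for neuron_id in bundle.neurons["neuron_id"]:
        nspk = spikes_by_neuron.get(neuron_id)
        by_trial = dict(tuple(nspk.groupby("trial_id"))) if nspk is not None else {}
        trains = [by_trial[t]["spike_time_ms"].to_numpy()
                  if t in by_trial else np.empty(0) for t in tids]
        traces = np.stack([
            estimate_rate(s[s < g1], kernel, g0, g1).rate for s in trains])
        avg = traces.mean(axis=0)
        j0, j1 = int(vis_win[0] - g0), int(vis_win[1] - g0)
        peak = avg[j0:j1].max()
        if peak <= 0:
            continue
        norm = traces / peak
        in_fast = np.array([t in fast_ids for t in tids])
        in_slow = np.array([t in slow_ids for t in tids])
        fast_traces.append(norm[in_fast].mean(axis=0))
        slow_traces.append(norm[in_slow].mean(axis=0))

    fast = np.stack(fast_traces) if fast_traces else np.empty((0, n_t))
    slow = np.stack(slow_traces) if slow_traces else np.empty((0, n_t))

    def _sem(x):
        return (x.std(axis=0, ddof=1) / np.sqrt(len(x))
                if len(x) > 1 else np.full(n_t, np.nan))

    return {
        "times": times,
        "fast_mean": fast.mean(axis=0) if len(fast) else np.full(n_t, np.nan),
        "fast_sem": _sem(fast),
        "slow_mean": slow.mean(axis=0) if len(slow) else np.full(n_t, np.nan),
        "slow_sem": _sem(slow),
        "n_neurons": len(fast),
    }
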