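"""End-to-end analysis pipeline: simulate -> rates -> features -> classify
-> correlate -> glmm -> laminar/waveforms -> report.

Stages read and write the text tables documented in :mod:`burstlink.io`;
a run is configured by a :class:`RunConfig` (optionally loaded from YAML),
persists its configuration verbatim into the output directory, and is
fully deterministic given the config (including its seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .classify import profile_neurons
from .features import compute_feature_table
from .glmm import GammaMixedModel
from .laminar import csd_from_lfp
from .rates import build_kernel
from .simulate import SimConfig, generate_session
from .stats import correlate_features, population_tests, reliability_summary
from .waveforms import waveform_width_class

__all__ = ["RunConfig", "run_pipeline", "validate_tables"]

logger = logging.getLogger("burstlink")

ALL_STAGES = ("simulate", "features", "classify", "correlate", "glmm",
              "laminar", "waveforms", "report")

_STAGE_INPUTS = {
    "simulate": (),
    "features": ("trials.tsv", "spikes.tsv", "neurons.tsv"),
    "classify": ("trials.tsv", "spikes.tsv", "neurons.tsv"),
    "correlate": ("features.tsv",),
    "glmm": ("features.tsv",),
    "laminar": ("lfp.npy", "lfp_meta.yaml"),
    "waveforms": ("waveforms.tsv",),
    "report": (),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    area: str = "SC"
    sim: dict = field(default_factory=dict)       # SimConfig overrides
    kernel_tau_rise: float = 1.0
    kernel_tau_decay: float = 20.0
    alpha: float = 0.05
    glmm_min_neurons: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        d = self.__dict__.copy()
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d))


def _sim_config(cfg: RunConfig) -> SimConfig:
    overrides = dict(cfg.sim)
    overrides.setdefault("seed", cfg.seed)
    if cfg.area == "V1":
        overrides.setdefault("include_lfp", True)
        overrides.setdefault("include_waveforms", True)
        return SimConfig.v1_like(**overrides)
    return SimConfig.sc_like(**overrides)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the machine-readable report.

    Each stage checks that its declared input tables exist (a missing
    upstream table raises a named-stage error) and writes its outputs into
    ``config.out_dir``.  The run report is also written as
    ``report.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"seed": config.seed, "area": config.area,
                    "stages": list(config.stages)}
    kernel = build_kernel(config.kernel_tau_rise, config.kernel_tau_decay)
    try:
        for stage in config.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            missing = [f for f in _STAGE_INPUTS[stage] if not (out / f).exists()]
            if missing:
                raise FileNotFoundError(
                    f"stage {stage!r}: missing upstream inputs {missing}")
            logger.info("running stage %s", stage)

            if stage == "simulate":
                bundle = generate_session(_sim_config(config))
                bio.write_session(bundle, out)
            elif stage == "features":
                bundle = bio.read_session(out)
                feats = compute_feature_table(bundle, kernel=kernel,
                                              area=config.area)
                bio.write_table(feats, out / "features.tsv")
            elif stage == "classify":
                bundle = bio.read_session(out)
                prof = profile_neurons(bundle, alpha=config.alpha)
                bio.write_table(prof, out / "neurons_profile.tsv")
                report["class_counts"] = (
                    prof["label"].value_counts().to_dict())
            elif stage == "correlate":
                feats = bio.read_table(out / "features.tsv")
                recs = correlate_features(feats)
                bio.write_table(recs, out / "correlations.tsv")
                summ = population_tests(recs)
                bio.write_table(summ.groups, out / "population_summary.tsv")
                rel = reliability_summary(feats, "latency_ms")
                bio.write_table(rel, out / "reliability_latency.tsv")
                report["mean_rho"] = {
                    feat: float(g["rho"].mean())
                    for feat, g in recs.groupby("feature")}
            elif stage == "glmm":
                feats = bio.read_table(out / "features.tsv")
                terms = {}
                for pol, g in feats.groupby("polarity"):
                    g = g[np.isfinite(g["latency_ms"])]
                    if (g["neuron_id"].nunique() < config.glmm_min_neurons
                            or len(g) < 10 or g["contrast"].nunique() < 2):
                        logger.warning("glmm: skipping polarity %s (too little data)",
                                       pol)
                        continue
                    model = GammaMixedModel.from_dataframe(g)
                    res = model.fit()
                    fit_df = pd.DataFrame({
                        "term": model.exog_names, "beta": res.params,
                        "se": res.bse, "z": res.zvalues, "p": res.pvalues})
                    fit_df["polarity"] = pol
                    dels = pd.DataFrame([res.single_term_deletion(t)
                                         for t in ("latency", "strength",
                                                   "contrast")])
                    dels["polarity"] = pol
                    mode = "a" if (out / "glmm_fit.tsv").exists() and terms else "w"
                    fit_df.to_csv(out / "glmm_fit.tsv", sep="\t", index=False,
                                  mode=mode, header=(mode == "w"))
                    dels.to_csv(out / "glmm_deletions.tsv", sep="\t", index=False,
                                mode=mode, header=(mode == "w"))
                    terms[pol] = {
                        "aic": res.aic,
                        "beta": dict(zip(model.exog_names,
                                         map(float, res.params))),
                    }
                report["glmm"] = terms
            elif stage == "laminar":
                meta = yaml.safe_load((out / "lfp_meta.yaml").read_text())
                lfp = np.load(out / "lfp.npy")
                prof = csd_from_lfp(lfp, spacing_um=meta["spacing_um"],
                                    t_start_ms=meta.get("t_start_ms", 0.0),
                                    fs_hz=meta.get("fs_hz", 1000.0))
                rows = [{"channel": c, "layer": prof.layer_map[c],
                         "mean_csd_0_100": (prof.mean_sink_profile()[c - 1]
                                            if 0 < c < lfp.shape[0] - 1
                                            else np.nan)}
                        for c in range(lfp.shape[0])]
                bio.write_table(pd.DataFrame(rows), out / "csd_profile.tsv")
                report["input_channel"] = prof.input_channel
            elif stage == "waveforms":
                wf = bio.read_table(out / "waveforms.tsv")
                meta = yaml.safe_load((out / "waveforms_meta.yaml").read_text())
                rows = []
                for nid, g in wf.groupby("neuron_id"):
                    w = g.sort_values("sample_index")["amplitude"].to_numpy()
                    m = waveform_width_class(w, meta["sampling_period_us"])
                    rows.append({"neuron_id": int(nid),
                                 "trough_to_peak_us": m.trough_to_peak,
                                 "class": m.cls})
                df = pd.DataFrame(rows)
                bio.write_table(df, out / "waveform_metrics.tsv")
                report["waveform_classes"] = df["class"].value_counts().to_dict()
            elif stage == "report":
                (out / "report.json").write_text(
                    json.dumps(report, indent=2, sort_keys=True, default=float))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report


def validate_tables(in_dir: str | Path) -> pd.DataFrame:
    """Schema and invariant checks on all tables of a run directory.

    Returns a frame (file, check, passed, detail); unreadable or missing
    files are listed as failures rather than aborting.
    """
    d = Path(in_dir)
    rows = []

    def check(fname, name, passed, detail=""):
        rows.append({"file": fname, "check": name, "passed": bool(passed),
                     "detail": detail})

    tables = {}
    for fname in ("trials.tsv", "spikes.tsv", "neurons.tsv", "features.tsv"):
        path = d / fname
        if not path.exists():
            if fname in bio._REQUIRED:
                check(fname, "exists", False, "missing")
            continue
        try:
            tables[fname] = bio.read_table(path)
            check(fname, "readable", True)
        except Exception as exc:  # noqa: BLE001 - report, do not abort
            check(fname, "readable", False, str(exc))

    for fname, cols in bio._REQUIRED.items():
        if fname in tables:
            missing = [c for c in cols if c not in tables[fname].columns]
            check(fname, "schema", not missing, f"missing {missing}" if missing else "")

    if "trials.tsv" in tables:
        t = tables["trials.tsv"]
        bad = t.index[t["reaction_time_ms"] <= 0].tolist()
        check("trials.tsv", "reaction_time_positive", not bad,
              f"rows {bad[:10]}" if bad else "")
    if "spikes.tsv" in tables and "trials.tsv" in tables:
        s, t = tables["spikes.tsv"], tables["trials.tsv"]
        orphan = ~s["trial_id"].isin(t["trial_id"])
        check("spikes.tsv", "trial_foreign_key", not orphan.any(),
              f"rows {s.index[orphan][:10].tolist()}" if orphan.any() else "")
    if "spikes.tsv" in tables and "neurons.tsv" in tables:
        s, n = tables["spikes.tsv"], tables["neurons.tsv"]
        orphan = ~s["neuron_id"].isin(n["neuron_id"])
        check("spikes.tsv", "neuron_foreign_key", not orphan.any(),
              f"rows {s.index[orphan][:10].tolist()}" if orphan.any() else "")
    return pd.DataFrame(rows)
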