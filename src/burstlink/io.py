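"""Delimited-text serialization of session bundles and analysis tables.

Schema (all times ms, stimulus onset = 0; tab-separated, header row):

* ``trials.tsv``: trial_id, contrast, polarity, reaction_time_ms, saccade_onset_ms
* ``spikes.tsv``: neuron_id, trial_id, spike_time_ms
* ``neurons.tsv``: neuron_id, area, ground-truth columns when simulated
* ``delayed_trials.tsv`` / ``delayed_spikes.tsv``: optional delayed-task block
* ``waveforms.tsv``: neuron_id, sample_index, amplitude (+ sampling period
  in ``waveforms_meta.yaml``)
* ``lfp.npy`` + ``lfp_meta.yaml``: optional channel x time x trial array
  with channel spacing, sampling rate and alignment in the text sidecar
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SessionBundle, SimConfig

__all__ = ["write_session", "read_session", "write_table", "read_table",
           "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_REQUIRED = {
    "trials.tsv": ["trial_id", "contrast", "polarity", "reaction_time_ms",
                   "saccade_onset_ms"],
    "spikes.tsv": ["neuron_id", "trial_id", "spike_time_ms"],
    "neurons.tsv": ["neuron_id", "area"],
}


def write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_session(bundle: SessionBundle, out_dir: str | Path) -> Path:
    """Write a session bundle to a directory of text tables (plus optional
    binary LFP with a text sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(bundle.trials, out / "trials.tsv")
    write_table(bundle.spikes, out / "spikes.tsv")
    write_table(bundle.neurons, out / "neurons.tsv")
    if bundle.delayed_trials is not None:
        write_table(bundle.delayed_trials, out / "delayed_trials.tsv")
    if bundle.delayed_spikes is not None:
        write_table(bundle.delayed_spikes, out / "delayed_spikes.tsv")
    if bundle.waveforms is not None:
        rows = []
        for nid, w in bundle.waveforms.items():
            for j, a in enumerate(np.asarray(w)):
                rows.append((nid, j, a))
        write_table(pd.DataFrame(rows, columns=["neuron_id", "sample_index",
                                                "amplitude"]),
                    out / "waveforms.tsv")
        (out / "waveforms_meta.yaml").write_text(yaml.safe_dump(
            {"sampling_period_us": float(bundle.waveform_sampling_us),
             "schema_version": SCHEMA_VERSION}))
    if bundle.lfp is not None:
        np.save(out / "lfp.npy", bundle.lfp)
        meta = dict(bundle.lfp_meta or {})
        meta.update({"n_channels": int(bundle.lfp.shape[0]),
                     "schema_version": SCHEMA_VERSION})
        (out / "lfp_meta.yaml").write_text(yaml.safe_dump(meta))
    if bundle.config is not None:
        cfg = asdict(bundle.config)
        cfg["schema_version"] = SCHEMA_VERSION
        (out / "sim_config.yaml").write_text(yaml.safe_dump(cfg))
    return out


def read_session(in_dir: str | Path) -> SessionBundle:
    """Load a session bundle from a directory written by :func:`write_session`
    (or hand-assembled to the same schema)."""
    d = Path(in_dir)
    for fname, cols in _REQUIRED.items():
        if not (d / fname).exists():
            raise FileNotFoundError(f"missing required table {fname} in {d}")
    trials = read_table(d / "trials.tsv")
    spikes = read_table(d / "spikes.tsv")
    neurons = read_table(d / "neurons.tsv")
    for fname, cols in _REQUIRED.items():
        df = {"trials.tsv": trials, "spikes.tsv": spikes,
              "neurons.tsv": neurons}[fname]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{fname} lacks columns {missing}")
    bundle = SessionBundle(trials=trials, spikes=spikes, neurons=neurons)
    if (d / "delayed_trials.tsv").exists():
        bundle.delayed_trials = read_table(d / "delayed_trials.tsv")
    if (d / "delayed_spikes.tsv").exists():
        bundle.delayed_spikes = read_table(d / "delayed_spikes.tsv")
    if (d / "waveforms.tsv").exists():
        wf = read_table(d / "waveforms.tsv")
        bundle.waveforms = {
            int(nid): g.sort_values("sample_index")["amplitude"].to_numpy()
            for nid, g in wf.groupby("neuron_id")}
        if (d / "waveforms_meta.yaml").exists():
            meta = yaml.safe_load((d / "waveforms_meta.yaml").read_text())
            bundle.waveform_sampling_us = float(meta["sampling_period_us"])
    if (d / "lfp.npy").exists():
        bundle.lfp = np.load(d / "lfp.npy")
        if (d / "lfp_meta.yaml").exists():
            bundle.lfp_meta = yaml.safe_load((d / "lfp_meta.yaml").read_text())
    if (d / "sim_config.yaml").exists():
        cfg = yaml.safe_load((d / "sim_config.yaml").read_text())
        cfg.pop("schema_version", None)
        for key in ("burst_amp_mean", "burst_latency_mean"):
            cfg[key] = {int(k): float(v) for k, v in cfg[key].items()}
        for key in ("contrasts", "polarities"):
            cfg[key] = tuple(cfg[key])
        bundle.config = SimConfig(**cfg)
    return bundle
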