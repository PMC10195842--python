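"""Artifact serialization.

Spike events and PSTHs travel as delimited text; weight matrices and input
traces go into an HDF5 container with a schema-version attribute and
weight matrices stored as (row, col, value) triplets.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .analysis import PSTHMatrix
from .network import SpikeData, InputTrace, PlasticConnectivity
from .params import PopulationLayout

SCHEMA_VERSION = "1"

__all__ = [
    "write_spikes", "read_spikes", "write_psth", "read_psth",
    "write_targets", "read_targets", "write_diagnostics",
    "write_snapshot", "read_snapshot_weights", "file_sha256",
    "write_manifest",
]


def write_spikes(spikes: SpikeData, path: str | Path) -> None:
    """Delimited spike events, deterministically ordered by
    (trial, time, neuron)."""
    order = np.lexsort((spikes.neuron, spikes.time_ms, spikes.trial))
    df = pd.DataFrame({"trial": spikes.trial[order],
                       "neuron": spikes.neuron[order],
                       "time_ms": spikes.time_ms[order]})
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={spikes.duration_ms} "
                 f"n_trials={spikes.n_trials} n_neurons={spikes.n_neurons}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_spikes(path: str | Path) -> SpikeData:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        df = pd.read_csv(fh, sep="\t")
    return SpikeData(trial=df["trial"].to_numpy(np.int32),
                     neuron=df["neuron"].to_numpy(np.int64),
                     time_ms=df["time_ms"].to_numpy(float),
                     duration_ms=float(meta["duration_ms"]),
                     n_trials=int(meta["n_trials"]),
                     n_neurons=int(meta["n_neurons"]))


def write_psth(psth: PSTHMatrix, path: str | Path) -> None:
    """Delimited PSTH table: first column neuron id, remaining columns the
    bins labeled by bin-center time in ms."""
    t = psth.time_axis()
    cols = [f"{x:.1f}" for x in t]
    ids = psth.neuron_ids if len(psth.neuron_ids) else \
        np.arange(psth.n_neurons)
    df = pd.DataFrame(psth.rates.T, columns=cols)
    df.insert(0, "neuron", ids)
    with open(path, "w") as fh:
        fh.write(f"# bin_ms={psth.bin_ms} smooth_ms={psth.smooth_ms} "
                 f"t0_ms={psth.t0_ms}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_psth(path: str | Path) -> PSTHMatrix:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        df = pd.read_csv(fh, sep="\t")
    ids = df["neuron"].to_numpy()
    rates = df.drop(columns="neuron").to_numpy(float).T
    return PSTHMatrix(rates=rates, bin_ms=float(meta["bin_ms"]),
                      smooth_ms=float(meta["smooth_ms"]),
                      t0_ms=float(meta["t0_ms"]), neuron_ids=ids)


def write_targets(tset, path: str | Path) -> None:
    """Target-input table: first column the assigned model-neuron id,
    remaining columns the bins labeled by bin-center time in ms."""
    t = tset.time_axis()
    df = pd.DataFrame(tset.f, columns=[f"{x:.1f}" for x in t])
    df.insert(0, "neuron", tset.neuron_ids)
    with open(path, "w") as fh:
        fh.write(f"# t_target_ms={tset.t_target_ms}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_targets(path: str | Path):
    from .targets import TargetSet

    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        df = pd.read_csv(fh, sep="\t")
    return TargetSet(f=df.drop(columns="neuron").to_numpy(float),
                     t_target_ms=float(meta["t_target_ms"]),
                     neuron_ids=df["neuron"].to_numpy())


def write_diagnostics(diag, path: str | Path) -> None:
    """Per-iteration training diagnostics as delimited text."""
    df = pd.DataFrame({
        "iteration": np.arange(len(diag.mean_abs_error)),
        "trial_type": diag.trial_types,
        "mean_abs_error": diag.mean_abs_error,
        "rowsum_drift_E": diag.rowsum_drift[:, 0],
        "rowsum_drift_I": diag.rowsum_drift[:, 1],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_snapshot(path: str | Path, *, plastic: PlasticConnectivity = None,
                   trace: InputTrace = None, extra: dict = None) -> None:
    """Hierarchical snapshot of trained weights and/or recorded traces."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if plastic is not None:
            g = f.create_group("plastic")
            rows = np.repeat(plastic.trained, plastic.l_rec)
            cols = plastic.pre_idx.ravel()
            vals = plastic.w[:, :plastic.l_rec].ravel()
            g.create_dataset("row", data=rows)
            g.create_dataset("col", data=cols)
            g.create_dataset("value", data=vals)
            g.create_dataset("w_ffwd", data=plastic.w[:, plastic.l_rec:])
            g.attrs["l_per_pop"] = plastic.l_per_pop
            g.attrs["l_x"] = plastic.l_x
        if trace is not None:
            g = f.create_group("trace")
            g.create_dataset("neuron_ids", data=trace.neuron_ids)
            g.create_dataset("time_ms", data=trace.time_ms)
            g.create_dataset("traces", data=trace.traces)
            g.create_dataset("x_bal", data=trace.x_bal)
        if extra:
            g = f.create_group("extra")
            for k, v in extra.items():
                g.create_dataset(k, data=np.asarray(v))


def read_snapshot_weights(path: str | Path):
    """Return (row, col, value, w_ffwd) triplets of a stored weight set."""
    with h5py.File(path, "r") as f:
        g = f["plastic"]
        return (g["row"][:], g["col"][:], g["value"][:], g["w_ffwd"][:])


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, entries: dict, meta: dict) -> None:
    """JSON manifest listing artifacts with content hashes."""
    manifest = {"meta": meta,
                "files": {str(k): file_sha256(v) for k, v in entries.items()}}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
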