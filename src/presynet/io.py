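"""File round-tripping: spike tables, state traces, run manifests.

Spike records travel as plain CSV (columns ``neuron_id``, ``t_ms``, sorted by
time then id) with a YAML sidecar holding duration, seed and manipulation
metadata.  State traces use an HDF5 container with one chunked dataset per
variable.  A run manifest captures everything needed to re-run a simulation
bit-identically: the full config, the seed, and SHA-256 checksums of every
output file.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .config import SimulationConfig, config_from_mapping, config_to_mapping
from .engine import SpikeRecord, StateTrace

__all__ = [
    "save_spikes", "load_spikes",
    "save_trace", "load_trace",
    "save_bursts",
    "write_manifest", "replay_manifest",
]


def save_spikes(spikes: SpikeRecord, path: str | Path,
                metadata: dict | None = None) -> Path:
    """Write a spike table (CSV) plus a ``.meta.yaml`` sidecar."""
    path = Path(path)
    order = np.lexsort((spikes.units, spikes.times))
    pd.DataFrame({"neuron_id": spikes.units[order],
                  "t_ms": spikes.times[order]}).to_csv(path, index=False)
    meta = {"n_neurons": int(spikes.n_neurons),
            "duration_ms": int(spikes.duration_ms)}
    meta.update(metadata or {})
    path.with_suffix(path.suffix + ".meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=False))
    return path


def load_spikes(path: str | Path) -> SpikeRecord:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        n_neurons = int(meta["n_neurons"])
        duration = int(meta["duration_ms"])
    else:
        n_neurons = int(df["neuron_id"].max()) + 1 if len(df) else 0
        duration = int(df["t_ms"].max()) + 1 if len(df) else 0
    times = df["t_ms"].to_numpy(dtype=np.int64)
    units = df["neuron_id"].to_numpy(dtype=np.int64)
    order = np.lexsort((units, times))
    return SpikeRecord(times=times[order], units=units[order],
                       n_neurons=n_neurons, duration_ms=duration)


def save_trace(trace: StateTrace, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["start_ms"] = trace.start_ms
        f.attrs["stride_ms"] = trace.stride_ms
        f.create_dataset("neurons", data=np.asarray(trace.neurons))
        for name, arr in trace.arrays.items():
            f.create_dataset(name, data=arr, chunks=True, compression="gzip",
                             compression_opts=1)
    return path


def load_trace(path: str | Path) -> StateTrace:
    with h5py.File(path, "r") as f:
        arrays = {k: f[k][...] for k in f.keys() if k != "neurons"}
        return StateTrace(arrays=arrays,
                          start_ms=int(f.attrs["start_ms"]),
                          stride_ms=int(f.attrs["stride_ms"]),
                          neurons=f["neurons"][...])


def save_bursts(bursts, path: str | Path) -> Path:
    """Burst table with the stable column order used across the package."""
    rows = [{"t_start_ms": b.t_start, "t_end_ms": b.t_end,
             "t_peak_ms": b.t_peak, "peak_rate_hz": b.peak_rate,
             "n_spikes": b.n_spikes, "n_participating": b.n_participating,
             "label": b.label} for b in bursts]
    cols = ["t_start_ms", "t_end_ms", "t_peak_ms", "peak_rate_hz",
            "n_spikes", "n_participating", "label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return Path(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: SimulationConfig, seed: int,
                   manipulations: list[str] | None = None) -> Path:
    """Checksum every file in ``out_dir`` and record the run provenance."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    files = {p.name: _sha256(p) for p in sorted(out_dir.iterdir())
             if p.is_file() and p.name != "manifest.json"}
    manifest = {
        "package_version": _version,
        "seed": int(seed),
        "manipulations": manipulations or [],
        "config": config_to_mapping(config),
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest_path


def replay_manifest(manifest_path: str | Path):
    """Re-run the simulation a manifest describes; returns the new result.

    Replays are bitwise identical: the manifest stores the full config
    (including the seed), which determines the spike record exactly.
    """
    from .engine import simulate

    manifest = json.loads(Path(manifest_path).read_text())
    config = config_from_mapping(manifest["config"])
    return simulate(config, seed=int(manifest["seed"]))
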