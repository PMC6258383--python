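"""Run artifacts: spike/current/weight containers, topology export,
manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import RunResult
from .network import Network

__all__ = [
    "save_run",
    "load_spikes",
    "save_weights",
    "load_weights",
    "export_topology",
    "write_manifest",
]


def save_run(result: RunResult, path) -> None:
    """Write a run's spikes, currents and metadata to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["duration_ms"] = result.duration
        f.attrs["pops"] = json.dumps(result.pops)
        f.attrs["offsets"] = json.dumps(result.offsets)
        f.attrs["v_min"] = result.v_min
        f.attrs["v_max"] = result.v_max
        f.attrs["counters"] = json.dumps(result.counters)
        g = f.create_group("spikes")
        g.create_dataset("t_ms", data=result.spike_t)
        g.create_dataset("idx", data=result.spike_idx)
        g.create_dataset("visible", data=result.spike_visible)
        if result.current_t is not None:
            g = f.create_group("currents")
            g.create_dataset("t_ms", data=result.current_t)
            g.create_dataset("i_exc", data=result.current_exc)
            g.create_dataset("i_inh", data=result.current_inh)
            g.create_dataset("idx", data=result.current_idx)


def load_spikes(path):
    """(t_ms, idx, visible, offsets) from a saved run."""
    with h5py.File(path, "r") as f:
        return (
            f["spikes/t_ms"][:],
            f["spikes/idx"][:],
            f["spikes/visible"][:],
            json.loads(f.attrs["offsets"]),
        )


def save_weights(network: Network, path) -> None:
    with h5py.File(path, "w") as f:
        for g in network.groups.values():
            grp = f.create_group(g.name)
            grp.create_dataset("w", data=g.w)
            grp.attrs["epsilon"] = g.epsilon
            grp.attrs["gamma"] = g.gamma


def load_weights(network: Network, path) -> None:
    with h5py.File(path, "r") as f:
        for g in network.groups.values():
            g.w[:] = f[g.name]["w"][:]


def export_topology(network: Network, path) -> None:
    """Columnar text export: pre_pop pre_idx post_pop post_idx weight."""
    frames = []
    for g in network.groups.values():
        pre = np.repeat(np.arange(g.n_pre), np.diff(g.indptr))
        frames.append(pd.DataFrame({
            "pre_pop": g.pre_pop,
            "pre_idx": pre,
            "post_pop": g.post_pop,
            "post_idx": g.post,
            "weight": g.w,
        }))
    pd.concat(frames).to_csv(path, sep=" ", index=False)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, config: dict, seed: int,
                   inputs: dict[str, str] | None = None,
                   outputs: list[str] | None = None,
                   notes: str = "") -> None:
    """A JSON manifest sufficient to re-run the simulation bit-identically."""
    from . import __version__

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": {k: (v if isinstance(v, (int, float, str, dict))
                       else str(v)) for k, v in config.items()},
        "input_digests": {k: file_digest(v) for k, v in
                          (inputs or {}).items()},
        "outputs": outputs or [],
        "notes": notes,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
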