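"""HDF5 persistence for neurogram sets and network checkpoints."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from . import network as nw
from .adaptation import NeurogramSet
from .network import NetworkConfig, NetworkState
from .periphery import CFGrid

__all__ = [
    "save_neurogram_set",
    "load_neurogram_set",
    "save_checkpoint",
    "load_checkpoint",
]


def save_neurogram_set(path, data: NeurogramSet, cf_grid: CFGrid,
                       frame_rate_hz: float = 100.0,
                       normalized: bool = True) -> None:
    """Layout: /values (n, cf, frame), /cf_grid, /manifest_json; attrs carry
    the state id, frame rate, and normalization flag."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=data.values, compression="gzip")
        f.create_dataset("cf_grid", data=cf_grid.cfs)
        f.create_dataset("manifest_json",
                         data=data.manifest.to_json(orient="records"))
        f.attrs["state_id"] = data.state_id
        f.attrs["frame_rate_hz"] = frame_rate_hz
        f.attrs["normalized"] = normalized


def load_neurogram_set(path) -> tuple[NeurogramSet, CFGrid]:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        cfs = f["cf_grid"][...]
        from io import StringIO
        raw = f["manifest_json"][()]
        if isinstance(raw, bytes):
            raw = raw.decode()
        manifest = pd.read_json(StringIO(raw), orient="records")
        state_id = f.attrs["state_id"]
    return NeurogramSet(values=values, manifest=manifest, state_id=state_id), \
        CFGrid(cfs)


def save_checkpoint(path, state: NetworkState) -> None:
    """One group per layer with weight/bias datasets; config as a JSON attr."""
    with h5py.File(path, "w") as f:
        for layer, tensors in state.params.items():
            g = f.create_group(layer)
            g.create_dataset("weight", data=tensors["weight"])
            g.create_dataset("bias", data=tensors["bias"])
        f.attrs["step"] = state.step
        f.attrs["seed"] = state.seed
        cfg = state.config.__dict__.copy()
        cfg["input_shape"] = list(cfg["input_shape"])
        cfg["conv_kernel_sizes"] = list(cfg["conv_kernel_sizes"])
        f.attrs["config_json"] = json.dumps(cfg)


def load_checkpoint(path) -> NetworkState:
    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["config_json"])
        cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
        cfg_dict["conv_kernel_sizes"] = tuple(cfg_dict["conv_kernel_sizes"])
        config = NetworkConfig(**cfg_dict)
        state = nw.build_network(config, seed=int(f.attrs["seed"]))
        for layer in state.params:
            state.params[layer]["weight"] = f[layer]["weight"][...]
            state.params[layer]["bias"] = f[layer]["bias"][...]
        state.step = int(f.attrs["step"])
    return state
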