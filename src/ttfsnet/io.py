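"""HDF5/JSON/CSV serialization shared across the package.

Network container layout (HDF5):

    /layers/<k>/        datasets  W (or w), B, theta_base, D, A  (b for ReLU)
                        attrs     kind, padding, pool, stride, in_shape, out_shape
    /readout/           datasets  W, A  (w, b for ReLU)
    /windows/deltas     window lengths in units of tau_c (TTFS only)
    /meta               attrs     model in {B1, alpha1, relu}, tau_c, seed, ...

Datasets are stored as HDF5 files with datasets ``X`` (samples x features
in [0, 1]) and ``y`` (integer labels) plus the train/test split; small
fixtures can use CSV instead.  Every artifact written here carries the
package version and, when available, the config hash and seed, so runs
are reproducible from the stored metadata alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import yaml

from .network_model import (
    ReLULayer, ReLUNetwork, TTFSLayer, TTFSNetwork, WindowSchedule, validate,
)
from .synthetic import ToyDataset

__all__ = [
    "save_network",
    "load_network",
    "save_dataset",
    "load_dataset",
    "architecture_dict",
    "save_architecture_json",
    "load_config",
    "config_hash",
]

_PKG_VERSION = "0.1.0"

_LAYER_ATTRS = ("kind", "padding", "pool", "stride")
_SHAPE_ATTRS = ("in_shape", "out_shape")


def _write_common(grp, layer, attrs_extra=None):
    for name in _LAYER_ATTRS:
        grp.attrs[name] = getattr(layer, name)
    for name in _SHAPE_ATTRS:
        val = getattr(layer, name)
        if val is not None:
            grp.attrs[name] = np.asarray(val, dtype=int)
    if attrs_extra:
        grp.attrs.update(attrs_extra)


def _read_geometry(grp):
    out = {}
    for name in _SHAPE_ATTRS:
        if name in grp.attrs:
            out[name] = tuple(int(v) for v in grp.attrs[name])
    for name in ("pool", "stride"):
        if name in grp.attrs:
            out[name] = int(grp.attrs[name])
    if "padding" in grp.attrs:
        out["padding"] = str(grp.attrs["padding"])
    return out


def save_network(path: Union[str, Path], net, *, seed: Optional[int] = None,
                 cfg_hash: Optional[str] = None) -> None:
    """Write a ReLU or TTFS network to the HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["version"] = _PKG_VERSION
        if seed is not None:
            meta.attrs["seed"] = int(seed)
        if cfg_hash is not None:
            meta.attrs["config_hash"] = cfg_hash
        if isinstance(net, ReLUNetwork):
            meta.attrs["model"] = "relu"
            for k, lay in enumerate(net.layers):
                grp = f.create_group(f"layers/{k}")
                _write_common(grp, lay)
                if lay.kind != "maxpool":
                    grp.create_dataset("w", data=lay.w)
                    grp.create_dataset("b", data=lay.b)
            grp = f.create_group("readout")
            grp.create_dataset("w", data=net.readout.w)
            grp.create_dataset("b", data=net.readout.b)
        elif isinstance(net, TTFSNetwork):
            meta.attrs["model"] = net.model
            meta.attrs["tau_c"] = float(net.tau_c)
            for k, lay in enumerate(net.layers):
                grp = f.create_group(f"layers/{k}")
                _write_common(grp, lay)
                if lay.kind != "maxpool":
                    for name in ("W", "B", "theta_base", "D", "A"):
                        grp.create_dataset(name, data=getattr(lay, name))
            grp = f.create_group("readout")
            grp.create_dataset("W", data=net.readout.W)
            grp.create_dataset("A", data=net.readout.A)
            wgrp = f.create_group("windows")
            wgrp.create_dataset("deltas", data=net.windows.deltas)
            wgrp.attrs["origin"] = float(net.windows.origin)
            if "layer_scales" in net.meta:
                meta.create_dataset(
                    "layer_scales", data=np.asarray(net.meta["layer_scales"]))
        else:
            raise TypeError(f"cannot serialize {type(net).__name__}")


def load_network(path: Union[str, Path]):
    """Load a network container; the model kind is read from metadata."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "meta" not in f or "model" not in f["meta"].attrs:
            raise KeyError(f"{path}: missing /meta group with a 'model' tag")
        model = str(f["meta"].attrs["model"])
        if model not in ("relu", "B1", "alpha1"):
            raise ValueError(f"{path}: unknown model tag {model!r}")
        keys = sorted((k for k in f.get("layers", {})), key=int) \
            if "layers" in f else []
        if model == "relu":
            layers = []
            for k in keys:
                grp = f[f"layers/{k}"]
                kind = str(grp.attrs["kind"])
                geo = _read_geometry(grp)
                if kind == "maxpool":
                    layers.append(ReLULayer(kind=kind, **geo))
                else:
                    layers.append(ReLULayer(kind=kind, w=grp["w"][()],
                                            b=grp["b"][()], **geo))
            readout = ReLULayer(kind="dense", w=f["readout/w"][()],
                                b=f["readout/b"][()])
            net = ReLUNetwork(layers, readout)
        else:
            if "windows" not in f:
                raise KeyError(
                    f"{path}: TTFS container is missing the /windows group")
            layers = []
            for k in keys:
                grp = f[f"layers/{k}"]
                kind = str(grp.attrs["kind"])
                geo = _read_geometry(grp)
                if kind == "maxpool":
                    layers.append(TTFSLayer(kind=kind, **geo))
                else:
                    layers.append(TTFSLayer(
                        kind=kind, W=grp["W"][()], B=grp["B"][()],
                        theta_base=grp["theta_base"][()], D=grp["D"][()],
                        A=grp["A"][()], **geo))
            readout = TTFSLayer(kind="dense", W=f["readout/W"][()],
                                A=f["readout/A"][()],
                                B=np.ones_like(f["readout/A"][()]))
            windows = WindowSchedule(f["windows/deltas"][()],
                                     origin=float(f["windows"].attrs["origin"]))
            meta = {}
            if "layer_scales" in f["meta"]:
                meta["layer_scales"] = list(f["meta/layer_scales"][()])
            net = TTFSNetwork(layers=layers, readout=readout,
                              tau_c=float(f["meta"].attrs["tau_c"]),
                              windows=windows, model=model, meta=meta)
    report = validate(net)
    if report:
        raise ValueError(f"{path}: invalid network: " + "; ".join(report))
    return net


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def save_dataset(path: Union[str, Path], data: ToyDataset) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=data.X)
        f.create_dataset("y", data=data.y)
        f.create_dataset("train_idx", data=data.train_idx)
        f.create_dataset("test_idx", data=data.test_idx)
        f.attrs["seed"] = int(data.seed)
        f.attrs["meta"] = json.dumps(data.meta)
        f.attrs["version"] = _PKG_VERSION


def load_dataset(path: Union[str, Path]) -> ToyDataset:
    """Load an HDF5 dataset container (or a CSV whose last column is the
    label, split 80/20 deterministically)."""
    path = Path(path)
    if path.suffix == ".csv":
        arr = np.loadtxt(path, delimiter=",")
        X, y = arr[:, :-1], arr[:, -1].astype(int)
        n = len(X)
        cut = max(1, int(0.8 * n))
        return ToyDataset(X=X, y=y, train_idx=np.arange(cut),
                          test_idx=np.arange(cut, n), seed=0,
                          meta={"kind": "csv"})
    with h5py.File(path, "r") as f:
        return ToyDataset(
            X=f["X"][()], y=f["y"][()].astype(int),
            train_idx=f["train_idx"][()], test_idx=f["test_idx"][()],
            seed=int(f.attrs.get("seed", 0)),
            meta=json.loads(f.attrs.get("meta", "{}")))


# ---------------------------------------------------------------------------
# Architecture sidecar and run configuration
# ---------------------------------------------------------------------------

def architecture_dict(net) -> dict:
    """Architecture-only description (no parameter values)."""
    def one(layer):
        d = {"kind": layer.kind}
        w = layer.W if hasattr(layer, "W") else layer.w
        if w is not None:
            d["shape"] = list(w.shape)
        for name in ("in_shape", "out_shape"):
            v = getattr(layer, name)
            if v is not None:
                d[name] = list(v)
        if layer.kind == "maxpool":
            d["pool"], d["stride"] = layer.pool, layer.stride
        return d

    kind = "relu" if isinstance(net, ReLUNetwork) else net.model
    return {"model": kind,
            "layers": [one(l) for l in net.layers],
            "readout": one(net.readout)}


def save_architecture_json(path: Union[str, Path], net) -> None:
    Path(path).write_text(json.dumps(architecture_dict(net), indent=2))


def load_config(path: Union[str, Path]) -> dict:
    """Read a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
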