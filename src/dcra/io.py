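"""Readers and writers: session containers, model/metric archives, predictions.

Sessions travel either as one HDF5 container with named arrays (features_e,
features_o, perclos, events, latent) or as a directory of delimited text
tables with a small JSON metadata file. Model and metric archives are HDF5
containers of named parameter arrays plus architecture metadata, round-trip
tested (save -> load -> identical outputs).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .datagen import EyeEventCounts, LabeledSession
from .gru import DRAParams, GRULayer, GRULayerParams, GRUStack
from .metric import MetricMatrix
from .model import DCRAParams
from .nn import BatchNorm, Tensor

__all__ = [
    "write_session",
    "read_features",
    "write_predictions",
    "save_model",
    "load_model",
    "save_metric",
    "load_metric",
    "export_metric_text",
]

_EVENT_COLS = ("blink", "fixation", "saccade", "clos")


def _events_array(session: LabeledSession) -> np.ndarray:
    return np.array([[ev.blink, ev.fixation, ev.saccade, ev.clos]
                     for ev in session.events], dtype=np.int64)


def _check_finite(name: str, arr: np.ndarray) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        loc = np.argwhere(bad)[0]
        raise ValueError(f"{name}: non-finite value at position {tuple(int(i) for i in loc)}")


def write_session(path: str | Path, session: LabeledSession,
                  metadata: dict | None = None) -> Path:
    """Write a session to HDF5 (.h5/.hdf5) or a directory of CSV tables."""
    path = Path(path)
    meta = dict(metadata or {})
    meta.setdefault("n_epochs", session.n_epochs)
    meta["steps_per_epoch"] = int(session.features_e.shape[1])
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("features_e", data=session.features_e)
            f.create_dataset("features_o", data=session.features_o)
            f.create_dataset("perclos", data=session.perclos)
            if session.events:
                f.create_dataset("events", data=_events_array(session))
            if session.latent is not None:
                f.create_dataset("latent", data=session.latent)
            f.attrs["metadata"] = json.dumps(meta)
        return path
    path.mkdir(parents=True, exist_ok=True)
    n, T, de = session.features_e.shape
    do = session.features_o.shape[2]
    np.savetxt(path / "features_e.csv", session.features_e.reshape(n * T, de),
               delimiter=",", header=",".join(f"e{i}" for i in range(de)), comments="")
    np.savetxt(path / "features_o.csv", session.features_o.reshape(n * T, do),
               delimiter=",", header=",".join(f"o{i}" for i in range(do)), comments="")
    np.savetxt(path / "perclos.csv", session.perclos, delimiter=",",
               header="perclos", comments="")
    if session.events:
        np.savetxt(path / "events.csv", _events_array(session), fmt="%d",
                   delimiter=",", header=",".join(_EVENT_COLS), comments="")
    if session.latent is not None:
        np.savetxt(path / "latent.csv", session.latent, delimiter=",",
                   header="latent", comments="")
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_features(path: str | Path) -> LabeledSession:
    """Read a session container written by `write_session` (HDF5 or CSV dir)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_file():
        with h5py.File(path, "r") as f:
            x_e = f["features_e"][()]
            x_o = f["features_o"][()]
            perclos_v = f["perclos"][()]
            events_arr = f["events"][()] if "events" in f else None
            latent = f["latent"][()] if "latent" in f else None
    else:
        meta = json.loads((path / "meta.json").read_text())
        n, T = int(meta["n_epochs"]), int(meta["steps_per_epoch"])
        x_e = np.loadtxt(path / "features_e.csv", delimiter=",", skiprows=1, ndmin=2)
        x_o = np.loadtxt(path / "features_o.csv", delimiter=",", skiprows=1, ndmin=2)
        x_e = x_e.reshape(n, T, -1)
        x_o = x_o.reshape(n, T, -1)
        perclos_v = np.loadtxt(path / "perclos.csv", delimiter=",", skiprows=1)
        events_arr = None
        if (path / "events.csv").exists():
            events_arr = np.loadtxt(path / "events.csv", delimiter=",",
                                    skiprows=1, dtype=np.int64, ndmin=2)
        latent = None
        if (path / "latent.csv").exists():
            latent = np.loadtxt(path / "latent.csv", delimiter=",", skiprows=1)
    _check_finite("features_e", x_e)
    _check_finite("features_o", x_o)
    events = ([EyeEventCounts(*(int(v) for v in row)) for row in events_arr]
              if events_arr is not None else [])
    return LabeledSession(x_e, x_o, events, np.atleast_1d(perclos_v), latent=latent)


def write_predictions(path: str | Path, ids, y, yhat) -> Path:
    """Write (epoch_id, true_perclos, predicted_perclos) as CSV."""
    path = Path(path)
    ids = np.asarray(ids)
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if not (len(ids) == len(y) == len(yhat)):
        raise ValueError("ids, y and yhat must have equal length")
    with open(path, "w") as f:
        f.write("epoch_id,true_perclos,predicted_perclos\n")
        for i, yt, yp in zip(ids, y, yhat):
            f.write(f"{i},{yt:.6f},{yp:.6f}\n")
    return path


# -- model archive ---------------------------------------------------------

def _save_layer(grp: h5py.Group, layer: GRULayer) -> None:
    for name, t in zip(
        ("W_xz", "W_xr", "W_xg", "W_hz", "W_hr", "W_hg", "b_z", "b_r", "b_g"),
        layer.params.tensors(),
    ):
        grp.create_dataset(name, data=t.data)
    grp.attrs["activation"] = layer.activation
    grp.attrs["batch_norm"] = layer.batch_norm is not None
    if layer.batch_norm is not None:
        bn = grp.create_group("bn")
        for k, v in layer.batch_norm.state().items():
            bn.create_dataset(k, data=v)


def _load_layer(grp: h5py.Group) -> GRULayer:
    t = {name: Tensor(grp[name][()], requires_grad=True)
         for name in ("W_xz", "W_xr", "W_xg", "W_hz", "W_hr", "W_hg",
                      "b_z", "b_r", "b_g")}
    params = GRULayerParams(**t)
    bn = None
    if grp.attrs["batch_norm"]:
        bn = BatchNorm(params.units)
        bn.load_state({k: grp["bn"][k][()] for k in
                       ("gamma", "beta", "running_mean", "running_var")})
    return GRULayer(params=params, activation=str(grp.attrs["activation"]),
                    batch_norm=bn)


def _save_stack(grp: h5py.Group, stack: GRUStack) -> None:
    grp.attrs["n_layers"] = len(stack.layers)
    for i, layer in enumerate(stack.layers):
        _save_layer(grp.create_group(f"layer_{i}"), layer)


def _load_stack(grp: h5py.Group) -> GRUStack:
    return GRUStack([_load_layer(grp[f"layer_{i}"])
                     for i in range(int(grp.attrs["n_layers"]))])


def _save_dra(grp: h5py.Group, dra: DRAParams) -> None:
    _save_stack(grp.create_group("encoder"), dra.encoder)
    _save_stack(grp.create_group("decoder"), dra.decoder)
    grp.create_dataset("proj_W", data=dra.proj_W.data)
    grp.create_dataset("proj_b", data=dra.proj_b.data)


def _load_dra(grp: h5py.Group) -> DRAParams:
    return DRAParams(
        encoder=_load_stack(grp["encoder"]),
        decoder=_load_stack(grp["decoder"]),
        proj_W=Tensor(grp["proj_W"][()], requires_grad=True),
        proj_b=Tensor(grp["proj_b"][()], requires_grad=True),
    )


def save_model(path: str | Path, model: DCRAParams,
               metadata: dict | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        _save_dra(f.create_group("ae_e"), model.ae_e)
        _save_dra(f.create_group("ae_o"), model.ae_o)
        f.attrs["alpha"] = model.alpha
        f.attrs["coupling_form"] = model.coupling_form
        f.attrs["metadata"] = json.dumps(metadata or {})
        if model.metric is not None:
            g = f.create_group("metric")
            g.create_dataset("M", data=model.metric.M)
            g.create_dataset("P", data=model.metric.P)
        if model.head_W is not None:
            g = f.create_group("head")
            g.create_dataset("W", data=model.head_W)
            g.attrs["b"] = model.head_b
    return path


def load_model(path: str | Path) -> DCRAParams:
    with h5py.File(Path(path), "r") as f:
        metric = None
        if "metric" in f:
            metric = MetricMatrix(f["metric"]["M"][()], f["metric"]["P"][()])
        model = DCRAParams(
            ae_e=_load_dra(f["ae_e"]),
            ae_o=_load_dra(f["ae_o"]),
            alpha=float(f.attrs["alpha"]),
            metric=metric,
            coupling_form=str(f.attrs["coupling_form"]),
        )
        if "head" in f:
            model.head_W = f["head"]["W"][()]
            model.head_b = float(f["head"].attrs["b"])
    return model


# -- metric archive --------------------------------------------------------

def save_metric(path: str | Path, metric: MetricMatrix,
                metadata: dict | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("M", data=metric.M)
        f.create_dataset("P", data=metric.P)
        f.attrs["d"] = metric.d
        f.attrs["metadata"] = json.dumps(metadata or {})
    return path


def load_metric(path: str | Path) -> MetricMatrix:
    with h5py.File(Path(path), "r") as f:
        return MetricMatrix(f["M"][()], f["P"][()])


def export_metric_text(path: str | Path, metric: MetricMatrix) -> Path:
    """Delimited-text export of M for inspection."""
    path = Path(path)
    np.savetxt(path, metric.M, delimiter=",")
    return path
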