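"""Readers and writers for response tensors and analysis products.

Two on-disk dialects are supported for :class:`~popgeom.core.ResponseTensor`:

* **HDF5** — one ``activity`` dataset plus ``time_axis``, a ``sequences``
  metadata group and a ``neurons`` group; ``bin_width`` is a root attribute.
  Round-trips activity bit-exactly.
* **CSV bundle** — a directory holding a long-format ``activity.csv``
  (columns ``neuron_id, sequence_id, time_bin, activity``), a
  ``sequences.csv`` metadata table and a small ``meta.json``. Human
  inspectable; round-trips values at float repr precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import ResponseTensor, SequenceInfo, StimulusEnsemble
from .errors import SchemaError, ValidationError

__all__ = ["read_response_tensor", "write_response_tensor"]

_SEQ_COLUMNS = ["sequence_id", "base_class", "variant_id", "direction"]
_ACT_COLUMNS = ["neuron_id", "sequence_id", "time_bin", "activity"]


def write_response_tensor(tensor: ResponseTensor, path, format: str | None = None) -> Path:
    """Write a tensor to ``path`` as HDF5 or a CSV bundle directory.

    ``format`` is inferred from the suffix when omitted (``.h5``/``.hdf5`` →
    hdf5, anything else → csv-bundle).
    """
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv-bundle")
    if fmt == "hdf5":
        _write_hdf5(tensor, path)
    elif fmt == "csv-bundle":
        _write_csv_bundle(tensor, path)
    else:
        raise SchemaError(f"unknown format {fmt!r}")
    return path


def read_response_tensor(path, format: str | None = None) -> ResponseTensor:
    """Read a validated :class:`ResponseTensor` from HDF5 or a CSV bundle."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv-bundle")
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "csv-bundle":
        return _read_csv_bundle(path)
    raise SchemaError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def _write_hdf5(tensor: ResponseTensor, path: Path) -> None:
    ens = tensor.ensemble
    with h5py.File(path, "w") as f:
        f.attrs["bin_width"] = tensor.bin_width
        f.create_dataset("activity", data=tensor.activity)
        f.create_dataset("time_axis", data=tensor.time_axis)
        g = f.create_group("sequences")
        g.attrs["n_directions"] = ens.n_directions
        g.attrs["class_names"] = [c.encode() for c in ens.class_names]
        g.create_dataset("sequence_id", data=[s.sequence_id.encode() for s in ens.sequences])
        g.create_dataset("base_class", data=[s.base_class.encode() for s in ens.sequences])
        g.create_dataset("variant_id", data=[s.variant_id.encode() for s in ens.sequences])
        g.create_dataset("direction", data=[s.direction for s in ens.sequences])
        n = f.create_group("neurons")
        n.create_dataset("neuron_id", data=[x.encode() for x in tensor.neuron_ids])


def _read_hdf5(path: Path) -> ResponseTensor:
    with h5py.File(path, "r") as f:
        for key in ("activity", "sequences", "neurons"):
            if key not in f:
                raise SchemaError(f"HDF5 file missing {key!r}")
        g = f["sequences"]
        for col in _SEQ_COLUMNS:
            if col not in g:
                raise SchemaError(f"sequences group missing column {col!r}")
        sequences = [
            SequenceInfo(sid.decode(), bc.decode(), vid.decode(), float(d))
            for sid, bc, vid, d in zip(
                g["sequence_id"][:], g["base_class"][:], g["variant_id"][:], g["direction"][:]
            )
        ]
        ensemble = StimulusEnsemble(
            sequences=sequences,
            n_directions=int(g.attrs["n_directions"]),
            class_names=[c.decode() if isinstance(c, bytes) else str(c)
                         for c in g.attrs["class_names"]],
        )
        neuron_ids = [x.decode() for x in f["neurons"]["neuron_id"][:]]
        return ResponseTensor(
            activity=f["activity"][:],
            bin_width=float(f.attrs["bin_width"]),
            ensemble=ensemble,
            neuron_ids=neuron_ids,
        )


# ---------------------------------------------------------------------------
# CSV bundle
# ---------------------------------------------------------------------------

def _write_csv_bundle(tensor: ResponseTensor, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    ens = tensor.ensemble
    n_idx, s_idx, t_idx = np.meshgrid(
        np.arange(tensor.n_neurons),
        np.arange(tensor.n_sequences),
        np.arange(tensor.n_time),
        indexing="ij",
    )
    act = pd.DataFrame(
        {
            "neuron_id": np.asarray(tensor.neuron_ids)[n_idx.ravel()],
            "sequence_id": np.asarray(ens.sequence_ids)[s_idx.ravel()],
            "time_bin": t_idx.ravel(),
            "activity": tensor.activity.ravel(),
        }
    )
    act.to_csv(path / "activity.csv", index=False)
    pd.DataFrame(
        {
            "sequence_id": [s.sequence_id for s in ens.sequences],
            "base_class": [s.base_class for s in ens.sequences],
            "variant_id": [s.variant_id for s in ens.sequences],
            "direction": [s.direction for s in ens.sequences],
        }
    ).to_csv(path / "sequences.csv", index=False)
    meta = {
        "bin_width": tensor.bin_width,
        "n_directions": ens.n_directions,
        "class_names": ens.class_names,
        "neuron_ids": tensor.neuron_ids,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def _read_csv_bundle(path: Path) -> ResponseTensor:
    for fname in ("activity.csv", "sequences.csv", "meta.json"):
        if not (path / fname).exists():
            raise SchemaError(f"CSV bundle missing {fname}")
    meta = json.loads((path / "meta.json").read_text())
    seq_df = pd.read_csv(path / "sequences.csv")
    for col in _SEQ_COLUMNS:
        if col not in seq_df.columns:
            raise SchemaError(f"sequences.csv missing column {col!r}")
    act = pd.read_csv(path / "activity.csv")
    for col in _ACT_COLUMNS:
        if col not in act.columns:
            raise SchemaError(f"activity.csv missing column {col!r}")

    known = set(seq_df["sequence_id"].astype(str))
    present = set(act["sequence_id"].astype(str))
    missing = sorted(present - known)
    if missing:
        raise SchemaError(
            f"activity references sequence ids absent from metadata: {missing[:5]}"
        )

    sequences = [
        SequenceInfo(str(r.sequence_id), str(r.base_class), str(r.variant_id), float(r.direction))
        for r in seq_df.itertuples()
    ]
    ensemble = StimulusEnsemble(
        sequences=sequences,
        n_directions=int(meta["n_directions"]),
        class_names=list(meta["class_names"]),
    )
    neuron_ids = [str(x) for x in meta["neuron_ids"]]
    n_time = int(act["time_bin"].max()) + 1
    shape = (len(neuron_ids), len(sequences), n_time)
    if len(act) != int(np.prod(shape)):
        raise SchemaError(
            f"activity.csv has {len(act)} rows; expected {int(np.prod(shape))} for "
            f"a dense {shape} tensor"
        )
    n_pos = {x: i for i, x in enumerate(neuron_ids)}
    s_pos = {s.sequence_id: i for i, s in enumerate(sequences)}
    arr = np.full(shape, np.nan)
    arr[
        act["neuron_id"].astype(str).map(n_pos).to_numpy(),
        act["sequence_id"].astype(str).map(s_pos).to_numpy(),
        act["time_bin"].to_numpy(),
    ] = act["activity"].to_numpy()
    if np.isnan(arr).any():
        raise SchemaError("activity.csv does not cover the full (neuron, sequence, bin) grid")
    return ResponseTensor(
        activity=arr,
        bin_width=float(meta["bin_width"]),
        ensemble=ensemble,
        neuron_ids=neuron_ids,
    )


def write_json_report(obj: dict, path) -> Path:
    """Serialise a report dict to pretty-printed JSON (numpy-safe)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, default=_default))
    return path


# ---------------------------------------------------------------------------
# Trajectory / manifold CSV exports
# ---------------------------------------------------------------------------

def write_trajectories_csv(trajs, path) -> Path:
    """Long-format trajectory export: one row per (trajectory, time step)."""
    K, T, D = trajs.trajectories.shape
    rows = {
        "trajectory": np.repeat(np.arange(K), T),
        "label": np.repeat(np.asarray(trajs.labels, dtype=object), T),
        "time": np.tile(trajs.time_axis, K),
    }
    flat = trajs.trajectories.reshape(K * T, D)
    for d in range(D):
        rows[f"d{d}"] = flat[:, d]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_trajectories_csv(path):
    """Read a trajectory set written by :func:`write_trajectories_csv`."""
    from .core import TrajectorySet

    df = pd.read_csv(path)
    for col in ("trajectory", "label", "time"):
        if col not in df.columns:
            raise SchemaError(f"trajectory CSV missing column {col!r}")
    dims = sorted(
        (c for c in df.columns if c.startswith("d") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not dims:
        raise SchemaError("trajectory CSV has no coordinate columns d0, d1, ...")
    ks = df["trajectory"].unique()
    T = int((df["trajectory"] == ks[0]).sum())
    labels = []
    arrs = []
    time_axis = None
    for k in ks:
        sub = df[df["trajectory"] == k].sort_values("time")
        if len(sub) != T:
            raise SchemaError("trajectories have unequal lengths")
        labels.append(str(sub["label"].iloc[0]))
        arrs.append(sub[dims].to_numpy())
        time_axis = sub["time"].to_numpy()
    return TrajectorySet(np.stack(arrs), labels, time_axis=time_axis)


def write_manifold_csv(manifold, path) -> Path:
    """Decoding-manifold export: one row per analysis-unit point."""
    D = manifold.coords.shape[1]
    rows = {
        "base_class": manifold.point_classes,
        "direction": manifold.point_directions,
    }
    for d in range(D):
        rows[f"pc{d + 1}"] = manifold.coords[:, d]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_embedding_csv(manifold, path) -> Path:
    """Encoding-manifold export: neuron id, coords, component, factor loadings."""
    rows = {"neuron_id": manifold.neuron_ids, "component": manifold.component_labels}
    for d in range(manifold.embedding.shape[1]):
        rows[f"dm{d + 1}"] = manifold.embedding[:, d]
    for r in range(manifold.neuron_factors.shape[1]):
        rows[f"factor{r + 1}"] = manifold.neuron_factors[:, r]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
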