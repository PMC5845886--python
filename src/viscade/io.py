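"""File I/O: npy / HDF5 / image-sequence readers, per-stage writers, and
CSV spike lists.

npy files carry their ``dt`` in a JSON sidecar (``<name>.json``) written
next to the array; HDF5 datasets carry ``dt`` as an attribute.  Color image
sequences are converted to grayscale by channel mean (logged once).
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import os

import numpy as np

from .retina import RetinaOutputs, spike_events
from .signals import VideoTensor, wrap_video

logger = logging.getLogger("viscade")

__all__ = [
    "StreamEndpoint",
    "read_video",
    "write_video",
    "write_outputs",
    "write_spike_csv",
]


@dataclasses.dataclass
class StreamEndpoint:
    kind: str  # npy_file | hdf5_file | image_sequence_dir | in_memory
    path: str | None = None
    dataset: str = "video"
    dt: float | None = None
    data: VideoTensor | None = None

    _KINDS = ("npy_file", "hdf5_file", "image_sequence_dir", "in_memory")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown endpoint kind {self.kind!r}")


def _endpoint_for(path_or_endpoint, dt=None) -> StreamEndpoint:
    if isinstance(path_or_endpoint, StreamEndpoint):
        return path_or_endpoint
    path = str(path_or_endpoint)
    if os.path.isdir(path):
        return StreamEndpoint("image_sequence_dir", path, dt=dt)
    if path.endswith(".npy"):
        return StreamEndpoint("npy_file", path, dt=dt)
    if path.endswith((".h5", ".hdf5")):
        return StreamEndpoint("hdf5_file", path, dt=dt)
    raise ValueError(f"cannot infer endpoint kind from {path!r}")


def _sidecar(path: str) -> str:
    return os.path.splitext(path)[0] + ".json"


def _as_tensor(arr: np.ndarray, dt: float | None, source: str) -> VideoTensor:
    if dt is None:
        raise ValueError(
            f"{source}: no dt available; pass dt= (or --dt on the CLI), or "
            f"write a JSON sidecar with a 'dt' key"
        )
    if arr.ndim == 3:
        return wrap_video(arr, dt=dt)
    if arr.ndim == 5:
        return VideoTensor(arr, dt=dt)
    raise ValueError(
        f"{source}: expected a 3D (time,x,y) or 5D (b,c,time,x,y) array; "
        f"found shape {arr.shape}"
    )


def read_video(path_or_endpoint, dt: float | None = None) -> VideoTensor:
    """Read a video from npy, HDF5 or a directory of images."""
    ep = _endpoint_for(path_or_endpoint, dt)
    dt = dt if dt is not None else ep.dt
    if ep.kind == "in_memory":
        return ep.data
    if ep.kind == "npy_file":
        arr = np.load(ep.path)
        if dt is None and os.path.exists(_sidecar(ep.path)):
            with open(_sidecar(ep.path)) as fh:
                dt = json.load(fh).get("dt")
        return _as_tensor(arr, dt, ep.path)
    if ep.kind == "hdf5_file":
        import h5py

        with h5py.File(ep.path, "r") as fh:
            ds = fh[ep.dataset]
            arr = ds[()]
            dt = dt if dt is not None else ds.attrs.get("dt")
        return _as_tensor(arr, None if dt is None else float(dt), ep.path)
    if ep.kind == "image_sequence_dir":
        import imageio.v3 as iio

        names = sorted(
            f for f in os.listdir(ep.path)
            if f.lower().endswith((".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"))
        )
        if not names:
            raise ValueError(f"{ep.path}: no image files found")
        frames = []
        converted = False
        for name in names:
            img = np.asarray(iio.imread(os.path.join(ep.path, name)), dtype=float)
            if img.ndim == 3:
                img = img.mean(axis=-1)
                converted = True
            frames.append(img)
        if converted:
            logger.info("converted color image sequence to grayscale (channel mean)")
        return _as_tensor(np.stack(frames), dt, ep.path)
    raise AssertionError  # pragma: no cover


def _config_hash(meta: dict | None) -> str:
    blob = json.dumps(meta or {}, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_video(video: VideoTensor, path_or_endpoint, meta: dict | None = None) -> None:
    ep = _endpoint_for(path_or_endpoint)
    if ep.kind == "npy_file":
        np.save(ep.path, video.values)
        with open(_sidecar(ep.path), "w") as fh:
            json.dump({"dt": video.dt, "t0": video.t0, "config_hash": _config_hash(meta)}, fh)
    elif ep.kind == "hdf5_file":
        import h5py

        with h5py.File(ep.path, "w") as fh:
            ds = fh.create_dataset(ep.dataset, data=video.values)
            ds.attrs["dt"] = video.dt
            ds.attrs["t0"] = video.t0
            ds.attrs["config_hash"] = _config_hash(meta)
    else:
        raise ValueError(f"cannot write a video to endpoint kind {ep.kind!r}")


def write_spike_csv(spikes: VideoTensor, path) -> int:
    """Write one row per spike: ``unit_x, unit_y, channel, time_s``.
    Returns the number of rows (an empty raster yields a header-only file)."""
    events = spike_events(spikes)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit_x", "unit_y", "channel", "time_s"])
        for x, y, c, t in events:
            writer.writerow([int(x), int(y), int(c), f"{t:.9g}"])
    return len(events)


def write_outputs(outputs, path, meta: dict | None = None) -> None:
    """Write a run record to disk.

    HDF5 (``.h5``/``.hdf5``): one dataset per stage with ``dt`` and config
    hash attributes.  Otherwise ``path`` is treated as a directory and one
    npy file (plus sidecar) is written per stage.  Spike rasters are also
    exported as CSV event lists.
    """
    if isinstance(outputs, VideoTensor):
        stages = {"output": outputs}
    elif isinstance(outputs, RetinaOutputs):
        stages = outputs.stages()
    else:
        raise TypeError(f"cannot write outputs of type {type(outputs).__name__}")
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["config_hash"] = _config_hash(meta)
            for name, tens in stages.items():
                ds = fh.create_dataset(name, data=tens.values)
                ds.attrs["dt"] = tens.dt
                ds.attrs["t0"] = tens.t0
        base = os.path.splitext(path)[0]
        for name, tens in stages.items():
            if name.startswith("spikes"):
                write_spike_csv(tens, f"{base}_{name}.csv")
    else:
        os.makedirs(path, exist_ok=True)
        for name, tens in stages.items():
            write_video(tens, os.path.join(path, f"{name}.npy"), meta=meta)
            if name.startswith("spikes"):
                write_spike_csv(tens, os.path.join(path, f"{name}.csv"))
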