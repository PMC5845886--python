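"""Core data model: 5-axis video tensors, the layer/parameter/state contract,
and chunked streaming execution with state carryover.

Every processing stage in the package consumes and produces
:class:`VideoTensor` objects whose values live on the fixed axis order
``(batch, channel, time, x, y)``; the time axis is always index 2.  Layers
own named :class:`Parameter` objects (values that are fixed or optimized)
and state buffers (values that depend on the input history).  State buffers
let :func:`run_chunked` process arbitrarily long inputs slice by slice with
results identical to one-pass processing.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np

__all__ = [
    "VideoTensor",
    "Parameter",
    "Layer",
    "wrap_video",
    "unwrap_video",
    "run_chunked",
    "reset_state",
    "resample",
]


TIME_AXIS = 2


def _first_nonfinite_index(values: np.ndarray):
    bad = ~np.isfinite(values)
    if bad.any():
        return tuple(int(i) for i in np.argwhere(bad)[0])
    return None


@dataclasses.dataclass
class VideoTensor:
    """A real-valued signal on axes ``(batch, channel, time, x, y)``.

    Parameters
    ----------
    values : ndarray
        Five-dimensional array of finite floats.
    dt : float
        Seconds per frame, strictly positive.
    t0 : float
        Start time of the first frame in seconds.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 5:
            raise ValueError(
                f"VideoTensor requires 5 axes (batch, channel, time, x, y); "
                f"got shape {self.values.shape}"
            )
        if min(self.values.shape) < 1:
            raise ValueError(f"all axis lengths must be >= 1; got {self.values.shape}")
        idx = _first_nonfinite_index(self.values)
        if idx is not None:
            raise ValueError(f"non-finite value at index {idx}")
        if not (np.isscalar(self.dt) or np.ndim(self.dt) == 0) or not self.dt > 0:
            raise ValueError(f"dt must be a positive scalar; got {self.dt!r}")
        self.dt = float(self.dt)
        self.t0 = float(self.t0)

    # -- axis bookkeeping ---------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_frames(self) -> int:
        return self.values.shape[TIME_AXIS]

    @property
    def times(self) -> np.ndarray:
        """Frame times ``t0 + k*dt``."""
        return self.t0 + np.arange(self.n_frames) * self.dt

    def with_values(self, values: np.ndarray, t0: float | None = None) -> "VideoTensor":
        return VideoTensor(values, dt=self.dt, t0=self.t0 if t0 is None else t0)

    def time_slice(self, start: int, stop: int) -> "VideoTensor":
        return VideoTensor(
            self.values[:, :, start:stop],
            dt=self.dt,
            t0=self.t0 + start * self.dt,
        )

    @classmethod
    def concatenate(cls, parts: list["VideoTensor"]) -> "VideoTensor":
        if not parts:
            raise ValueError("cannot concatenate zero chunks")
        dt = parts[0].dt
        spatial = parts[0].values.shape[:2] + parts[0].values.shape[3:]
        for p in parts[1:]:
            s = p.values.shape[:2] + p.values.shape[3:]
            if s != spatial:
                raise ValueError(
                    f"mid-stream shape change: {spatial} -> {s}"
                )
            if abs(p.dt - dt) > 1e-12 * dt:
                raise ValueError("mid-stream dt change")
        values = np.concatenate([p.values for p in parts], axis=TIME_AXIS)
        return cls(values, dt=dt, t0=parts[0].t0)


def wrap_video(frames: np.ndarray, dt: float, t0: float = 0.0) -> VideoTensor:
    """Promote a ``(time, x, y)`` array to a VideoTensor with singleton
    batch and channel axes; values are unchanged."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError(f"expected 3 axes (time, x, y); got shape {frames.shape}")
    idx = _first_nonfinite_index(frames)
    if idx is not None:
        raise ValueError(f"non-finite value at index {idx}")
    return VideoTensor(frames[None, None], dt=dt, t0=t0)


def unwrap_video(video: VideoTensor) -> np.ndarray:
    """Inverse of :func:`wrap_video`: drop singleton batch/channel axes."""
    if video.values.shape[0] != 1 or video.values.shape[1] != 1:
        raise ValueError(
            f"cannot unwrap batch/channel axes of lengths "
            f"{video.values.shape[:2]}; both must be 1"
        )
    return video.values[0, 0]


class Parameter:
    """A named model value with an optional gradient slot.

    Scalars are stored as 0-d arrays so that in-place optimizer updates and
    gradient accumulation work uniformly for kernels and scalar parameters.
    """

    def __init__(self, value, trainable: bool = True):
        self.value = np.array(value, dtype=float)
        self.trainable = bool(trainable)
        self.grad: np.ndarray | None = None

    def zero_grad(self):
        self.grad = np.zeros_like(self.value)

    def add_grad(self, g):
        g = np.asarray(g, dtype=float)
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad = self.grad + g.reshape(self.value.shape)

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):
        return f"Parameter(shape={self.value.shape}, trainable={self.trainable})"


class GradientNotAvailable(RuntimeError):
    """Raised when a layer cannot provide the requested analytic gradient."""


class Layer:
    """Base class for all processing nodes.

    Subclasses implement :meth:`process` (consume one chunk, advance state)
    and optionally :meth:`backward` (reverse-mode gradient of the most
    recent :meth:`process` call).  Parameters and child layers assigned as
    attributes are collected automatically under dotted names.
    """

    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_children", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Layer):
            self._children[name] = value
        object.__setattr__(self, name, value)

    # -- parameter collection ------------------------------------------------

    def named_parameters(self, prefix: str = "") -> dict:
        out = {}
        for name, p in self._parameters.items():
            out[prefix + name] = p
        for cname, child in self._children.items():
            out.update(child.named_parameters(prefix + cname + "."))
        return out

    def parameters(self) -> Iterator[Parameter]:
        return iter(self.named_parameters().values())

    def get_parameter(self, dotted: str) -> Parameter:
        params = self.named_parameters()
        if dotted not in params:
            raise KeyError(f"no parameter {dotted!r}; have {sorted(params)}")
        return params[dotted]

    def set_parameter(self, dotted: str, value):
        p = self.get_parameter(dotted)
        p.value = np.array(value, dtype=float).reshape(p.value.shape)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- state ---------------------------------------------------------------

    def _reset_state(self):
        """Zero this layer's own buffers.  Default: stateless."""

    def reset_state(self):
        self._reset_state()
        for child in self._children.values():
            child.reset_state()

    def state_arrays(self, prefix: str = "") -> dict:
        """Flat view of all state buffers (for determinism checks)."""
        out = {}
        for name, val in self._local_state().items():
            out[prefix + name] = val
        for cname, child in self._children.items():
            out.update(child.state_arrays(prefix + cname + "."))
        return out

    def _local_state(self) -> dict:
        return {}

    # -- execution -----------------------------------------------------------

    def process(self, video: VideoTensor) -> VideoTensor:
        raise NotImplementedError

    def __call__(self, video: VideoTensor):
        if not isinstance(video, VideoTensor):
            raise TypeError(f"expected VideoTensor, got {type(video).__name__}")
        return self.process(video)

    def backward(self, grad_out: np.ndarray) -> np.ndarray | None:
        """Accumulate parameter gradients for the last ``process`` call and
        return the gradient with respect to that call's input (or None)."""
        raise GradientNotAvailable(
            f"{type(self).__name__} does not implement analytic gradients"
        )

    def run(self, video: VideoTensor, dt: int):
        """Chunked execution, mirroring ``run_chunked(self, video, dt)``."""
        return run_chunked(self, video, dt)


def reset_state(model: Layer) -> None:
    """Zero every state buffer reachable from ``model``; parameters are
    untouched."""
    model.reset_state()


def run_chunked(model: Layer, video: VideoTensor, chunk_len: int):
    """Process ``video`` in consecutive time slices of ``chunk_len`` frames.

    State carryover inside the layers makes the concatenated result equal
    (within float tolerance) to one-pass processing; a chunk length longer
    than the video simply yields a single chunk.
    """
    chunk_len = int(chunk_len)
    if chunk_len < 1:
        raise ValueError(f"chunk_len must be >= 1; got {chunk_len}")
    n = video.n_frames
    outputs = []
    for start in range(0, n, chunk_len):
        chunk = video.time_slice(start, min(start + chunk_len, n))
        outputs.append(model(chunk))
    return type(outputs[0]).concatenate(outputs)


def resample(video: VideoTensor, dt_new: float) -> VideoTensor:
    """Linear interpolation in time onto a new grid spanning the same
    ``[t0, t0 + K*dt]`` interval."""
    if not dt_new > 0:
        raise ValueError(f"dt_new must be positive; got {dt_new}")
    n = video.n_frames
    duration = n * video.dt
    n_new = int(round(duration / dt_new))
    if n_new < 2:
        raise ValueError(
            f"dt_new={dt_new} yields {n_new} frame(s); need at least 2"
        )
    t_old = np.arange(n) * video.dt
    t_new = np.arange(n_new) * dt_new
    # clamp to the sampled support so the last interval extrapolates flatly
    t_new = np.clip(t_new, t_old[0], t_old[-1])
    idx = np.clip(np.searchsorted(t_old, t_new, side="right") - 1, 0, n - 2)
    w = (t_new - t_old[idx]) / video.dt
    v = video.values
    shape = (1, 1, n_new, 1, 1)
    w5 = w.reshape(shape)
    out = v[:, :, idx] * (1.0 - w5) + v[:, :, idx + 1] * w5
    return VideoTensor(out, dt=float(dt_new), t0=video.t0)
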