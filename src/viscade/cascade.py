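"""LN-family cascade models and direction-selective 3D kernels.

A cascade is an ordered list of stages, each a linear operator (dense 3D
kernel or recursive exponential) followed by a pointwise nonlinearity and,
optionally, delayed subtractive feedback of the stage's own output onto its
input.  The classic model names map onto cascades as:

========  ====================================================
LN        one stage
LNSN      two stages (subunits, then pooling)
LNSNF     feedback on the second stage
LNFSNF    feedback on both stages
LNFDSNF   feedback on both stages with a longer delay
========  ====================================================

Feedback wiring (not pinned down by the usual model definitions): the
stage output, filtered and delayed by >= 1 frame, is subtracted
gain-weighted from the stage input.  Gain 0 reduces every feedback model
to its feedback-free counterpart exactly.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .filters import (
    Conv3D,
    ExponentialSmooth,
    Kernel3D,
    Nonlinearity,
    NonlinearitySpec,
    conv3d,
)
from .signals import GradientNotAvailable, Layer, VideoTensor

__all__ = [
    "FeedbackSpec",
    "StageSpec",
    "CascadeSpec",
    "DSKernelSpec",
    "Sequential",
    "CascadeStage",
    "CascadeModel",
    "cascade_forward",
    "LN",
    "LNSN",
    "LNSNF",
    "LNFSNF",
    "LNFDSNF",
    "make_ds_kernel",
    "ds_response",
    "direction_tuning",
    "cascade_to_json",
    "cascade_from_json",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FeedbackSpec:
    """Delayed subtractive feedback: ``filter`` is either an exponential
    time constant (seconds) or a dense kernel; ``delay`` >= 1 frame keeps
    the loop causal."""

    tau: float | None = None
    kernel: np.ndarray | None = None
    delay: int = 1
    gain: float = 1.0

    def __post_init__(self):
        if self.delay < 1:
            raise ValueError(f"feedback delay must be >= 1 frame; got {self.delay}")
        if (self.tau is None) == (self.kernel is None):
            raise ValueError("feedback needs exactly one of tau or kernel")


@dataclasses.dataclass
class StageSpec:
    linear: Kernel3D | float  # kernel, or exponential tau (seconds)
    nonlinearity: NonlinearitySpec = dataclasses.field(
        default_factory=NonlinearitySpec
    )
    feedback: FeedbackSpec | None = None


@dataclasses.dataclass
class CascadeSpec:
    stages: list

    def __post_init__(self):
        if len(self.stages) < 1:
            raise ValueError("a cascade needs at least one stage")
        # channel chaining: conv stages must agree out -> in
        prev_out = None
        for i, st in enumerate(self.stages):
            if isinstance(st.linear, Kernel3D):
                o, c = st.linear.weights.shape[:2]
                if prev_out is not None and c != prev_out:
                    raise ValueError(
                        f"stage {i}: expects {c} input channel(s) but stage "
                        f"{i - 1} produces {prev_out}"
                    )
                prev_out = o
            # exponential stages are channel-preserving


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Sequential(Layer):
    """Chain of layers with reverse-mode backward through the chain."""

    def __init__(self, *layers: Layer):
        super().__init__()
        self._n = len(layers)
        for i, lay in enumerate(layers):
            setattr(self, f"stage{i}", lay)

    def layers(self):
        return [getattr(self, f"stage{i}") for i in range(self._n)]

    def process(self, video: VideoTensor) -> VideoTensor:
        out = video
        for lay in self.layers():
            out = lay(out)
        return out

    def backward(self, grad_out: np.ndarray):
        g = grad_out
        for lay in reversed(self.layers()):
            g = lay.backward(g)
            if g is None:
                return None
        return g


class CascadeStage(Layer):
    """One linear+nonlinear stage with optional delayed feedback."""

    def __init__(self, spec: StageSpec):
        super().__init__()
        if isinstance(spec.linear, (Kernel3D, np.ndarray)):
            self.linear = Conv3D(spec.linear)
        else:
            self.linear = ExponentialSmooth(float(spec.linear))
        self.nonlinearity = Nonlinearity(spec.nonlinearity)
        self.feedback_spec = spec.feedback
        if spec.feedback is not None:
            fb = spec.feedback
            if fb.tau is not None:
                self.fb_filter = ExponentialSmooth(fb.tau, trainable=False)
            else:
                self.fb_filter = Conv3D(fb.kernel, trainable=False)
            self._fb_buffer = None  # last `delay` outputs, oldest first
        self._spatial = None

    def _reset_state(self):
        if self.feedback_spec is not None:
            self._fb_buffer = None

    def _local_state(self) -> dict:
        if self.feedback_spec is None:
            return {}
        return {
            "fb_buffer": self._fb_buffer
            if self._fb_buffer is not None
            else np.zeros(0)
        }

    def process(self, video: VideoTensor) -> VideoTensor:
        if self.feedback_spec is None or self.feedback_spec.gain == 0.0:
            # gain 0 reduces exactly to the feedforward model (and avoids
            # the frame-by-frame loop)
            return self.nonlinearity(self.linear(video))
        fb = self.feedback_spec
        x = video.values
        outs = []
        for k in range(x.shape[2]):
            frame = video.time_slice(k, k + 1)
            if self._fb_buffer is None:
                z = np.zeros_like(
                    frame.values
                    if isinstance(self.linear, ExponentialSmooth)
                    else frame.values[:, :1].repeat(
                        self.linear.weight.value.shape[0], axis=1
                    )
                )
                self._fb_buffer = [z.copy() for _ in range(fb.delay)]
            delayed = frame.with_values(self._fb_buffer.pop(0))
            f = self.fb_filter(delayed)
            # feedback is shaped like the stage *output*; subtract it from
            # the input only where channel counts agree (they do for the
            # standard subunit models, which are channel-preserving)
            if f.values.shape != frame.values.shape:
                raise ValueError(
                    "feedback output shape does not match stage input; "
                    "feedback requires channel-preserving stages"
                )
            driven = frame.with_values(frame.values - fb.gain * f.values)
            y = self.nonlinearity(self.linear(driven))
            self._fb_buffer.append(y.values.copy())
            outs.append(y)
        return VideoTensor.concatenate(outs)

    def backward(self, grad_out: np.ndarray):
        if self.feedback_spec is not None and self.feedback_spec.gain != 0.0:
            raise GradientNotAvailable(
                "analytic gradients through the feedback loop are not "
                "implemented; use finite differences"
            )
        g = self.nonlinearity.backward(grad_out)
        return self.linear.backward(g)


class CascadeModel(Sequential):
    """Stages applied in order; with all-linear nonlinearities and no
    feedback this is exactly the composition of the stage convolutions."""

    def __init__(self, spec: CascadeSpec):
        spec = spec if isinstance(spec, CascadeSpec) else CascadeSpec(spec)
        super().__init__(*[CascadeStage(s) for s in spec.stages])
        self.spec = spec


def cascade_forward(video: VideoTensor, spec: CascadeSpec) -> VideoTensor:
    model = CascadeModel(spec)
    model.reset_state()
    return model(video)


# -- named model families ----------------------------------------------------


def _nl(nl) -> NonlinearitySpec:
    if isinstance(nl, NonlinearitySpec):
        return nl
    return NonlinearitySpec(kind=nl)


def LN(kernel, nonlinearity="linear") -> CascadeModel:
    return CascadeModel(CascadeSpec([StageSpec(Kernel3D(kernel), _nl(nonlinearity))]))


def LNSN(kernel1, kernel2, nl1="half_wave", nl2="linear") -> CascadeModel:
    return CascadeModel(
        CascadeSpec(
            [
                StageSpec(Kernel3D(kernel1), _nl(nl1)),
                StageSpec(Kernel3D(kernel2), _nl(nl2)),
            ]
        )
    )


def LNSNF(kernel1, kernel2, nl1="half_wave", nl2="linear",
          fb_tau=0.05, fb_gain=1.0, fb_delay=1) -> CascadeModel:
    return CascadeModel(
        CascadeSpec(
            [
                StageSpec(Kernel3D(kernel1), _nl(nl1)),
                StageSpec(
                    Kernel3D(kernel2),
                    _nl(nl2),
                    FeedbackSpec(tau=fb_tau, gain=fb_gain, delay=fb_delay),
                ),
            ]
        )
    )


def LNFSNF(kernel1, kernel2, nl1="half_wave", nl2="linear",
           fb_tau=0.05, fb_gain=1.0, fb_delay=1) -> CascadeModel:
    fb = lambda: FeedbackSpec(tau=fb_tau, gain=fb_gain, delay=fb_delay)
    return CascadeModel(
        CascadeSpec(
            [
                StageSpec(Kernel3D(kernel1), _nl(nl1), fb()),
                StageSpec(Kernel3D(kernel2), _nl(nl2), fb()),
            ]
        )
    )


def LNFDSNF(kernel1, kernel2, nl1="half_wave", nl2="linear",
            fb_tau=0.05, fb_gain=1.0, fb_delay=5) -> CascadeModel:
    return LNFSNF(kernel1, kernel2, nl1, nl2, fb_tau, fb_gain, fb_delay)


# ---------------------------------------------------------------------------
# direction-selective kernels
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DSKernelSpec:
    """A positive Gaussian travelling across the receptive field, trailed at
    ``trail_lag`` frames by a negative Gaussian on the same track, so only a
    moving edge can excite the cell."""

    direction: float = 0.0  # degrees
    speed: float = 1.0  # px / frame
    sigma: float = 1.5  # px
    trail_lag: int = 2  # frames
    duration: int = 12  # frames
    extent: int = 17  # px

    def __post_init__(self):
        if self.trail_lag < 1:
            raise ValueError(f"trail_lag must be >= 1; got {self.trail_lag}")
        if abs(self.speed) * self.duration > self.extent:
            raise ValueError(
                f"speed*duration = {abs(self.speed) * self.duration} exceeds "
                f"extent {self.extent}: the moving Gaussian leaves the frame"
            )


def make_ds_kernel(spec: DSKernelSpec) -> Kernel3D:
    """Zero-sum direction-selective kernel of shape
    ``(1, 1, duration, extent, extent)``; kernel frames play forward in
    time, so a stimulus travelling with the Gaussian excites maximally."""
    n = spec.extent
    th = np.deg2rad(spec.direction)
    u = np.array([np.cos(th), np.sin(th)])
    mid = (n - 1) / 2.0
    # center the trajectory in the frame
    start = np.array([mid, mid]) - u * spec.speed * (spec.duration - 1) / 2.0
    xg, yg = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")

    def gauss_at(c):
        if not (0 <= c[0] <= n - 1 and 0 <= c[1] <= n - 1):
            raise ValueError(
                f"Gaussian center {tuple(np.round(c, 2))} leaves the "
                f"{n}x{n} spatial extent"
            )
        return np.exp(-((xg - c[0]) ** 2 + (yg - c[1]) ** 2) / (2 * spec.sigma**2))

    frames = np.zeros((spec.duration, n, n))
    for tau in range(spec.duration):
        frames[tau] = gauss_at(start + u * spec.speed * tau)
        lag = tau - spec.trail_lag
        if lag >= 0:
            frames[tau] -= gauss_at(start + u * spec.speed * lag)
    frames -= frames.mean()
    return Kernel3D(frames[None, None])


def ds_response(video: VideoTensor, kernel: Kernel3D) -> np.ndarray:
    """Per-frame response: ``|conv3d(video, kernel)|`` taken per pixel, then
    summed over space (batch and channel folded in)."""
    out = conv3d(video, kernel)
    return np.abs(out.values).sum(axis=(0, 1, 3, 4))


def direction_tuning(
    spec: DSKernelSpec,
    directions,
    stim_shape: tuple | None = None,
    bar_width: float | None = None,
    n_frames: int | None = None,
    dt: float = 1e-3,
) -> tuple:
    """Normalized tuning curve: mean ds_response to a moving bar per
    stimulus direction; max-normalized to 1."""
    from .stimuli import moving_bar

    directions = np.asarray(list(directions), dtype=float)
    if directions.size < 8:
        raise ValueError(f"need >= 8 directions; got {directions.size}")
    kernel = make_ds_kernel(spec)
    shape = stim_shape or (int(1.5 * spec.extent) | 1,) * 2
    width = bar_width if bar_width is not None else max(2.0, 2.0 * spec.sigma)
    speed = abs(spec.speed) / dt  # px/frame -> px/s
    if n_frames is None:
        # enough frames for the bar to cross the longest diagonal
        n_frames = int(np.ceil((np.hypot(*shape) + 2 * width) / abs(spec.speed))) + 1
    responses = np.empty(directions.size)
    for i, d in enumerate(directions):
        stim = moving_bar(shape, dt, width, speed, d, n_frames)
        responses[i] = ds_response(stim, kernel).mean()
    peak = responses.max()
    if peak <= 0:
        raise ValueError("flat zero tuning curve; cannot normalize")
    return directions, responses / peak


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def _nl_to_dict(nl: NonlinearitySpec) -> dict:
    return dataclasses.asdict(nl)


def cascade_to_json(spec: CascadeSpec) -> str:
    stages = []
    for st in spec.stages:
        if isinstance(st.linear, Kernel3D):
            linear = {"type": "conv", "weights": st.linear.weights.tolist()}
        else:
            linear = {"type": "exponential", "tau": float(st.linear)}
        entry = {"linear": linear, "nonlinearity": _nl_to_dict(st.nonlinearity)}
        if st.feedback is not None:
            fb = {
                "delay": st.feedback.delay,
                "gain": st.feedback.gain,
            }
            if st.feedback.tau is not None:
                fb["tau"] = st.feedback.tau
            else:
                fb["kernel"] = st.feedback.kernel.tolist()
            entry["feedback"] = fb
        stages.append(entry)
    return json.dumps({"stages": stages}, indent=2)


def cascade_from_json(text: str) -> CascadeSpec:
    doc = json.loads(text)
    stages = []
    for entry in doc["stages"]:
        lin = entry["linear"]
        if lin["type"] == "conv":
            linear = Kernel3D(np.asarray(lin["weights"], dtype=float))
        elif lin["type"] == "exponential":
            linear = float(lin["tau"])
        else:
            raise ValueError(f"unknown linear stage type {lin['type']!r}")
        nl = NonlinearitySpec(**entry.get("nonlinearity", {}))
        fb = None
        if "feedback" in entry:
            f = dict(entry["feedback"])
            if "kernel" in f:
                f["kernel"] = np.asarray(f["kernel"], dtype=float)
            fb = FeedbackSpec(**f)
        stages.append(StageSpec(linear, nl, fb))
    return CascadeSpec(stages)
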