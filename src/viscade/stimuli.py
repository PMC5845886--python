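"""Seeded stimulus generators.

Every generator is a pure function of its arguments and the seed: identical
calls produce bit-identical movies.  All outputs are :class:`VideoTensor`
objects (except :func:`letters_rf`, which builds a 2D ground-truth
receptive-field image for the fitting experiments).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .signals import VideoTensor, wrap_video

__all__ = [
    "ChirpSpec",
    "GratingSpec",
    "chirp",
    "moving_grating",
    "checkerboard_flicker",
    "moving_bar",
    "gaussian_noise",
    "poisson_events",
    "letters_rf",
    "CONVIS_GLYPH",
]


@dataclasses.dataclass
class ChirpSpec:
    """Full-field chirp: a pulse, a frequency sweep, an amplitude sweep.

    The printed protocols do not fix the numbers, so the defaults below
    (2 s pre, 3 s OFF-ON-OFF pulse, 0->8 Hz over 8 s, amplitude sweep at
    2 Hz over 8 s, dt 1 ms) are documented, overridable choices.
    """

    dt: float = 1e-3
    shape: tuple = (1, 1)
    base: float = 0.5
    amplitude: float = 0.5
    t_pre: float = 2.0
    t_pulse: float = 3.0
    t_freq: float = 8.0
    t_amp: float = 8.0
    t_post: float = 1.0
    f0: float = 0.0
    f1: float = 8.0
    f_amp: float = 2.0
    a0: float = 0.0
    a1: float = 1.0

    def __post_init__(self):
        for name in ("t_pre", "t_pulse", "t_freq", "t_amp", "t_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.f1 >= self.f0 >= 0):
            raise ValueError(f"need f1 >= f0 >= 0; got ({self.f0}, {self.f1})")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


def chirp(spec: ChirpSpec | None = None, **kwargs) -> VideoTensor:
    """Full-field chirp movie; see :class:`ChirpSpec` for the segments."""
    spec = spec or ChirpSpec(**kwargs)
    dt = spec.dt

    def n(t):
        return int(round(t / dt))

    segs = []
    segs.append(np.full(n(spec.t_pre), spec.base))
    # OFF-ON-OFF pulse: dark third, bright third, dark third
    n_pulse = n(spec.t_pulse)
    pulse = np.full(n_pulse, spec.base - spec.amplitude)
    third = n_pulse // 3
    pulse[third:2 * third] = spec.base + spec.amplitude
    segs.append(pulse)
    # linear frequency sweep: phase = 2*pi*(f0*t + (f1-f0)*t^2/(2*T))
    t = np.arange(n(spec.t_freq)) * dt
    T = max(spec.t_freq, dt)
    phase = 2 * np.pi * (spec.f0 * t + (spec.f1 - spec.f0) * t**2 / (2 * T))
    segs.append(spec.base + spec.amplitude * np.sin(phase))
    # amplitude sweep at fixed frequency
    t = np.arange(n(spec.t_amp)) * dt
    T = max(spec.t_amp, dt)
    amp = spec.a0 + (spec.a1 - spec.a0) * t / T
    segs.append(spec.base + spec.amplitude * amp * np.sin(2 * np.pi * spec.f_amp * t))
    segs.append(np.full(n(spec.t_post), spec.base))
    trace = np.concatenate(segs)
    nx, ny = spec.shape
    frames = np.broadcast_to(trace[:, None, None], (trace.size, nx, ny)).copy()
    return wrap_video(frames, dt=dt)


@dataclasses.dataclass
class GratingSpec:
    shape: tuple = (20, 20)
    dt: float = 1e-3
    n_frames: int = 1000
    direction: float = 0.0  # degrees
    speed: float = 10.0  # px / s
    spatial_freq: float = 0.1  # cycles / px
    contrast: float = 1.0
    mean: float = 0.5

    def __post_init__(self):
        if not 0 <= self.contrast <= 1:
            raise ValueError(f"contrast must be in [0, 1]; got {self.contrast}")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


def moving_grating(spec: GratingSpec | None = None, **kwargs) -> VideoTensor:
    """Drifting sinusoidal grating,
    ``L = mean * (1 + contrast * sin(2 pi sf (x cos th + y sin th) - 2 pi sf speed t))``.
    """
    spec = spec or GratingSpec(**kwargs)
    nx, ny = spec.shape
    th = np.deg2rad(spec.direction)
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    proj = x * np.cos(th) + y * np.sin(th)
    t = np.arange(spec.n_frames) * spec.dt
    phase = (
        2 * np.pi * spec.spatial_freq * proj[None]
        - 2 * np.pi * spec.spatial_freq * spec.speed * t[:, None, None]
    )
    frames = spec.mean * (1.0 + spec.contrast * np.sin(phase))
    return wrap_video(frames, dt=spec.dt)


def checkerboard_flicker(
    shape: tuple,
    dt: float,
    box_px: int,
    n_frames: int,
    seed: int = 0,
    mean: float = 0.5,
    amplitude: float = 0.5,
) -> VideoTensor:
    """Random binary checkerboard: each box flips independently to
    ``mean - amplitude`` or ``mean + amplitude`` every frame."""
    nx, ny = shape
    if box_px < 1:
        raise ValueError("box_px must be >= 1")
    rng = np.random.default_rng(seed)
    bx = -(-nx // box_px)  # ceil; edge boxes truncated
    by = -(-ny // box_px)
    signs = rng.integers(0, 2, size=(n_frames, bx, by)) * 2 - 1
    frames = np.repeat(np.repeat(signs, box_px, axis=1), box_px, axis=2)
    frames = frames[:, :nx, :ny].astype(float)
    return wrap_video(mean + amplitude * frames, dt=dt)


def moving_bar(
    shape: tuple,
    dt: float,
    width_px: float,
    speed: float,
    direction: float,
    n_frames: int,
    foreground: float = 1.0,
    background: float = 0.0,
) -> VideoTensor:
    """A bright bar of the given width translating at ``speed`` px/s along
    ``direction`` (degrees), entering from outside the frame."""
    nx, ny = shape
    th = np.deg2rad(direction)
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    proj = x * np.cos(th) + y * np.sin(th)
    lo, hi = proj.min(), proj.max()
    t = np.arange(n_frames) * dt
    # bar center travels from just before the frame to just after it
    start = lo - width_px
    center = start + speed * t
    dist = np.abs(proj[None] - center[:, None, None])
    frames = np.where(dist <= width_px / 2.0, foreground, background)
    return wrap_video(frames, dt=dt)


def gaussian_noise(
    shape: tuple,
    dt: float,
    n_frames: int,
    mean: float = 0.5,
    level: float = 0.2,
    seed: int = 0,
) -> VideoTensor:
    """I.i.d. normal luminance per pixel per frame with standard deviation
    ``level``."""
    if level < 0:
        raise ValueError("level must be >= 0")
    rng = np.random.default_rng(seed)
    frames = mean + level * rng.standard_normal((n_frames,) + tuple(shape))
    return wrap_video(frames, dt=dt)


def poisson_events(
    rate_hz: float, duration_s: float, dt: float, seed: int = 0
) -> VideoTensor:
    """Single-pixel event train: per frame an event fires with probability
    ``rate * dt`` (Bernoulli thinning, exact on the discrete grid)."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    p = rate_hz * dt
    if p > 0.2:
        import warnings

        warnings.warn(
            f"rate*dt = {p:.3g} > 0.2: Bernoulli thinning is a poor Poisson "
            f"approximation at this resolution",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt))
    frames = (rng.random(n) < p).astype(float)[:, None, None]
    return wrap_video(frames, dt=dt)


# 16x16 binary raster: "con" on the upper half, "vis" on the lower half,
# drawn from a hand-coded 4x6 pixel font so the receptive-field recovery
# experiment needs no font files.
_FONT = {
    "c": ["0111", "1000", "1000", "1000", "1000", "0111"],
    "o": ["0110", "1001", "1001", "1001", "1001", "0110"],
    "n": ["1001", "1101", "1011", "1001", "1001", "1001"],
    "v": ["1001", "1001", "1001", "1001", "0110", "0110"],
    "i": ["0110", "0000", "0110", "0110", "0110", "0110"],
    "s": ["0111", "1000", "0110", "0001", "0001", "1110"],
}


def _render_word(word: str) -> np.ndarray:
    cols = []
    for i, ch in enumerate(word):
        glyph = np.array([[int(c) for c in row] for row in _FONT[ch]])
        cols.append(glyph)
        if i < len(word) - 1:
            cols.append(np.zeros((6, 1), dtype=int))
    return np.concatenate(cols, axis=1)


def _build_convis_glyph() -> np.ndarray:
    raster = np.zeros((16, 16), dtype=float)
    top = _render_word("con")  # 6 x 14
    bot = _render_word("vis")
    raster[1:7, 1:1 + top.shape[1]] = top
    raster[9:15, 1:1 + bot.shape[1]] = bot
    return raster


CONVIS_GLYPH = _build_convis_glyph()


def letters_rf(
    shape: tuple = (16, 16),
    mask_pattern: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Ground-truth spatial receptive field: a binary letter raster plus
    i.i.d. normal noise of standard deviation ``noise_sigma``."""
    if mask_pattern is None:
        mask_pattern = CONVIS_GLYPH
    mask = np.asarray(mask_pattern, dtype=float)
    if set(np.unique(mask)) - {0.0, 1.0}:
        raise ValueError("mask_pattern must be binary")
    if mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} != requested shape {tuple(shape)}")
    rng = np.random.default_rng(seed)
    return mask + noise_sigma * rng.standard_normal(mask.shape)
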