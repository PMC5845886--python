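"""Linear filtering primitives and pointwise nonlinearities.

Two complementary filter families are provided.  Dense 3D convolution
(:class:`Conv3D`) realizes arbitrary, non-separable spatio-temporal
receptive fields at the cost of one weight per tap.  Recursive (IIR)
filters (:class:`TemporalIIR`, :class:`ExponentialSmooth`,
:class:`RecursiveGaussian2D`) realize restricted shapes — exponentials in
time, axis-aligned Gaussians in space — with a handful of coefficients.
:class:`SoftConvBank` is the hybrid: fixed recursive temporal filters of
increasing length multiplied by trainable spatial kernels.

Conventions
-----------
* Temporal filtering is causal: output frame ``k`` depends on input frames
  ``k - k_t + 1 .. k``, with zero history before the start of the signal
  (or the layer's state buffer when streaming).
* Spatial convolution is same-size with centered zero padding; for even
  kernel sizes the center tie is broken toward earlier indices.
* In a dense kernel the *last* time slice is aligned with the current
  frame, so kernel frames read in temporal order like the stimulus they
  match.
* All gradients are computed analytically (reverse mode for convolutions
  and pointwise maps, forward sensitivities for recursion coefficients)
  and are validated against central finite differences in the test suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as _sig

from .signals import (
    GradientNotAvailable,
    Layer,
    Parameter,
    VideoTensor,
)

__all__ = [
    "Kernel3D",
    "IIRFilter",
    "ExponentialParams",
    "GaussianParams",
    "NonlinearitySpec",
    "Conv3D",
    "TemporalIIR",
    "ExponentialSmooth",
    "RecursiveGaussian2D",
    "SoftConvBank",
    "Nonlinearity",
    "conv3d",
    "iir_temporal",
    "exp_smooth",
    "recursive_gaussian2d",
    "softconv",
    "apply_nonlinearity",
    "save_kernel",
    "load_kernel",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Kernel3D:
    """Dense convolution weights ``(out_channels, in_channels, t, x, y)``."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim == 3:  # (t, x, y) convenience form
            self.weights = self.weights[None, None]
        if self.weights.ndim != 5:
            raise ValueError(
                f"Kernel3D requires 5 axes (out, in, t, x, y); got {self.weights.shape}"
            )
        if min(self.weights.shape) < 1:
            raise ValueError(f"all kernel axes must be >= 1; got {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")

    @property
    def shape(self):
        return self.weights.shape


@dataclasses.dataclass
class IIRFilter:
    """Recursive filter ``Y(k) = sum_j b_j X(k-j) - sum_{i=1..N} a_i Y(k-i)``.

    ``b`` has length M >= 1 over current and past inputs; ``a`` has length
    N >= 0 over past outputs.  Stability is not enforced but can be queried.
    """

    b: np.ndarray
    a: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float)) if np.size(self.a) else np.zeros(0)
        if self.b.size < 1:
            raise ValueError("b must have at least one coefficient")
        if not (np.all(np.isfinite(self.b)) and np.all(np.isfinite(self.a))):
            raise ValueError("filter coefficients must be finite")

    def is_stable(self) -> bool:
        """All roots of the characteristic polynomial inside the unit circle."""
        if self.a.size == 0:
            return True
        roots = np.roots(np.concatenate(([1.0], self.a)))
        return bool(np.all(np.abs(roots) < 1.0))


@dataclasses.dataclass
class ExponentialParams:
    tau: float

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError(f"tau must be positive; got {self.tau}")


@dataclasses.dataclass
class GaussianParams:
    sigma_x: float
    sigma_y: float

    def __post_init__(self):
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise ValueError(
                f"sigmas must be positive; got ({self.sigma_x}, {self.sigma_y})"
            )


_NL_KINDS = ("linear", "half_wave", "square", "threshold", "sigmoid", "tanh")


@dataclasses.dataclass
class NonlinearitySpec:
    """Pointwise nonlinearity.

    ``threshold`` outputs exact 0/1 but exposes a boxcar surrogate gradient
    of width ``surrogate_width`` around ``theta`` (the true derivative is
    zero almost everywhere); set ``gradient_policy='none'`` to make any
    gradient request an explicit error instead.
    """

    kind: str = "linear"
    theta: float = 0.0
    slope: float = 1.0
    surrogate_width: float = 1.0
    gradient_policy: str = "surrogate"

    def __post_init__(self):
        if self.kind not in _NL_KINDS:
            raise ValueError(f"unknown nonlinearity {self.kind!r}; choose from {_NL_KINDS}")


# ---------------------------------------------------------------------------
# dense 3D convolution
# ---------------------------------------------------------------------------


def _spatial_centers(kx: int, ky: int) -> tuple:
    # tie toward earlier indices for even sizes
    return (kx - 1) // 2, (ky - 1) // 2


class Conv3D(Layer):
    """Dense spatio-temporal convolution, causal in time, same-size in space.

    Output channel ``o`` at frame ``k`` is
    ``sum_c sum_{tau,u,v} w[o,c,tau,u,v] * x[c, k-k_t+1+tau, i+u-cx, j+v-cy]``
    with zero padding in space and zero history (or the state buffer) in time.
    """

    def __init__(self, kernel, trainable: bool = True):
        super().__init__()
        k = kernel if isinstance(kernel, Kernel3D) else Kernel3D(kernel)
        self.weight = Parameter(k.weights, trainable=trainable)
        self._tail = None  # last k_t - 1 input frames
        self._cache = None

    @property
    def kernel(self) -> Kernel3D:
        return Kernel3D(self.weight.value)

    def _reset_state(self):
        self._tail = None
        self._cache = None

    def _local_state(self) -> dict:
        kt = self.weight.value.shape[2]
        if kt == 1:
            return {}
        return {"tail": self._tail if self._tail is not None else np.zeros(0)}

    def process(self, video: VideoTensor) -> VideoTensor:
        w = self.weight.value
        o_ch, i_ch, kt, kx, ky = w.shape
        x = video.values
        if x.shape[1] != i_ch:
            raise ValueError(
                f"channel mismatch: kernel expects {i_ch} input channel(s), "
                f"video has {x.shape[1]}"
            )
        b, _, t, nx, ny = x.shape
        if self._tail is None:
            history = np.zeros((b, i_ch, kt - 1, nx, ny))
        else:
            history = self._tail
            if history.shape != (b, i_ch, kt - 1, nx, ny):
                raise ValueError(
                    f"mid-stream shape change: state {history.shape[0:2] + history.shape[3:]} "
                    f"vs input {x.shape[0:2] + x.shape[3:]}"
                )
        cx, cy = _spatial_centers(kx, ky)
        xt = np.concatenate([history, x], axis=2) if kt > 1 else x
        xp = np.pad(xt, ((0, 0), (0, 0), (0, 0), (cx, kx - 1 - cx), (cy, ky - 1 - cy)))
        out = np.zeros((b, o_ch, t, nx, ny))
        for bi in range(b):
            for oc in range(o_ch):
                acc = None
                for ic in range(i_ch):
                    r = _sig.correlate(xp[bi, ic], w[oc, ic], mode="valid")
                    acc = r if acc is None else acc + r
                out[bi, oc] = acc
        if kt > 1:
            self._tail = xt[:, :, -(kt - 1):].copy()
        self._cache = (xp, x.shape)
        return video.with_values(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise GradientNotAvailable("backward called before process")
        xp, x_shape = self._cache
        w = self.weight.value
        o_ch, i_ch, kt, kx, ky = w.shape
        b, _, t, nx, ny = x_shape
        cx, cy = _spatial_centers(kx, ky)
        g = np.asarray(grad_out)
        if self.weight.trainable:
            gw = np.zeros_like(w)
            for oc in range(o_ch):
                for ic in range(i_ch):
                    for bi in range(b):
                        # auto method selection badly misjudges this
                        # long-kernel correlation; FFT is much faster here
                        gw[oc, ic] += _sig.correlate(
                            xp[bi, ic], g[bi, oc], mode="valid", method="fft"
                        )
            self.weight.add_grad(gw)
        gin = np.zeros(x_shape)
        for bi in range(b):
            for ic in range(i_ch):
                acc = None
                for oc in range(o_ch):
                    r = _sig.convolve(g[bi, oc], w[oc, ic], mode="full")
                    acc = r if acc is None else acc + r
                # drop history frames and spatial padding
                gin[bi, ic] = acc[kt - 1:, cx:cx + nx, cy:cy + ny]
        return gin


def conv3d(video: VideoTensor, kernel) -> VideoTensor:
    """One-pass dense convolution with zero initial history."""
    layer = Conv3D(kernel)
    layer.reset_state()
    return layer(video)


# ---------------------------------------------------------------------------
# recursive temporal filters
# ---------------------------------------------------------------------------


class TemporalIIR(Layer):
    """Per-pixel recursive filter applied along the time axis.

    Realizes ``Y(k) = sum_{j=0}^{M-1} b_j X(k-j) - sum_{i=1}^{N} a_i Y(k-i)``
    in temporally correct order via a direct-form state that is carried
    across chunks.
    """

    def __init__(self, filt: IIRFilter):
        super().__init__()
        if not isinstance(filt, IIRFilter):
            filt = IIRFilter(*filt)
        self.b = Parameter(filt.b, trainable=False)
        self.a = Parameter(filt.a, trainable=False) if filt.a.size else Parameter(
            np.zeros(0), trainable=False
        )
        self._zi = None

    @property
    def filt(self) -> IIRFilter:
        return IIRFilter(self.b.value, self.a.value)

    def _scipy_ba(self):
        return self.b.value, np.concatenate(([1.0], self.a.value))

    def _reset_state(self):
        self._zi = None

    def _local_state(self) -> dict:
        return {"zi": self._zi if self._zi is not None else np.zeros(0)}

    def process(self, video: VideoTensor) -> VideoTensor:
        b, a = self._scipy_ba()
        x = video.values
        order = max(len(b), len(a)) - 1
        if order == 0:
            return video.with_values(b[0] * x)
        if self._zi is None:
            zi_shape = list(x.shape)
            zi_shape[2] = order
            self._zi = np.zeros(zi_shape)
        elif self._zi.shape[:2] + self._zi.shape[3:] != x.shape[:2] + x.shape[3:]:
            raise ValueError("mid-stream shape change in TemporalIIR")
        y, zf = _sig.lfilter(b, a, x, axis=2, zi=self._zi)
        self._zi = zf
        return video.with_values(y)


def iir_temporal(video: VideoTensor, filt: IIRFilter) -> VideoTensor:
    layer = TemporalIIR(filt)
    layer.reset_state()
    return layer(video)


class ExponentialSmooth(Layer):
    """First-order low-pass with unit DC gain:
    ``Y(k) = (1 - lam) X(k) + lam Y(k-1)``, ``lam = exp(-dt / tau)``.

    ``tau`` is the single trainable parameter; its gradient is propagated
    by an exact forward sensitivity recursion.
    """

    def __init__(self, tau: float, trainable: bool = True):
        super().__init__()
        if not tau > 0:
            raise ValueError(f"tau must be positive; got {tau}")
        self.tau = Parameter(float(tau), trainable=trainable)
        self._zi = None
        self._cache = None

    def _reset_state(self):
        self._zi = None
        self._cache = None

    def _local_state(self) -> dict:
        return {"zi": self._zi if self._zi is not None else np.zeros(0)}

    def _lam(self, dt: float) -> float:
        tau = float(self.tau.value)
        if not tau > 0:
            raise ValueError(f"tau must be positive; got {tau}")
        return float(np.exp(-dt / tau))

    def process(self, video: VideoTensor) -> VideoTensor:
        lam = self._lam(video.dt)
        x = video.values
        b = np.array([1.0 - lam])
        a = np.array([1.0, -lam])
        if self._zi is None:
            zi_shape = list(x.shape)
            zi_shape[2] = 1
            self._zi = np.zeros(zi_shape)
        y_prev0 = self._zi[:, :, 0] / lam if lam > 0 else np.zeros(x.shape[:2] + x.shape[3:])
        y, zf = _sig.lfilter(b, a, x, axis=2, zi=self._zi)
        self._zi = zf
        self._cache = (x, y, y_prev0, video.dt)
        return video.with_values(y)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise GradientNotAvailable("backward called before process")
        x, y, y_prev0, dt = self._cache
        lam = self._lam(dt)
        g = np.asarray(grad_out)
        if self.tau.trainable:
            tau = float(self.tau.value)
            dlam = lam * dt / tau**2
            y_prev = np.concatenate([y_prev0[:, :, None], y[:, :, :-1]], axis=2)
            drive = dlam * (y_prev - x)
            s = _sig.lfilter([1.0], [1.0, -lam], drive, axis=2)
            self.tau.add_grad(np.sum(g * s))
        # adjoint of the causal recursion is the anti-causal recursion
        grev = _sig.lfilter([1.0], [1.0, -lam], g[:, :, ::-1], axis=2)[:, :, ::-1]
        return (1.0 - lam) * grev


def exp_smooth(video: VideoTensor, p) -> VideoTensor:
    tau = p.tau if isinstance(p, ExponentialParams) else float(p)
    layer = ExponentialSmooth(tau)
    layer.reset_state()
    return layer(video)


# ---------------------------------------------------------------------------
# recursive Gaussian (4th-order Deriche: sum of a causal and an anti-causal
# recursive pass per axis)
# ---------------------------------------------------------------------------

# damped-cosine components of the causal half-impulse-response,
# (amplitude_cos, amplitude_sin, damping, frequency) in units of 1/sigma
_DERICHE_CONST = (
    (1.6800, 3.7350, 1.7830, 0.6318),
    (-0.6803, -0.2598, 1.7230, 1.9970),
)


def _deriche_coeffs(sigma: float):
    """Causal/anti-causal numerators and the shared denominator for one axis."""
    sections = []
    for amp_c, amp_s, lam, om in _DERICHE_CONST:
        e = np.exp(-lam / sigma)
        c, s = np.cos(om / sigma), np.sin(om / sigma)
        num = np.array([amp_c, e * (amp_s * s - amp_c * c)])
        den = np.array([1.0, -2.0 * e * c, e * e])
        sections.append((num, den))
    n_p = np.polymul(sections[0][0], sections[1][1]) + np.polymul(
        sections[1][0], sections[0][1]
    )
    den = np.polymul(sections[0][1], sections[1][1])
    n_causal = np.concatenate([n_p, [0.0]])  # taps z^0 .. z^-4
    # anti-causal taps z^-1..z^-4 on the reversed signal; the z^0 tap is
    # removed so the n=0 sample is counted once
    n_anti = np.concatenate([[0.0], n_causal[1:] - den[1:] * n_causal[0]])
    dc = (n_causal.sum() + n_anti.sum()) / den.sum()
    return n_causal / dc, n_anti / dc, den


def _dense_gauss_taps(sigma: float) -> np.ndarray:
    r = max(1, int(np.ceil(4.0 * sigma)))
    t = np.arange(-r, r + 1)
    g = np.exp(-0.5 * (t / sigma) ** 2)
    return g / g.sum()


def _smooth_axis(x: np.ndarray, sigma: float, axis: int) -> np.ndarray:
    """Unit-DC-gain Gaussian smoothing along one axis.

    sigma >= 0.5 uses the recursive approximation; below 0.5 a dense sampled
    kernel is used instead (the recursive fit degrades there).  Both passes
    are initialized at steady state, so constant fields stay constant and
    edges behave like edge replication.
    """
    if sigma < 0.5:
        from scipy import ndimage

        taps = _dense_gauss_taps(sigma)
        return ndimage.correlate1d(x, taps, axis=axis, mode="nearest")
    n_c, n_a, den = _deriche_coeffs(sigma)
    xm = np.moveaxis(x, axis, -1)
    zi_c = _sig.lfilter_zi(n_c, den)
    y_c, _ = _sig.lfilter(n_c, den, xm, axis=-1, zi=zi_c * xm[..., :1])
    xr = xm[..., ::-1]
    zi_a = _sig.lfilter_zi(n_a, den)
    y_a, _ = _sig.lfilter(n_a, den, xr, axis=-1, zi=zi_a * xr[..., :1])
    return np.moveaxis(y_c + y_a[..., ::-1], -1, axis)


def gauss2d_array(values: np.ndarray, sigma_x: float, sigma_y: float) -> np.ndarray:
    """Separable x-then-y Gaussian smoothing of the last two axes."""
    out = _smooth_axis(values, sigma_x, axis=values.ndim - 2)
    return _smooth_axis(out, sigma_y, axis=values.ndim - 1)


class RecursiveGaussian2D(Layer):
    """Spatial Gaussian blur (axis-aligned, possibly anisotropic); stateless
    in time."""

    def __init__(self, sigma_x: float, sigma_y: float | None = None):
        super().__init__()
        if sigma_y is None:
            sigma_y = sigma_x
        if not (sigma_x > 0 and sigma_y > 0):
            raise ValueError(f"sigmas must be positive; got ({sigma_x}, {sigma_y})")
        self.sigma_x = Parameter(float(sigma_x), trainable=False)
        self.sigma_y = Parameter(float(sigma_y), trainable=False)

    def process(self, video: VideoTensor) -> VideoTensor:
        out = gauss2d_array(
            video.values, float(self.sigma_x.value), float(self.sigma_y.value)
        )
        return video.with_values(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        # the smoothing operator is (approximately) self-adjoint in the
        # interior; sigmas are not trainable, so only the input gradient
        # is propagated
        return gauss2d_array(
            np.asarray(grad_out), float(self.sigma_x.value), float(self.sigma_y.value)
        )


def recursive_gaussian2d(video: VideoTensor, p) -> VideoTensor:
    if isinstance(p, GaussianParams):
        sx, sy = p.sigma_x, p.sigma_y
    else:
        sx = sy = float(p)
    return RecursiveGaussian2D(sx, sy)(video)


# ---------------------------------------------------------------------------
# SoftConv hybrid
# ---------------------------------------------------------------------------


class SoftConvBank(Layer):
    """Sum over K branches of (fixed exponential temporal filter) followed by
    a trainable 2D spatial kernel.  The taus never receive gradients."""

    def __init__(self, taus, spatial_kernels):
        super().__init__()
        taus = [float(t) for t in taus]
        if len(taus) < 1:
            raise ValueError("need at least one tau")
        if any(t2 <= t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError(f"taus must be strictly increasing; got {taus}")
        kernels = np.asarray(spatial_kernels, dtype=float)
        if kernels.ndim != 3 or kernels.shape[0] != len(taus):
            raise ValueError(
                f"spatial_kernels must have shape (K, kx, ky) with K={len(taus)}; "
                f"got {kernels.shape}"
            )
        self.taus = tuple(taus)
        for k, tau in enumerate(taus):
            setattr(self, f"smooth{k}", ExponentialSmooth(tau, trainable=False))
            setattr(self, f"conv{k}", Conv3D(kernels[k][None, None, None], trainable=True))

    @property
    def spatial_kernels(self) -> np.ndarray:
        return np.stack(
            [getattr(self, f"conv{k}").weight.value[0, 0, 0] for k in range(len(self.taus))]
        )

    def process(self, video: VideoTensor) -> VideoTensor:
        out = None
        for k in range(len(self.taus)):
            branch = getattr(self, f"conv{k}")(getattr(self, f"smooth{k}")(video))
            out = branch.values if out is None else out + branch.values
        return video.with_values(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        gin = None
        for k in range(len(self.taus)):
            g = getattr(self, f"conv{k}").backward(grad_out)
            g = getattr(self, f"smooth{k}").backward(g)
            gin = g if gin is None else gin + g
        return gin


def softconv(video: VideoTensor, bank: SoftConvBank) -> VideoTensor:
    bank.reset_state()
    return bank(video)


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------


class Nonlinearity(Layer):
    """Stateless pointwise map; ``theta``/``slope`` are trainable where the
    kind uses them (sigmoid, tanh, threshold-with-surrogate)."""

    def __init__(self, spec: NonlinearitySpec | str = "linear"):
        super().__init__()
        if isinstance(spec, str):
            spec = NonlinearitySpec(kind=spec)
        self.spec = spec
        uses_theta = spec.kind in ("threshold", "sigmoid")
        uses_slope = spec.kind in ("sigmoid", "tanh")
        self.theta = Parameter(spec.theta, trainable=uses_theta)
        self.slope = Parameter(spec.slope, trainable=uses_slope)
        self._cache = None

    def process(self, video: VideoTensor) -> VideoTensor:
        v = video.values
        kind = self.spec.kind
        th = float(self.theta.value)
        sl = float(self.slope.value)
        if kind == "linear":
            out = v.copy()
        elif kind == "half_wave":
            out = np.maximum(0.0, v)
        elif kind == "square":
            out = v * v
        elif kind == "threshold":
            out = (v > th).astype(float)
        elif kind == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-sl * (v - th)))
        elif kind == "tanh":
            out = np.tanh(sl * v)
        else:  # pragma: no cover - guarded by the spec dataclass
            raise ValueError(f"unknown nonlinearity {kind!r}")
        self._cache = (v, out)
        return video.with_values(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise GradientNotAvailable("backward called before process")
        v, out = self._cache
        g = np.asarray(grad_out)
        kind = self.spec.kind
        th = float(self.theta.value)
        sl = float(self.slope.value)
        if kind == "linear":
            return g.copy()
        if kind == "half_wave":
            return g * (v > 0.0)
        if kind == "square":
            return g * 2.0 * v
        if kind == "threshold":
            if self.spec.gradient_policy != "surrogate":
                raise GradientNotAvailable(
                    "threshold nonlinearity has zero gradient almost everywhere; "
                    "enable gradient_policy='surrogate' to optimize through it"
                )
            w = self.spec.surrogate_width
            box = (np.abs(v - th) <= w / 2.0) / w
            if self.theta.trainable:
                self.theta.add_grad(-np.sum(g * box))
            return g * box
        if kind == "sigmoid":
            d = out * (1.0 - out)
            if self.slope.trainable:
                self.slope.add_grad(np.sum(g * d * (v - th)))
            if self.theta.trainable:
                self.theta.add_grad(-np.sum(g * d * sl))
            return g * d * sl
        if kind == "tanh":
            d = 1.0 - out * out
            if self.slope.trainable:
                self.slope.add_grad(np.sum(g * d * v))
            return g * d * sl
        raise ValueError(f"unknown nonlinearity {kind!r}")  # pragma: no cover


def apply_nonlinearity(video: VideoTensor, nl: NonlinearitySpec | str) -> VideoTensor:
    return Nonlinearity(nl)(video)


# ---------------------------------------------------------------------------
# npy serialization for kernels
# ---------------------------------------------------------------------------


def save_kernel(path, kernel: Kernel3D) -> None:
    k = kernel if isinstance(kernel, Kernel3D) else Kernel3D(kernel)
    np.save(path, k.weights)


def load_kernel(path) -> Kernel3D:
    w = np.load(path)
    if w.ndim not in (3, 5):
        raise ValueError(
            f"kernel file must hold a 3D or 5D array; got shape {w.shape}"
        )
    return Kernel3D(w)
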