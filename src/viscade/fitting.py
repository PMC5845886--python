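"""Gradient-based parameter estimation and model diagnostics.

The gradient contract
---------------------
Every trainable parameter exposes a gradient of a scalar loss through the
package's *analytic* backend: reverse-mode rules for convolutions and
pointwise maps, exact forward sensitivities for the recursive filters and
the gain-control integrator.  :func:`finite_difference_gradients` provides
the independent central-difference route; the two must agree to a relative
error < 1e-4 on unit-scale problems, and the test suite enforces this for
every trainable parameter class.

Optimizers
----------
``gradient_descent``, ``momentum``, ``adaptive`` (Adam) and
``quasi_newton_limited_memory`` (scipy's L-BFGS-B, warm-started).  One
*outer step* is one optimizer update call; for the quasi-Newton method an
outer step may run up to ``inner_cap`` internal line-search iterations.
All step-count claims use this definition.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize as _opt

from .signals import Layer, VideoTensor

__all__ = [
    "OptimizerSpec",
    "FitResult",
    "loss_mse",
    "param_gradients",
    "finite_difference_gradients",
    "fit",
    "scan_error_curve",
    "hessian_pair",
    "optimize_stimulus",
    "fraction_variance_explained",
]


_METHODS = (
    "gradient_descent",
    "momentum",
    "adaptive",
    "quasi_newton_limited_memory",
)


@dataclasses.dataclass
class OptimizerSpec:
    method: str = "adaptive"
    lr: float = 0.01
    max_steps: int = 100
    inner_cap: int = 20  # quasi-Newton line-search iterations per outer step
    tol: float = 0.0  # absolute convergence tolerance on the loss
    momentum: float = 0.9
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {_METHODS}")
        if not self.lr >= 0:
            raise ValueError("learning rate must be >= 0")
        if self.max_steps < 1 or self.inner_cap < 1:
            raise ValueError("step caps must be >= 1")


@dataclasses.dataclass
class FitResult:
    param_names: list
    snapshots: list  # per outer step: dict name -> array copy (incl. start)
    loss_trace: np.ndarray  # length steps + 1
    grad_norms: np.ndarray
    final_params: dict
    steps: int
    converged: bool


def _values(a) -> np.ndarray:
    return a.values if isinstance(a, VideoTensor) else np.asarray(a, dtype=float)


def loss_mse(a, b) -> float:
    """Mean squared difference over all elements."""
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    return float(np.mean((av - bv) ** 2))


def _forward_loss(model: Layer, x: VideoTensor, y) -> tuple:
    """Reset state, run the model, return (loss, residual-gradient, output)."""
    model.reset_state()
    out = model(x)
    ov, yv = _values(out), _values(y)
    if ov.shape != yv.shape:
        raise ValueError(f"model output shape {ov.shape} != target {yv.shape}")
    resid = ov - yv
    loss = float(np.mean(resid**2))
    gout = 2.0 * resid / resid.size
    return loss, gout, out


def _trainable(model: Layer, params=None) -> dict:
    named = model.named_parameters()
    if params is None:
        return {k: p for k, p in named.items() if p.trainable}
    return {k: named[k] for k in params}


def param_gradients(model: Layer, x: VideoTensor, y, params=None) -> dict:
    """Analytic gradient of the MSE loss w.r.t. every trainable parameter
    (or the named subset).  The model must be deterministic."""
    wanted = _trainable(model, params)
    model.zero_grad()
    _, gout, _ = _forward_loss(model, x, y)
    model.backward(gout)
    return {k: np.array(p.grad) for k, p in wanted.items()}


def finite_difference_gradients(
    model: Layer, x: VideoTensor, y, params=None, step: float = 1e-4,
    relative: bool = False,
) -> dict:
    """Central finite differences of the MSE loss; the independent oracle
    for the analytic backend.  ``relative=True`` scales the step by the
    parameter magnitude (useful for taus)."""
    wanted = _trainable(model, params)
    grads = {}
    for name, p in wanted.items():
        g = np.zeros_like(p.value)
        flat = p.value.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            h = step * max(abs(flat[i]), 1.0) if relative else step
            orig = flat[i]
            flat[i] = orig + h
            lp, _, _ = _forward_loss(model, x, y)
            flat[i] = orig - h
            lm, _, _ = _forward_loss(model, x, y)
            flat[i] = orig
            gflat[i] = (lp - lm) / (2 * h)
        grads[name] = g
    return grads


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def _pack(params: dict) -> np.ndarray:
    return np.concatenate([p.value.reshape(-1) for p in params.values()]) if params else np.zeros(0)


def _unpack(vec: np.ndarray, params: dict):
    i = 0
    for p in params.values():
        n = p.value.size
        p.value = vec[i:i + n].reshape(p.value.shape).copy()
        i += n


def fit(model: Layer, x: VideoTensor, y, opt: OptimizerSpec, params=None) -> FitResult:
    """Fit the model so that input ``x`` produces output ``y`` under MSE.

    Loss and parameters are recorded at every outer step; a loss exceeding
    1e6 times the initial loss aborts with a diagnostic.
    """
    wanted = _trainable(model, params)
    if not wanted:
        raise ValueError("no trainable parameters selected")
    names = list(wanted)

    def closure(vec):
        _unpack(vec, wanted)
        model.zero_grad()
        loss, gout, _ = _forward_loss(model, x, y)
        model.backward(gout)
        grad = np.concatenate([wanted[n].grad.reshape(-1) for n in names])
        return loss, grad

    vec = _pack(wanted)
    loss0, grad = closure(vec)
    snapshots = [{n: wanted[n].value.copy() for n in names}]
    loss_trace = [loss0]
    grad_norms = [float(np.linalg.norm(grad))]
    converged = loss0 <= opt.tol
    steps = 0
    velocity = np.zeros_like(vec)
    m1 = np.zeros_like(vec)
    m2 = np.zeros_like(vec)

    for step_idx in range(1, opt.max_steps + 1):
        if converged:
            break
        if opt.method == "quasi_newton_limited_memory":
            res = _opt.minimize(
                closure,
                vec,
                jac=True,
                method="L-BFGS-B",
                options={
                    "maxiter": opt.inner_cap,
                    "ftol": 0.0,
                    "gtol": 0.0,
                    "maxls": 40,
                },
            )
            vec = res.x
        elif opt.method == "gradient_descent":
            vec = vec - opt.lr * grad
        elif opt.method == "momentum":
            velocity = opt.momentum * velocity - opt.lr * grad
            vec = vec + velocity
        elif opt.method == "adaptive":
            m1 = opt.beta1 * m1 + (1 - opt.beta1) * grad
            m2 = opt.beta2 * m2 + (1 - opt.beta2) * grad**2
            mh = m1 / (1 - opt.beta1**step_idx)
            vh = m2 / (1 - opt.beta2**step_idx)
            vec = vec - opt.lr * mh / (np.sqrt(vh) + opt.eps)
        loss, grad = closure(vec)
        steps = step_idx
        loss_trace.append(loss)
        grad_norms.append(float(np.linalg.norm(grad)))
        snapshots.append({n: wanted[n].value.copy() for n in names})
        if loss > 1e6 * max(loss0, np.finfo(float).tiny):
            raise RuntimeError(
                f"optimization diverged at outer step {step_idx}: "
                f"loss {loss:.3e} > 1e6 x initial {loss0:.3e}"
            )
        if loss <= opt.tol:
            converged = True

    _unpack(vec, wanted)
    return FitResult(
        param_names=names,
        snapshots=snapshots,
        loss_trace=np.asarray(loss_trace),
        grad_norms=np.asarray(grad_norms),
        final_params={n: wanted[n].value.copy() for n in names},
        steps=steps,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ErrorCurve:
    grid: np.ndarray
    losses: np.ndarray
    gradients: np.ndarray
    unimodal: bool
    sign_change_index: int | None  # gradient crosses - to + between i and i+1


def scan_error_curve(model_factory, param_name: str, grid, x: VideoTensor,
                     target) -> ErrorCurve:
    """Loss and analytic gradient along one parameter axis, all other
    parameters held at the factory (ground-truth) values."""
    grid = np.asarray(list(grid), dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    losses = np.empty(grid.size)
    grads = np.empty(grid.size)
    for i, val in enumerate(grid):
        model = model_factory()
        model.set_parameter(param_name, val)
        model.zero_grad()
        loss, gout, _ = _forward_loss(model, x, target)
        model.backward(gout)
        losses[i] = loss
        grads[i] = float(model.get_parameter(param_name).grad)
    # unimodality: the discrete loss decreases then increases (one local min)
    d = np.diff(losses)
    falls = d < 0
    first_rise = int(np.argmax(~falls)) if not falls.all() else falls.size
    unimodal = bool(np.all(~falls[first_rise:]))
    # - to + crossings (an exact zero at a grid point counts once)
    up = np.nonzero((grads[:-1] < 0) & (grads[1:] >= 0))[0]
    down = np.nonzero((grads[:-1] > 0) & (grads[1:] <= 0))[0]
    sign_change = int(up[0]) if up.size else None
    unimodal = unimodal and up.size <= 1 and down.size == 0
    return ErrorCurve(grid, losses, grads, unimodal, sign_change)


@dataclasses.dataclass
class HessianPair:
    hessian: np.ndarray  # 2x2 curvature at the current parameter values
    grid_a: np.ndarray | None = None
    grid_b: np.ndarray | None = None
    flow_a: np.ndarray | None = None  # negative gradient field on the grid
    flow_b: np.ndarray | None = None
    losses: np.ndarray | None = None

    def valley_direction(self) -> np.ndarray:
        """Unit eigenvector of the smaller-curvature eigenvalue."""
        w, v = np.linalg.eigh(self.hessian)
        return v[:, 0]


def _pair_grads(model, x, y, param_a, param_b) -> np.ndarray:
    model.zero_grad()
    _, gout, _ = _forward_loss(model, x, y)
    model.backward(gout)
    return np.array(
        [float(model.get_parameter(param_a).grad),
         float(model.get_parameter(param_b).grad)]
    )


def hessian_pair(model: Layer, x: VideoTensor, y, param_a: str, param_b: str,
                 rel_step: float = 1e-3, grid_a=None, grid_b=None) -> HessianPair:
    """2x2 curvature matrix (finite differences of analytic first
    derivatives) and, when grids are given, the negative-gradient flow field
    over the (param_a, param_b) plane."""
    pa, pb = model.get_parameter(param_a), model.get_parameter(param_b)
    if pa.value.size != 1 or pb.value.size != 1:
        raise ValueError("hessian_pair requires two scalar parameters")
    center = np.array([float(pa.value), float(pb.value)])
    h = np.array([rel_step * max(abs(c), 1e-6) for c in center])
    H = np.zeros((2, 2))
    for j, (p, name) in enumerate(((pa, param_a), (pb, param_b))):
        orig = float(p.value)
        p.value = np.array(orig + h[j])
        gp = _pair_grads(model, x, y, param_a, param_b)
        p.value = np.array(orig - h[j])
        gm = _pair_grads(model, x, y, param_a, param_b)
        p.value = np.array(orig)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = 0.5 * (H + H.T)  # symmetrize the finite-difference estimate
    res = HessianPair(hessian=H)
    if grid_a is not None and grid_b is not None:
        grid_a = np.asarray(list(grid_a), dtype=float)
        grid_b = np.asarray(list(grid_b), dtype=float)
        fa = np.empty((grid_a.size, grid_b.size))
        fb = np.empty_like(fa)
        losses = np.empty_like(fa)
        for i, va in enumerate(grid_a):
            for j, vb in enumerate(grid_b):
                pa.value = np.array(va)
                pb.value = np.array(vb)
                model.zero_grad()
                loss, gout, _ = _forward_loss(model, x, y)
                model.backward(gout)
                losses[i, j] = loss
                fa[i, j] = -float(pa.grad)
                fb[i, j] = -float(pb.grad)
        pa.value = np.array(center[0])
        pb.value = np.array(center[1])
        res = HessianPair(H, grid_a, grid_b, fa, fb, losses)
    return res


@dataclasses.dataclass
class StimulusOptResult:
    grid: np.ndarray
    objective: np.ndarray
    gradient: np.ndarray
    argmax: float | None
    zero_crossing: float | None
    flat: bool


def optimize_stimulus(model_a: Layer, model_b: Layer, stimulus_fn, grid,
                      fd_step: float | None = None) -> StimulusOptResult:
    """Scan a one-parameter stimulus family for the value that maximally
    separates two models.

    Objective: ``D(s) = mean |model_a(stim(s)) - model_b(stim(s))|``.
    The gradient dD/ds is measured by central differences with a step much
    smaller than the grid spacing; the returned zero crossing (+ to -) of
    the gradient should bracket the grid argmax within one grid step.
    """
    grid = np.asarray(list(grid), dtype=float)
    if fd_step is None:
        fd_step = float(np.min(np.diff(grid))) / 50.0

    def D(s):
        stim = stimulus_fn(s)
        model_a.reset_state()
        model_b.reset_state()
        va = _values(model_a(stim))
        vb = _values(model_b(stim))
        return float(np.mean(np.abs(va - vb)))

    objective = np.array([D(s) for s in grid])
    gradient = np.array([(D(s + fd_step) - D(s - fd_step)) / (2 * fd_step) for s in grid])
    if objective.max() - objective.min() < 1e-9:
        return StimulusOptResult(grid, objective, gradient, None, None, True)
    i_max = int(np.argmax(objective))
    argmax = float(grid[i_max])
    crossings = np.nonzero((gradient[:-1] > 0) & (gradient[1:] <= 0))[0]
    zero_crossing = None
    if crossings.size:
        # linear interpolation of the crossing nearest the argmax
        best = crossings[np.argmin(np.abs(crossings - i_max))]
        g0, g1 = gradient[best], gradient[best + 1]
        frac = g0 / (g0 - g1) if g0 != g1 else 0.5
        zero_crossing = float(grid[best] + frac * (grid[best + 1] - grid[best]))
    return StimulusOptResult(grid, objective, gradient, argmax, zero_crossing, False)


def fraction_variance_explained(a, b) -> float:
    """``1 - var(a - b) / var(a)``; 1 for identical traces, ~0 for an
    unrelated constant."""
    av, bv = _values(a).ravel(), _values(b).ravel()
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.size} vs {bv.size}")
    va = np.var(av)
    if va == 0:
        raise ValueError("var(a) = 0: fraction of variance explained undefined")
    return float(1.0 - np.var(av - bv) / va)
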