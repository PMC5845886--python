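import numpy as np
import pytest

from viscade.signals import wrap_video


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_video(rng):
    """Factory for small seeded noise movies."""

    def make(n_frames=40, nx=8, ny=8, dt=1e-3, scale=1.0, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return wrap_video(scale * r.standard_normal((n_frames, nx, ny)), dt=dt)

    return make


def rel_err(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return np.abs(a - b).max() / max(np.abs(b).max(), 1e-300)


@pytest.fixture
def grad_check():
    """Compare analytic gradients against central finite differences."""
    from viscade.fitting import finite_difference_gradients, param_gradients

    def check(model, x, y, tol=1e-4, step=1e-5, relative=False, params=None):
        ga = param_gradients(model, x, y, params=params)
        gf = finite_difference_gradients(
            model, x, y, params=params, step=step, relative=relative
        )
        for name in ga:
            scale = max(np.abs(gf[name]).max(), 1e-10)
            err = np.abs(ga[name] - gf[name]).max() / scale
            assert err < tol, f"{name}: analytic vs FD rel err {err:.2e} >= {tol}"
        return ga

    return check
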