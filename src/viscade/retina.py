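"""The retina cascade: center-surround OPL stage, bipolar contrast gain
control, ganglion static nonlinearity, and leaky integrate-and-fire spike
generation.

The cascade converts a monochrome luminance movie into ON and OFF spike
rasters through four stages:

1. OPL: band-pass center-surround filtering that converts luminance into a
   contrast signal (with balanced surround weight, constant luminance is
   removed entirely).
2. Bipolar: a leaky integrator whose leak conductance grows with the local
   (spatio-temporally pooled) squared contrast - shunting gain control that
   compresses amplitude and advances response phase at high contrast.
3. Ganglion: a static, strictly positive nonlinearity (linear above a
   threshold potential, hyperbolic decay below it) applied to the signed
   bipolar signal, once per polarity.
4. LIF: Euler-integrated membrane with threshold/reset, refractory period
   and optional seeded Gaussian current noise.

Configuration comes from a :class:`RetinaConfig`, a VirtualRetina-dialect
XML file (:func:`load_vr_xml`; the attribute mapping is shipped as package
data so dialect fixes do not touch code) or an equivalent JSON document.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import xml.etree.ElementTree as ET
from importlib import resources

import numpy as np

from .filters import ExponentialSmooth, RecursiveGaussian2D, gauss2d_array
from .signals import GradientNotAvailable, Layer, Parameter, VideoTensor

logger = logging.getLogger("viscade")

__all__ = [
    "OPLParams",
    "BipolarParams",
    "GanglionParams",
    "LIFParams",
    "RetinaConfig",
    "RetinaOutputs",
    "OPLStage",
    "BipolarStage",
    "GanglionStage",
    "LIFStage",
    "RetinaModel",
    "opl_stage",
    "bipolar_stage",
    "ganglion_current",
    "lif_spikes",
    "run_retina",
    "load_vr_xml",
    "load_retina_json",
    "config_to_dict",
    "spike_events",
    "instantaneous_rate",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class OPLParams:
    sigma_center: float = 1.0  # px
    tau_center: float = 0.02  # s
    sigma_surround: float = 2.5  # px
    tau_surround: float = 0.06  # s
    w_surround: float = 1.0  # relative surround weight in [0, 1]
    lambda_opl: float = 10.0  # output units per luminance unit

    def __post_init__(self):
        if not (self.sigma_center > 0 and self.sigma_surround > 0):
            raise ValueError("OPL sigmas must be positive")
        if not (self.tau_center > 0 and self.tau_surround > 0):
            raise ValueError("OPL taus must be positive")
        if not np.isfinite(self.lambda_opl):
            raise ValueError("lambda_opl must be finite")


@dataclasses.dataclass
class BipolarParams:
    g_leak: float = 10.0  # 1/s
    lambda_bip: float = 10.0  # 1/s per squared-signal unit
    sigma_A: float = 1.5  # px, contrast-neighborhood spatial scale
    tau_A: float = 0.05  # s, contrast-neighborhood temporal scale

    def __post_init__(self):
        if not self.g_leak > 0:
            raise ValueError(
                f"g_leak must be positive (unbounded integrator otherwise); "
                f"got {self.g_leak}"
            )
        if self.lambda_bip < 0:
            raise ValueError("lambda_bip must be >= 0")
        if not (self.sigma_A > 0 and self.tau_A > 0):
            raise ValueError("sigma_A and tau_A must be positive")


@dataclasses.dataclass
class GanglionParams:
    sign: int = 1  # +1 ON, -1 OFF
    v0: float = 0.0  # threshold of the static nonlinearity
    lambda_g: float = 100.0  # slope above threshold
    i0: float = 30.0  # current at threshold

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1; got {self.sign}")
        if not self.i0 > 0:
            raise ValueError(f"i0 must be positive; got {self.i0}")
        if self.lambda_g < 0:
            raise ValueError("lambda_g must be >= 0")


@dataclasses.dataclass
class LIFParams:
    g_l: float = 50.0  # 1/s membrane leak
    v_thresh: float = 1.0
    v_reset: float = 0.0
    tau_refr: float = 0.002  # s
    sigma_noise: float = 0.1  # per sqrt(s)
    seed: int = 0

    def __post_init__(self):
        if not self.v_thresh > self.v_reset:
            raise ValueError("v_thresh must exceed v_reset")
        if self.tau_refr < 0 or self.sigma_noise < 0:
            raise ValueError("tau_refr and sigma_noise must be >= 0")


@dataclasses.dataclass
class RetinaConfig:
    dt: float = 1e-3
    opl: OPLParams = dataclasses.field(default_factory=OPLParams)
    bipolar: BipolarParams = dataclasses.field(default_factory=BipolarParams)
    ganglion_on: GanglionParams = dataclasses.field(
        default_factory=lambda: GanglionParams(sign=1)
    )
    ganglion_off: GanglionParams = dataclasses.field(
        default_factory=lambda: GanglionParams(sign=-1)
    )
    lif: LIFParams = dataclasses.field(default_factory=LIFParams)
    spiking_enabled: bool = True

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        limit = min(self.opl.tau_center, self.opl.tau_surround, self.bipolar.tau_A) / 5.0
        if self.dt > limit:
            logger.warning(
                "dt=%g exceeds min(tau)/5=%g; Euler integration may be inaccurate",
                self.dt,
                limit,
            )


@dataclasses.dataclass
class RetinaOutputs:
    """Per-stage traces of one retina run; spike fields are None when
    spiking is disabled."""

    i_opl: VideoTensor
    v_bip: VideoTensor
    i_gang_on: VideoTensor
    i_gang_off: VideoTensor
    spikes_on: VideoTensor | None = None
    spikes_off: VideoTensor | None = None

    @classmethod
    def concatenate(cls, parts: list["RetinaOutputs"]) -> "RetinaOutputs":
        kw = {}
        for f in dataclasses.fields(cls):
            vals = [getattr(p, f.name) for p in parts]
            if vals[0] is None:
                kw[f.name] = None
            else:
                kw[f.name] = VideoTensor.concatenate(vals)
        return cls(**kw)

    def stages(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) is not None
        }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


class OPLStage(Layer):
    """Center-surround band-pass:
    ``I_OPL = lambda_opl * (C - w_surround * S)`` with
    ``C = Gauss(sigma_c) . Exp(tau_c) [luminance]`` and
    ``S = Gauss(sigma_s) . Exp(tau_s) [C]``."""

    def __init__(self, p: OPLParams):
        super().__init__()
        self.gauss_center = RecursiveGaussian2D(p.sigma_center)
        self.exp_center = ExponentialSmooth(p.tau_center, trainable=False)
        self.gauss_surround = RecursiveGaussian2D(p.sigma_surround)
        self.exp_surround = ExponentialSmooth(p.tau_surround, trainable=False)
        self.w_surround = Parameter(p.w_surround, trainable=False)
        self.lambda_opl = Parameter(p.lambda_opl, trainable=False)

    def process(self, video: VideoTensor) -> VideoTensor:
        if video.values.shape[1] != 1:
            raise ValueError(
                f"retina input must be single-channel (monochrome); got "
                f"{video.values.shape[1]} channels"
            )
        center = self.exp_center(self.gauss_center(video))
        surround = self.exp_surround(self.gauss_surround(center))
        out = float(self.lambda_opl.value) * (
            center.values - float(self.w_surround.value) * surround.values
        )
        return video.with_values(out)


class BipolarStage(Layer):
    """Shunting gain control: explicit-Euler integration per pixel of
    ``dV/dt = I(t) - g(t) V(t)`` with
    ``g = max(g_leak, g_leak + lambda_bip * A)`` and
    ``A = Gauss(sigma_A) . Exp(tau_A) [V^2]``.

    Gradients with respect to ``g_leak`` and ``lambda_bip`` are exact
    forward sensitivities of the Euler recursion; gradients with respect to
    the stage *input* are not available (the computational graph of the
    package stops here on the way upstream).
    """

    def __init__(self, p: BipolarParams):
        super().__init__()
        if not p.g_leak > 0:
            raise ValueError("g_leak must be positive")
        self.g_leak = Parameter(p.g_leak, trainable=True)
        self.lambda_bip = Parameter(p.lambda_bip, trainable=True)
        self.sigma_A = Parameter(p.sigma_A, trainable=False)
        self.tau_A = Parameter(p.tau_A, trainable=False)
        self._v = None  # membrane per pixel
        self._e = None  # exponential-smoothing state of the V^2 pool
        self._cache = None

    def _reset_state(self):
        self._v = None
        self._e = None
        self._cache = None

    def _local_state(self) -> dict:
        return {
            "v": self._v if self._v is not None else np.zeros(0),
            "e": self._e if self._e is not None else np.zeros(0),
        }

    def process(self, video: VideoTensor) -> VideoTensor:
        x = video.values
        dt = video.dt
        field_shape = (x.shape[0], x.shape[1]) + x.shape[3:]
        if self._v is None:
            self._v = np.zeros(field_shape)
            self._e = np.zeros(field_shape)
        v0, e0 = self._v.copy(), self._e.copy()
        out = self._run(x, dt, self._v, self._e)
        self._cache = (x, dt, v0, e0)
        return video.with_values(out)

    def _run(self, x, dt, v, e, sens=None):
        """Euler loop; mutates v and e in place.  With ``sens`` a dict
        ``{param_name: (S_v, S_e)}``, exact forward sensitivities are
        propagated alongside and per-frame sensitivity traces returned."""
        gl = float(self.g_leak.value)
        lb = float(self.lambda_bip.value)
        sx, sy = float(self.sigma_A.value), float(self.sigma_A.value)
        lam_a = np.exp(-dt / float(self.tau_A.value))
        n = x.shape[2]
        out = np.empty_like(x)
        straces = {k: np.empty_like(x) for k in (sens or {})}
        for k in range(n):
            xk = x[:, :, k]
            e *= lam_a
            e += (1.0 - lam_a) * v * v
            a = gauss2d_array(e, sx, sy)
            raw = gl + lb * a
            g = np.maximum(raw, gl)
            unclamped = raw >= gl
            if sens:
                for name, (s_v, s_e) in sens.items():
                    s_e *= lam_a
                    s_e += (1.0 - lam_a) * 2.0 * v * s_v
                    s_a = gauss2d_array(s_e, sx, sy)
                    if name == "g_leak":
                        dg = np.where(unclamped, 1.0 + lb * s_a, 1.0)
                    else:  # lambda_bip
                        dg = np.where(unclamped, a + lb * s_a, 0.0)
                    s_v += dt * (-dg * v - g * s_v)
                    straces[name][:, :, k] = s_v
            v += dt * (xk - g * v)
            out[:, :, k] = v
        if sens:
            return out, straces
        return out

    def backward(self, grad_out: np.ndarray) -> None:
        if self._cache is None:
            raise GradientNotAvailable("backward called before process")
        x, dt, v0, e0 = self._cache
        wanted = [
            n for n in ("g_leak", "lambda_bip") if getattr(self, n).trainable
        ]
        sens = {
            n: (np.zeros_like(v0), np.zeros_like(e0)) for n in wanted
        }
        v, e = v0.copy(), e0.copy()
        _, straces = self._run(x, dt, v, e, sens=sens)
        g = np.asarray(grad_out)
        for name in wanted:
            getattr(self, name).add_grad(np.sum(g * straces[name]))
        return None  # no input gradient across the gain-control recursion


class GanglionStage(Layer):
    """Static nonlinearity mapping signed bipolar potential to a strictly
    positive firing current.  With ``u = sign * v``:

    ``N(u) = i0 + lambda_g (u - v0)``            for ``u >= v0``
    ``N(u) = i0 / (1 - lambda_g (u - v0) / i0)`` for ``u <  v0``

    Continuous and C1 at ``v0``; decays to 0 as ``u -> -inf``.
    """

    def __init__(self, p: GanglionParams):
        super().__init__()
        self.sign = int(p.sign)
        self.v0 = Parameter(p.v0, trainable=True)
        self.lambda_g = Parameter(p.lambda_g, trainable=True)
        self.i0 = Parameter(p.i0, trainable=True)
        self._cache = None

    def process(self, video: VideoTensor) -> VideoTensor:
        i0 = float(self.i0.value)
        if not i0 > 0:
            raise ValueError(f"i0 must be positive; got {i0}")
        lg = float(self.lambda_g.value)
        v0 = float(self.v0.value)
        u = self.sign * video.values
        z = u - v0
        above = z >= 0
        denom = 1.0 - lg * np.where(above, 0.0, z) / i0
        out = np.where(above, i0 + lg * z, i0 / denom)
        self._cache = (z, above, denom, out)
        return video.with_values(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise GradientNotAvailable("backward called before process")
        z, above, denom, out = self._cache
        i0 = float(self.i0.value)
        lg = float(self.lambda_g.value)
        g = np.asarray(grad_out)
        # dN/du: lambda_g above threshold, lambda_g / denom^2 below
        dndu = np.where(above, lg, lg / denom**2)
        if self.v0.trainable:
            self.v0.add_grad(-np.sum(g * dndu))
        if self.lambda_g.trainable:
            dndl = np.where(above, z, z / denom**2)
            self.lambda_g.add_grad(np.sum(g * dndl))
        if self.i0.trainable:
            dndi = np.where(above, 1.0, (1.0 - 2.0 * lg * z / i0) / denom**2)
            self.i0.add_grad(np.sum(g * dndi))
        return g * dndu * self.sign


class LIFStage(Layer):
    """Leaky integrate-and-fire spike generation, Euler-stepped at the video
    dt with a seeded Gaussian current noise stream that is carried across
    chunks (so chunked and whole runs draw identical noise)."""

    def __init__(self, p: LIFParams):
        super().__init__()
        self.params = p
        self.g_l = Parameter(p.g_l, trainable=False)
        self.v_thresh = Parameter(p.v_thresh, trainable=False)
        self.v_reset = Parameter(p.v_reset, trainable=False)
        self.tau_refr = Parameter(p.tau_refr, trainable=False)
        self.sigma_noise = Parameter(p.sigma_noise, trainable=False)
        self.seed = int(p.seed)
        self._v = None
        self._refr = None
        self._rng = np.random.default_rng(self.seed)

    def _reset_state(self):
        self._v = None
        self._refr = None
        self._rng = np.random.default_rng(self.seed)

    def _local_state(self) -> dict:
        return {
            "v": self._v if self._v is not None else np.zeros(0),
            "refr": self._refr if self._refr is not None else np.zeros(0),
        }

    def process(self, video: VideoTensor):
        x = video.values
        dt = video.dt
        gl = float(self.g_l.value)
        vth = float(self.v_thresh.value)
        vre = float(self.v_reset.value)
        sig = float(self.sigma_noise.value)
        n_refr = int(round(float(self.tau_refr.value) / dt))
        field_shape = (x.shape[0], x.shape[1]) + x.shape[3:]
        if self._v is None:
            self._v = np.full(field_shape, vre)
            self._refr = np.zeros(field_shape, dtype=int)
        v, refr = self._v, self._refr
        n = x.shape[2]
        spikes = np.zeros_like(x)
        membrane = np.empty_like(x)
        sqdt = np.sqrt(dt)
        for k in range(n):
            in_refr = refr > 0
            v = np.where(in_refr, vre, v)
            dv = dt * (x[:, :, k] - gl * v)
            if sig > 0:
                dv = dv + sig * sqdt * self._rng.standard_normal(field_shape)
            v = np.where(in_refr, vre, v + dv)
            fired = (v >= vth) & ~in_refr
            spikes[:, :, k] = fired
            v = np.where(fired, vre, v)
            refr = np.where(fired, n_refr, np.maximum(refr - 1, 0))
            membrane[:, :, k] = v
        self._v, self._refr = v, refr
        return (
            video.with_values(spikes),
            video.with_values(membrane),
        )

    def __call__(self, video: VideoTensor):
        return self.process(video)


# ---------------------------------------------------------------------------
# functional wrappers (fresh state each call)
# ---------------------------------------------------------------------------


def opl_stage(luminance: VideoTensor, p: OPLParams) -> VideoTensor:
    layer = OPLStage(p)
    layer.reset_state()
    return layer(luminance)


def bipolar_stage(i_opl: VideoTensor, p: BipolarParams) -> VideoTensor:
    layer = BipolarStage(p)
    layer.reset_state()
    return layer(i_opl)


def ganglion_current(v_bip: VideoTensor, p: GanglionParams) -> VideoTensor:
    return GanglionStage(p)(v_bip)


def lif_spikes(current: VideoTensor, p: LIFParams):
    layer = LIFStage(p)
    layer.reset_state()
    return layer(current)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------


class RetinaModel(Layer):
    """OPL -> bipolar -> {ON, OFF} ganglion -> {ON, OFF} LIF.

    ``process`` returns a :class:`RetinaOutputs` record with every
    intermediate trace; chunked runs concatenate record-wise.
    """

    def __init__(self, cfg: RetinaConfig | None = None):
        super().__init__()
        cfg = cfg or RetinaConfig()
        self.cfg = cfg
        self.opl = OPLStage(cfg.opl)
        self.bipolar = BipolarStage(cfg.bipolar)
        self.gang_on = GanglionStage(cfg.ganglion_on)
        self.gang_off = GanglionStage(cfg.ganglion_off)
        self.lif_on = LIFStage(cfg.lif)
        self.lif_off = LIFStage(
            dataclasses.replace(cfg.lif, seed=cfg.lif.seed + 1)
        )

    def process(self, video: VideoTensor) -> RetinaOutputs:
        i_opl = self.opl(video)
        v_bip = self.bipolar(i_opl)
        i_on = self.gang_on(v_bip)
        i_off = self.gang_off(v_bip)
        spikes_on = spikes_off = None
        if self.cfg.spiking_enabled:
            spikes_on, _ = self.lif_on(i_on)
            spikes_off, _ = self.lif_off(i_off)
        return RetinaOutputs(
            i_opl=i_opl,
            v_bip=v_bip,
            i_gang_on=i_on,
            i_gang_off=i_off,
            spikes_on=spikes_on,
            spikes_off=spikes_off,
        )


def run_retina(luminance: VideoTensor, cfg: RetinaConfig) -> RetinaOutputs:
    model = RetinaModel(cfg)
    model.reset_state()
    return model(luminance)


# ---------------------------------------------------------------------------
# spike utilities
# ---------------------------------------------------------------------------


def spike_events(spikes: VideoTensor) -> np.ndarray:
    """Convert a binary raster to an event list with rows
    ``(unit_x, unit_y, channel, time_s)``, ordered by time."""
    b, c, k, x, y = np.nonzero(spikes.values)
    t = spikes.t0 + k * spikes.dt
    order = np.argsort(t, kind="stable")
    return np.column_stack([x, y, c, t])[order]


def instantaneous_rate(spikes: VideoTensor, width: float = 0.05) -> VideoTensor:
    """Causal exponential smoothing of the raster, scaled to Hz."""
    layer = ExponentialSmooth(width, trainable=False)
    layer.reset_state()
    rate = layer(spikes.with_values(spikes.values / spikes.dt))
    return rate


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------


def _load_attribute_map() -> dict:
    text = resources.files("viscade").joinpath("data/vr_attribute_map.json").read_text()
    return json.loads(text)


def _coerce(field: str, raw: str, attr: str):
    if field in ("spiking_enabled",):
        low = raw.strip().lower()
        if low in ("1", "true", "yes", "on"):
            return True
        if low in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"attribute {attr!r}: cannot parse boolean from {raw!r}")
    try:
        val = float(raw)
    except ValueError as exc:
        raise ValueError(f"attribute {attr!r}: malformed number {raw!r}") from exc
    if field in ("sign", "seed", "lif.seed"):
        return int(val)
    return val


def _assign(target: dict, dotted: str, value):
    parts = dotted.split(".")
    d = target
    for p in parts[:-1]:
        d = d.setdefault(p, {})
    d[parts[-1]] = value


def load_vr_xml(path) -> RetinaConfig:
    """Parse a VirtualRetina-dialect XML file into a :class:`RetinaConfig`.

    Recognized attributes follow the shipped mapping table
    (``data/vr_attribute_map.json``); unrecognized attributes and
    radially-varying-blur settings are warned about and ignored; sections
    missing from the document fall back to defaults with one warning each.
    """
    table = _load_attribute_map()
    ignored_patterns = table.pop("_ignored_patterns")
    table.pop("_comment", None)
    tree = ET.parse(path)
    root = tree.getroot()
    collected: dict = {}
    ganglions: list[dict] = []

    def handle(elem, section):
        mapping = table[section]
        out = {}
        for attr, raw in elem.attrib.items():
            if any(pat in attr for pat in ignored_patterns):
                logger.warning(
                    "ignoring radially-varying attribute %r (not implemented)", attr
                )
                continue
            if attr not in mapping:
                logger.warning(
                    "ignoring unrecognized attribute %r in <%s>", attr, section
                )
                continue
            out[mapping[attr]] = _coerce(mapping[attr], raw, attr)
        return out

    root_section = root.tag
    if root_section in table:
        for dotted, val in handle(root, root_section).items():
            _assign(collected, dotted, val)
    seen = set()
    for elem in root.iter():
        if elem is root:
            continue
        if elem.tag not in table:
            logger.warning("ignoring unrecognized element <%s>", elem.tag)
            continue
        fields = handle(elem, elem.tag)
        if elem.tag == "ganglion-layer":
            ganglions.append(fields)
            seen.add(elem.tag)
            continue
        for dotted, val in fields.items():
            _assign(collected, dotted, val)
        seen.add(elem.tag)
    for section in ("outer-plexiform-layer", "contrast-gain-control",
                    "ganglion-layer", "spiking-channel"):
        if section not in seen:
            logger.warning("section <%s> missing; using defaults", section)
    for fields in ganglions:
        sign = int(fields.get("sign", 1))
        key = "ganglion_on" if sign >= 0 else "ganglion_off"
        for fname, val in fields.items():
            _assign(collected, f"{key}.{fname}", val)
        _assign(collected, f"{key}.sign", 1 if sign >= 0 else -1)
    return _config_from_dict(collected)


def _config_from_dict(d: dict) -> RetinaConfig:
    return RetinaConfig(
        dt=d.get("dt", 1e-3),
        opl=OPLParams(**d.get("opl", {})),
        bipolar=BipolarParams(**d.get("bipolar", {})),
        ganglion_on=GanglionParams(**{"sign": 1, **d.get("ganglion_on", {})}),
        ganglion_off=GanglionParams(**{"sign": -1, **d.get("ganglion_off", {})}),
        lif=LIFParams(**d.get("lif", {})),
        spiking_enabled=bool(d.get("spiking_enabled", True)),
    )


def load_retina_json(path) -> RetinaConfig:
    """JSON alternative to the XML dialect: a nested object mirroring
    :class:`RetinaConfig` field names; missing sections use defaults."""
    with open(path) as fh:
        d = json.load(fh)
    return _config_from_dict(d)


def config_to_dict(cfg: RetinaConfig) -> dict:
    return dataclasses.asdict(cfg)
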