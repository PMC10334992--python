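"""Synthetic phantom scenes and division-of-focal-plane sensor rendering.

This module is the package's data generator.  It emulates collagen-gel
tissue phantoms imaged by a polarization camera:

* a :class:`PhantomScene` holds per-pixel optical maps (fiber axis,
  retardance, depolarization, transmissivity) parameterized by the
  experimental factors of a gel study — fiber alignment (aligned vs
  disorganized), collagen density (1.5 / 3.0 / 4.5 mg/mL), riboflavin
  crosslinking (0 / 0.5 / 1.0 mM), and absorber level (100% / 67% / 33% of
  control transmission, a Beer-Lambert attenuation);
* :func:`render_mosaic` pushes circularly polarized light through each
  pixel's Mueller chain (retarder, optional helicity-flipping mirror for
  reflectance mode, depolarizer, attenuator) and samples the result with a
  2x2 micropolarizer mosaic (0/45/90/135 degree analyzers) under a
  Poisson-Gaussian sensor noise model;
* :func:`generate_fiber_texture` renders grayscale fiber images with
  axial-von-Mises-distributed orientations, for testing the FFT orientation
  analysis.

Optical maps are constant within each 2x2 superpixel so that a noise-free
mosaic determines the polarization state of every superpixel exactly.

All randomness flows through explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

from qpli.mueller import retarder_matrix

__all__ = [
    "PhantomScene",
    "SensorParams",
    "MosaicImage",
    "generate_scene",
    "uniform_scene",
    "scene_stokes",
    "scene_true_maps",
    "render_mosaic",
    "generate_fiber_texture",
    "sample_axial_von_mises",
    "COLLAGEN_DENSITIES",
    "RIBOFLAVIN_LEVELS",
    "TRANSMISSION_LEVELS",
]

COLLAGEN_DENSITIES = (1.5, 3.0, 4.5)      # mg/mL, 1.5 = control
RIBOFLAVIN_LEVELS = (0.0, 0.5, 1.0)       # mM photoinitiator
TRANSMISSION_LEVELS = (1.0, 0.67, 0.33)   # fraction of control transmission

#: retardance per unit collagen density, rad/(mg/mL); chosen so the control
#: aligned transmission scene lands in the AVG DoLP ~0.7-0.8 regime.
DEFAULT_C_RET = 0.7

#: retained linear/circular polarization fraction added by the reflectance
#: geometry (backscattering depolarizes; transmission keeps ballistic photons).
DEFAULT_REFLECTANCE_RETENTION = 0.36

DEFAULT_LAYOUT = ((90, 45), (135, 0))


@dataclass
class SensorParams:
    """Division-of-focal-plane sensor model.

    ``layout`` is the 2x2 superpixel arrangement of analyzer angles
    (row-major from the top-left of the frame) and must be a permutation of
    {0, 45, 90, 135}.  Noise is Poisson shot noise at ``full_well``
    photoelectrons per unit intensity plus Gaussian read noise with standard
    deviation ``read_noise_sd`` (fraction of full scale), quantized to
    ``bit_depth`` bits.
    """

    layout: tuple = DEFAULT_LAYOUT
    full_well: float = 1000.0
    read_noise_sd: float = 0.005
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        flat = tuple(int(a) for row in self.layout for a in row)
        if sorted(flat) != [0, 45, 90, 135]:
            raise ValueError(
                f"layout must be a 2x2 permutation of (0, 45, 90, 135), got {self.layout}"
            )
        self.layout = (tuple(self.layout[0]), tuple(self.layout[1]))
        if self.full_well <= 0:
            raise ValueError("full_well must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")

    @property
    def dn_max(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class PhantomScene:
    """Per-pixel optical description of a phantom.

    ``depol_linear`` / ``depol_circular`` are depolarization *strengths* in
    [0, 1] (0 = fully polarization-preserving); the renderer converts them to
    the retained fractions ``1 - strength`` of the diagonal depolarizer.
    """

    fiber_axis_deg: np.ndarray
    retardance_rad: np.ndarray
    depol_linear: np.ndarray
    depol_circular: np.ndarray
    transmissivity: np.ndarray
    base_intensity: np.ndarray
    alignment: str = "aligned"
    mode: str = "transmission"
    collagen_density: float = 1.5
    riboflavin_mm: float = 0.0
    transmission_level: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        maps = {
            "fiber_axis_deg": self.fiber_axis_deg,
            "retardance_rad": self.retardance_rad,
            "depol_linear": self.depol_linear,
            "depol_circular": self.depol_circular,
            "transmissivity": self.transmissivity,
            "base_intensity": self.base_intensity,
        }
        shapes = {name: np.asarray(m).shape for name, m in maps.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"scene maps must share one shape, got {shapes}")
        for name in maps:
            setattr(self, name, np.asarray(maps[name], dtype=float))
        for name in ("depol_linear", "depol_circular", "transmissivity"):
            m = getattr(self, name)
            if m.min() < 0 or m.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.retardance_rad.min() < 0:
            raise ValueError("retardance_rad must be non-negative")
        if self.mode not in ("transmission", "reflectance"):
            raise ValueError(f"mode must be 'transmission' or 'reflectance', got {self.mode!r}")

    @property
    def shape(self) -> tuple:
        return self.fiber_axis_deg.shape


@dataclass
class MosaicImage:
    """Raw DoFP frame plus the metadata needed to demosaic it."""

    pixels: np.ndarray
    layout: tuple = DEFAULT_LAYOUT
    mode: str = "transmission"
    handedness: str = "right"
    seed: Optional[int] = None
    scene_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mosaic must be a 2D array")
        h, w = self.pixels.shape
        if h % 2 or w % 2:
            raise ValueError(f"mosaic dimensions must be even, got {self.pixels.shape}")
        if self.pixels.min() < 0:
            raise ValueError("mosaic values must be non-negative")
        self.layout = (tuple(int(a) for a in self.layout[0]), tuple(int(a) for a in self.layout[1]))


def sample_axial_von_mises(rng: np.random.Generator, mu_deg: float, kappa: float, size) -> np.ndarray:
    """Draw axial orientations (degrees in [-90, 90)) from a von Mises.

    The axial von Mises density p(theta) ~ exp(kappa * cos 2(theta - mu)) on
    a 180-degree domain is sampled by drawing the doubled angle from an
    ordinary von Mises and halving.  ``kappa = 0`` is exactly uniform.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return rng.uniform(-90.0, 90.0, size=size)
    doubled = rng.vonmises(np.deg2rad(2.0 * mu_deg), kappa, size=size)
    angles = 0.5 * np.rad2deg(doubled)
    return angles - 180.0 * np.floor((angles + 90.0) / 180.0)


def _check_level(name: str, value: float, allowed: tuple) -> float:
    value = float(value)
    if not any(np.isclose(value, a) for a in allowed):
        raise ValueError(f"unknown {name} level {value}; expected one of {allowed}")
    return value


def generate_scene(
    alignment: str,
    mode: str = "transmission",
    shape: tuple = (128, 128),
    collagen_density: float = 1.5,
    riboflavin_mm: float = 0.0,
    transmission_level: float = 1.0,
    seed: int = 0,
    kappa: Optional[float] = None,
    mean_axis_deg: float = 20.0,
    c_ret: float = DEFAULT_C_RET,
    thickness_factor: float = 1.0,
    retardance_rad: Optional[float] = None,
    reflectance_retention: float = DEFAULT_REFLECTANCE_RETENTION,
    retardance_jitter_sd: float = 0.05,
    fibers_per_superpixel: int = 12,
) -> PhantomScene:
    """Generate a phantom scene from experimental factor levels.

    Each superpixel contains ``fibers_per_superpixel`` fibers whose axes are
    drawn from an axial von Mises — concentrated for aligned scenes
    (``kappa`` default 4), near-uniform for disorganized ones (default
    0.05).  The incoherent mixture of equally retarding fibers at different
    axes is exactly a single retarder at the local circular mean axis
    followed by a linear depolarizer whose retained fraction is the local
    doubled-angle resultant length R2: that is how sub-resolution fiber
    disorder depolarizes — disorganized scenes lose DoLP not because single
    fibers retard less but because their axes cancel within a pixel.

    Retardance scales linearly with collagen density (``c_ret * density *
    thickness_factor``, overridable via ``retardance_rad``) with mild
    per-superpixel lognormal jitter.  Isotropic depolarization grows with
    density and crosslinking, and the reflectance geometry multiplies the
    retained polarization by ``reflectance_retention``.  Transmissivity is
    set directly from the absorber transmission level (a Beer-Lambert
    attenuation already expressed as a fraction of control).  Deterministic
    for a fixed seed.
    """
    if alignment not in ("aligned", "disorganized"):
        raise ValueError(f"unknown alignment {alignment!r}; expected 'aligned' or 'disorganized'")
    if mode not in ("transmission", "reflectance"):
        raise ValueError(f"unknown mode {mode!r}")
    h, w = shape
    if h % 2 or w % 2:
        raise ValueError(f"scene shape must be even in both axes, got {shape}")
    density = _check_level("collagen_density", collagen_density, COLLAGEN_DENSITIES)
    ribo = _check_level("riboflavin_mm", riboflavin_mm, RIBOFLAVIN_LEVELS)
    t_level = _check_level("transmission_level", transmission_level, TRANSMISSION_LEVELS)

    if kappa is None:
        kappa = 4.0 if alignment == "aligned" else 0.05

    rng = np.random.default_rng(seed)
    sh, sw = h // 2, w // 2
    draws = sample_axial_von_mises(rng, mean_axis_deg, kappa, (sh, sw, fibers_per_superpixel))
    z = np.exp(2j * np.deg2rad(draws)).mean(axis=-1)
    r2_local = np.abs(z)  # retained linear polarization from sub-pixel fiber mixing
    axis_sp = 0.5 * np.degrees(np.angle(z))
    axis_sp = axis_sp - 180.0 * np.floor((axis_sp + 90.0) / 180.0)

    if retardance_rad is None:
        delta0 = c_ret * density * thickness_factor
    else:
        delta0 = float(retardance_rad)
    if retardance_jitter_sd > 0:
        jitter = rng.lognormal(mean=0.0, sigma=retardance_jitter_sd, size=(sh, sw))
    else:
        jitter = np.ones((sh, sw))
    ret_sp = delta0 * jitter

    # retained polarization: scattering grows with density and crosslinking,
    # and reflectance collects multiply backscattered photons
    retention = np.exp(-0.10 * (density - 1.5)) * np.exp(-0.06 * ribo)
    if mode == "reflectance":
        retention *= reflectance_retention
    retention_lin = np.clip(r2_local * retention, 0.0, 1.0)
    strength_circ = float(np.clip(1.0 - retention, 0.0, 1.0))

    up = lambda m: np.repeat(np.repeat(m, 2, axis=0), 2, axis=1)
    const = lambda v: np.full((h, w), v, dtype=float)
    return PhantomScene(
        fiber_axis_deg=up(axis_sp),
        retardance_rad=up(ret_sp),
        depol_linear=up(1.0 - retention_lin),
        depol_circular=const(strength_circ),
        transmissivity=const(t_level),
        base_intensity=const(1.0),
        alignment=alignment,
        mode=mode,
        collagen_density=density,
        riboflavin_mm=ribo,
        transmission_level=t_level,
        seed=seed,
    )


def uniform_scene(
    shape: tuple = (64, 64),
    fiber_axis_deg: float = 20.0,
    retardance_rad: float = np.pi / 2,
    depol_linear: float = 0.0,
    depol_circular: Optional[float] = None,
    transmissivity: float = 1.0,
    base_intensity: float = 1.0,
    mode: str = "transmission",
) -> PhantomScene:
    """A spatially uniform scene — every pixel is one retarder state.

    Convenient for closed-form oracles: the whole field of view behaves like
    a single optical chain.
    """
    if depol_circular is None:
        depol_circular = depol_linear
    const = lambda v: np.full(shape, float(v))
    return PhantomScene(
        fiber_axis_deg=const(fiber_axis_deg),
        retardance_rad=const(retardance_rad),
        depol_linear=const(depol_linear),
        depol_circular=const(depol_circular),
        transmissivity=const(transmissivity),
        base_intensity=const(base_intensity),
        alignment="aligned",
        mode=mode,
    )


def scene_stokes(scene: PhantomScene, input_handedness: str = "right") -> np.ndarray:
    """Per-pixel Stokes vectors (H, W, 4) of light leaving the scene.

    Each pixel applies, in optical order: for reflectance mode a
    helicity-flipping mirror (backscattering reverses circular handedness
    before the exit pass) — linear retarder (fiber axis, retardance) —
    diagonal depolarizer — neutral attenuator; the source is fully
    circularly polarized light of the requested handedness at the pixel's
    base intensity.  Because the mirror precedes the retarder, the
    reflectance-mode AoP is rotated by exactly 90 degrees relative to
    transmission at every pixel, matching the uniform shift this geometry
    produces.
    """
    if input_handedness not in ("right", "left"):
        raise ValueError(f"handedness must be 'right' or 'left', got {input_handedness!r}")
    sign = 1.0 if input_handedness == "right" else -1.0
    h, w = scene.shape
    s_in = np.zeros((h, w, 4))
    s_in[..., 0] = 1.0
    s_in[..., 3] = sign
    if scene.mode == "reflectance":
        s_in[..., 3] *= -1.0  # mirror: diag(1,1,-1,-1) on a circular-pure state

    m_ret = retarder_matrix(scene.fiber_axis_deg, scene.retardance_rad)
    s = np.einsum("...ij,...j->...i", m_ret, s_in)
    s[..., 1] *= 1.0 - scene.depol_linear
    s[..., 2] *= 1.0 - scene.depol_linear
    s[..., 3] *= 1.0 - scene.depol_circular
    s *= (scene.transmissivity * scene.base_intensity)[..., None]
    return s


def scene_true_maps(scene: PhantomScene, input_handedness: str = "right"):
    """Ground-truth (S0, DoLP, AoP) maps of the rendered scene (no sensor)."""
    s = scene_stokes(scene, input_handedness)
    s0 = s[..., 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        dolp = np.where(s0 > 0, np.hypot(s[..., 1], s[..., 2]) / np.where(s0 > 0, s0, 1.0), 0.0)
    aop = 0.5 * np.degrees(np.arctan2(s[..., 2], s[..., 1]))
    aop = aop - 180.0 * np.floor((aop + 90.0) / 180.0)
    return s0, dolp, aop


def render_mosaic(
    scene: PhantomScene,
    sensor: Optional[SensorParams] = None,
    input_handedness: str = "right",
    noise: bool = True,
) -> MosaicImage:
    """Render the DoFP mosaic a polarization camera would record.

    The intensity behind a linear analyzer at angle theta is the Malus-law
    projection ``0.5 * (S0 + S1 cos 2theta + S2 sin 2theta)``, tiled over the
    frame by the sensor's 2x2 superpixel layout.  With ``noise=True`` the
    reading is Poisson shot noise at ``sensor.full_well`` photoelectrons per
    unit intensity plus Gaussian read noise, clipped to the sensor bit
    depth and returned in DN; with ``noise=False`` the exact Malus
    intensities are returned as floats.
    """
    if sensor is None:
        sensor = SensorParams()
    s = scene_stokes(scene, input_handedness)
    h, w = scene.shape
    layout = np.asarray(sensor.layout, dtype=float)
    theta = np.tile(layout, (h // 2, w // 2))
    theta_rad = np.deg2rad(theta)
    intensity = 0.5 * (
        s[..., 0]
        + s[..., 1] * np.cos(2.0 * theta_rad)
        + s[..., 2] * np.sin(2.0 * theta_rad)
    )
    intensity = np.clip(intensity, 0.0, None)

    if noise:
        rng = np.random.default_rng(sensor.seed)
        electrons = rng.poisson(intensity * sensor.full_well).astype(float)
        dn = electrons / sensor.full_well * sensor.dn_max
        dn += rng.normal(0.0, sensor.read_noise_sd * sensor.dn_max, size=dn.shape)
        pixels = np.clip(np.round(dn), 0, sensor.dn_max)
    else:
        pixels = intensity

    return MosaicImage(
        pixels=pixels,
        layout=sensor.layout,
        mode=scene.mode,
        handedness=input_handedness,
        seed=sensor.seed if noise else None,
        scene_id=f"{scene.alignment}-{scene.mode}-seed{scene.seed}",
    )


def _clip_segment(r0, c0, r1, c1, h, w):
    """Liang-Barsky clip of a segment to the image rectangle.

    Clipping parametrically preserves the segment's orientation (clipping
    endpoint coordinates independently would not).  Returns None when the
    segment misses the image entirely.
    """
    dr, dc = r1 - r0, c1 - c0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dr, r0),            # r >= 0
        (dr, h - 1 - r0),     # r <= h-1
        (-dc, c0),            # c >= 0
        (dc, w - 1 - c0),     # c <= w-1
    ):
        if p == 0:
            if q < 0:
                return None
            continue
        t = q / p
        if p < 0:
            t0 = max(t0, t)
        else:
            t1 = min(t1, t)
        if t0 > t1:
            return None
    return (r0 + t0 * dr, c0 + t0 * dc, r0 + t1 * dr, c0 + t1 * dc)


def generate_fiber_texture(
    kappa: float,
    mu_deg: float = 0.0,
    n_fibers: int = 300,
    shape: tuple = (256, 256),
    fiber_width: float = 2.0,
    seed: int = 0,
    background_noise_sd: float = 0.02,
    length_frac: float = 0.5,
) -> np.ndarray:
    """Render a grayscale fiber-texture image with known orientation statistics.

    Draws ``n_fibers`` anti-aliased line segments whose orientations are
    i.i.d. axial von Mises(mu, kappa) samples, at uniformly random centers,
    blurs to the requested fiber width, and adds Gaussian background noise.
    Angles use the y-up convention (degrees counterclockwise from the image
    horizontal).  Deterministic per seed.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if n_fibers < 1:
        raise ValueError("n_fibers must be at least 1")
    h, w = shape
    rng = np.random.default_rng(seed)
    angles = sample_axial_von_mises(rng, mu_deg, kappa, n_fibers)
    centers_r = rng.uniform(0, h, n_fibers)
    centers_c = rng.uniform(0, w, n_fibers)
    half_len = 0.5 * length_frac * min(h, w)

    canvas = np.zeros((h, w))
    for ang, cr, cc in zip(np.deg2rad(angles), centers_r, centers_c):
        dc = np.cos(ang) * half_len
        dr = -np.sin(ang) * half_len  # rows grow downward; angle is y-up
        seg = _clip_segment(cr - dr, cc - dc, cr + dr, cc + dc, h, w)
        if seg is None:
            continue
        r0, c0, r1, c1 = (int(round(v)) for v in seg)
        rr, ccidx, val = line_aa(r0, c0, r1, c1)
        canvas[rr, ccidx] += val

    if fiber_width > 0:
        canvas = gaussian_filter(canvas, sigma=fiber_width / 2.0)
    if canvas.max() > 0:
        canvas = canvas / canvas.max()
    if background_noise_sd > 0:
        canvas = canvas + rng.normal(0.0, background_noise_sd, size=canvas.shape)
    return canvas
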