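"""Stokes/Mueller algebra for circular-illumination Stokes polarimetry.

The forward model treats every optical interaction as a 4x4 real Mueller
matrix acting on a Stokes vector ``(S0, S1, S2, S3)``.  Five element kinds
are supported:

``retarder``
    Linear retarder with fast axis ``fast_axis_deg`` (degrees,
    counterclockwise from the camera horizontal) and retardance
    ``retardance_rad`` (radians).  Models birefringent collagen.
``polarizer``
    Ideal linear polarizer at ``axis_deg``.
``depolarizer``
    Diagonal depolarizer ``diag(1, d_lin, d_lin, d_circ)`` where the factors
    are the *retained* polarization fractions (1 = no depolarization).
    Models multiple scattering.
``attenuator``
    Neutral attenuator ``T * I`` with transmissivity ``T``.  Models
    Beer-Lambert absorption.
``mirror``
    Helicity-flipping reflection, ``diag(1, 1, -1, -1)``: circularly
    polarized photons reverse handedness on reflection.  This is the element
    that distinguishes the reflectance-mode chain from the transmission-mode
    chain and produces the 90 degree angle-of-polarization shift between
    the two imaging geometries.

Angle conventions: polarization and axis angles are in degrees on the axial
interval [-90, 90), measured counterclockwise from the camera x-axis.
``S3 > 0`` denotes right-handed circular polarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StokesVector4",
    "MuellerElement",
    "ModeChain",
    "make_element",
    "propagate",
    "aop_circular_difference",
    "retarder_matrix",
    "polarizer_matrix",
    "depolarizer_matrix",
    "attenuator_matrix",
    "mirror_matrix",
    "chain_to_dict",
    "chain_from_dict",
]

_PHYSICALITY_RTOL = 1e-9

ELEMENT_KINDS = ("retarder", "polarizer", "depolarizer", "attenuator", "mirror")


@dataclass(frozen=True)
class StokesVector4:
    """Full four-component Stokes state.

    Parameters
    ----------
    s0 : float
        Total intensity, arbitrary units, >= 0.
    s1 : float
        0/90 degree linear component.
    s2 : float
        +-45 degree linear component.
    s3 : float
        Circular component; positive = right-handed.
    """

    s0: float
    s1: float = 0.0
    s2: float = 0.0
    s3: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.s0, self.s1, self.s2, self.s3]).all():
            raise ValueError("Stokes components must be finite")
        if self.s0 < 0:
            raise ValueError(f"S0 must be non-negative, got {self.s0}")
        pol = float(np.sqrt(self.s1**2 + self.s2**2 + self.s3**2))
        if pol > self.s0 * (1.0 + _PHYSICALITY_RTOL) + 1e-300:
            raise ValueError(
                f"non-physical Stokes vector: sqrt(S1^2+S2^2+S3^2)={pol:.6g} "
                f"exceeds S0={self.s0:.6g}"
            )

    # -- constructors ---------------------------------------------------
    @classmethod
    def unpolarized(cls, intensity: float = 1.0) -> "StokesVector4":
        return cls(intensity, 0.0, 0.0, 0.0)

    @classmethod
    def circular(cls, handedness: str = "right", intensity: float = 1.0) -> "StokesVector4":
        """Fully circularly polarized state of the given handedness."""
        if handedness not in ("right", "left"):
            raise ValueError(f"handedness must be 'right' or 'left', got {handedness!r}")
        sign = 1.0 if handedness == "right" else -1.0
        return cls(intensity, 0.0, 0.0, sign * intensity)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "StokesVector4":
        a = np.asarray(arr, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"expected 4 components, got shape {a.shape}")
        return cls(*a.tolist())

    # -- derived quantities ---------------------------------------------
    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3], dtype=float)

    @property
    def dop(self) -> float:
        """Total degree of polarization sqrt(S1^2+S2^2+S3^2)/S0."""
        if self.s0 == 0:
            return 0.0
        return float(np.sqrt(self.s1**2 + self.s2**2 + self.s3**2) / self.s0)

    @property
    def dolp(self) -> float:
        """Degree of linear polarization sqrt(S1^2+S2^2)/S0."""
        if self.s0 == 0:
            return 0.0
        return float(np.sqrt(self.s1**2 + self.s2**2) / self.s0)

    @property
    def aop_deg(self) -> float:
        """Angle of polarization 0.5*atan2(S2, S1), degrees in [-90, 90)."""
        a = 0.5 * np.degrees(np.arctan2(self.s2, self.s1))
        return float(a - 180.0 * np.floor((a + 90.0) / 180.0))


# ---------------------------------------------------------------------------
# Matrix builders.  All accept scalar or broadcastable array parameters and
# return arrays of shape (..., 4, 4) so the synthetic renderer can evaluate
# whole per-pixel maps in one call.
# ---------------------------------------------------------------------------

def retarder_matrix(fast_axis_deg, retardance_rad) -> np.ndarray:
    """Mueller matrix of a linear retarder.

    Fast axis at ``fast_axis_deg`` (degrees CCW from horizontal), retardance
    ``retardance_rad`` (radians).
    """
    theta = np.deg2rad(np.asarray(fast_axis_deg, dtype=float))
    delta = np.asarray(retardance_rad, dtype=float)
    c = np.cos(2.0 * theta)
    s = np.sin(2.0 * theta)
    cd = np.cos(delta)
    sd = np.sin(delta)
    shape = np.broadcast_shapes(c.shape, cd.shape)
    one = np.ones(shape)
    zero = np.zeros(shape)
    c, s, cd, sd = (np.broadcast_to(x, shape) for x in (c, s, cd, sd))
    rows = [
        [one, zero, zero, zero],
        [zero, c * c + s * s * cd, c * s * (1.0 - cd), -s * sd],
        [zero, c * s * (1.0 - cd), s * s + c * c * cd, c * sd],
        [zero, s * sd, -c * sd, cd],
    ]
    return np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)


def polarizer_matrix(axis_deg) -> np.ndarray:
    """Mueller matrix of an ideal linear polarizer at ``axis_deg``."""
    theta = np.deg2rad(np.asarray(axis_deg, dtype=float))
    c = np.cos(2.0 * theta)
    s = np.sin(2.0 * theta)
    one = np.ones_like(c)
    zero = np.zeros_like(c)
    rows = [
        [one, c, s, zero],
        [c, c * c, c * s, zero],
        [s, c * s, s * s, zero],
        [zero, zero, zero, zero],
    ]
    return 0.5 * np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)


def depolarizer_matrix(depol_linear, depol_circular) -> np.ndarray:
    """Diagonal depolarizer ``diag(1, d_lin, d_lin, d_circ)``.

    The parameters are retained polarization fractions in [0, 1]; 0 is a
    perfect depolarizer, 1 an identity.
    """
    d_lin = np.asarray(depol_linear, dtype=float)
    d_circ = np.asarray(depol_circular, dtype=float)
    shape = np.broadcast_shapes(d_lin.shape, d_circ.shape)
    m = np.zeros(shape + (4, 4))
    m[..., 0, 0] = 1.0
    m[..., 1, 1] = d_lin
    m[..., 2, 2] = d_lin
    m[..., 3, 3] = d_circ
    return m


def attenuator_matrix(transmissivity) -> np.ndarray:
    """Neutral attenuator ``T * I``."""
    t = np.asarray(transmissivity, dtype=float)
    return t[..., None, None] * np.eye(4)


def mirror_matrix() -> np.ndarray:
    """Helicity-flipping mirror reflection ``diag(1, 1, -1, -1)``."""
    return np.diag([1.0, 1.0, -1.0, -1.0])


_PARAM_RANGES = {
    "retarder": {"fast_axis_deg": None, "retardance_rad": (0.0, 2.0 * np.pi, "half_open")},
    "polarizer": {"axis_deg": None},
    "depolarizer": {"depol_linear": (0.0, 1.0, "closed"), "depol_circular": (0.0, 1.0, "closed")},
    "attenuator": {"transmissivity": (0.0, 1.0, "closed")},
    "mirror": {},
}


def _check_param(kind: str, name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{kind} parameter '{name}' must be finite, got {value}")
    rng = _PARAM_RANGES[kind][name]
    if rng is not None:
        lo, hi, mode = rng
        ok = lo <= value <= hi if mode == "closed" else lo <= value < hi
        bracket = "]" if mode == "closed" else ")"
        if not ok:
            raise ValueError(
                f"{kind} parameter '{name}' out of range [{lo}, {hi}{bracket}: got {value}"
            )
    return value


@dataclass(frozen=True)
class MuellerElement:
    """A single optical element: its kind, parameters, and 4x4 matrix."""

    kind: str
    params: dict
    matrix: np.ndarray = field(repr=False, compare=False)

    def apply(self, state: StokesVector4) -> StokesVector4:
        out = self.matrix @ state.as_array()
        return StokesVector4.from_array(out)


def make_element(kind: str, **params) -> MuellerElement:
    """Build a :class:`MuellerElement` of the given kind.

    Parameters are kind-specific; see the module docstring.  Depolarizer
    defaults ``depol_circular`` to ``depol_linear`` when omitted.

    Raises
    ------
    ValueError
        If the kind is unknown or a parameter is out of range (the message
        names the offending field).
    """
    if kind not in ELEMENT_KINDS:
        raise ValueError(f"unknown element kind {kind!r}; expected one of {ELEMENT_KINDS}")
    if kind == "depolarizer" and "depol_circular" not in params and "depol_linear" in params:
        params = dict(params, depol_circular=params["depol_linear"])
    expected = set(_PARAM_RANGES[kind])
    given = set(params)
    if given != expected:
        missing, extra = expected - given, given - expected
        detail = []
        if missing:
            detail.append(f"missing {sorted(missing)}")
        if extra:
            detail.append(f"unexpected {sorted(extra)}")
        raise ValueError(f"{kind} parameters invalid: {'; '.join(detail)}")
    clean = {name: _check_param(kind, name, value) for name, value in params.items()}
    if kind == "retarder":
        m = retarder_matrix(clean["fast_axis_deg"], clean["retardance_rad"])
    elif kind == "polarizer":
        m = polarizer_matrix(clean["axis_deg"])
    elif kind == "depolarizer":
        m = depolarizer_matrix(clean["depol_linear"], clean["depol_circular"])
    elif kind == "attenuator":
        m = attenuator_matrix(clean["transmissivity"])
    else:
        m = mirror_matrix()
    return MuellerElement(kind=kind, params=clean, matrix=np.asarray(m, dtype=float))


@dataclass
class ModeChain:
    """An ordered optical chain for one imaging mode.

    ``elements`` are listed in optical order (first element hit first).  A
    reflectance-mode chain must contain exactly one mirror element; a
    transmission-mode chain must contain none.  The default input state is
    right-handed circular, matching a circular-polarizer illumination arm.
    """

    mode: str
    elements: list
    input_state: StokesVector4 = field(default_factory=lambda: StokesVector4.circular("right"))

    def __post_init__(self) -> None:
        if self.mode not in ("transmission", "reflectance"):
            raise ValueError(f"mode must be 'transmission' or 'reflectance', got {self.mode!r}")
        if not self.elements:
            raise ValueError("chain must contain at least one element")
        n_mirror = sum(1 for e in self.elements if e.kind == "mirror")
        if self.mode == "reflectance" and n_mirror != 1:
            raise ValueError(f"reflectance chain must contain exactly one mirror, got {n_mirror}")
        if self.mode == "transmission" and n_mirror != 0:
            raise ValueError("transmission chain must not contain a mirror element")

    def matrix(self) -> np.ndarray:
        """Total chain matrix M_n ... M_1 (right-to-left in optical order)."""
        m = np.eye(4)
        for element in self.elements:
            m = element.matrix @ m
        return m

    def output(self) -> StokesVector4:
        return propagate(self.input_state, self)


def propagate(state: StokesVector4, chain: ModeChain) -> StokesVector4:
    """Propagate a Stokes state through an optical chain.

    Returns ``M_n ... M_1 @ state``.  The input must be a physical Stokes
    vector (enforced by :class:`StokesVector4`); passivity of the supported
    elements guarantees a physical output up to roundoff.
    """
    if not isinstance(state, StokesVector4):
        state = StokesVector4.from_array(state)
    out = chain.matrix() @ state.as_array()
    # guard against roundoff pushing sqrt(S1^2+S2^2+S3^2) infinitesimally past S0
    pol = np.sqrt(out[1] ** 2 + out[2] ** 2 + out[3] ** 2)
    if pol > out[0] and pol <= out[0] * (1.0 + 1e-12) + 1e-300:
        out[1:] *= out[0] / pol
    return StokesVector4.from_array(out)


def aop_circular_difference(a_deg: float, b_deg: float) -> float:
    """Axial (180-degree-periodic) difference between two AoP values.

    Returns ``min(|d| mod 180, 180 - |d| mod 180)``, in [0, 90].
    """
    if not (np.isfinite(a_deg) and np.isfinite(b_deg)):
        raise ValueError("angles must be finite")
    d = abs(float(a_deg) - float(b_deg)) % 180.0
    return float(min(d, 180.0 - d))


# ---------------------------------------------------------------------------
# Serialization: chains round-trip through plain dicts (YAML/JSON friendly).
# ---------------------------------------------------------------------------

def chain_to_dict(chain: ModeChain) -> dict:
    return {
        "mode": chain.mode,
        "input_state": chain.input_state.as_array().tolist(),
        "elements": [{"kind": e.kind, **e.params} for e in chain.elements],
    }


def chain_from_dict(doc: dict) -> ModeChain:
    known = {"mode", "input_state", "elements"}
    extra = set(doc) - known
    if extra:
        raise ValueError(f"unknown chain config keys: {sorted(extra)}")
    elements = []
    for spec in doc["elements"]:
        spec = dict(spec)
        kind = spec.pop("kind")
        elements.append(make_element(kind, **spec))
    state = doc.get("input_state")
    if state is None:
        input_state = StokesVector4.circular("right")
    else:
        input_state = StokesVector4.from_array(state)
    return ModeChain(mode=doc["mode"], elements=elements, input_state=input_state)
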