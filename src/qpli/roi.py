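"""ROI outcome measures and polarization color maps.

Two scalar outcomes summarize a region of interest:

* **AVG DoLP** — the arithmetic mean of DoLP over the ROI; a proxy for the
  strength of collagen fiber alignment.
* **STD AoP** — the dispersion of the AoP over the ROI; a proxy for the
  spread of fiber orientations.  AoP is axial (180-degree periodic), so a
  naive standard deviation is ill-defined at the branch cut.  The default
  ``recentred`` estimator finds the circular mean axis via the doubled-angle
  resultant, recentres every angle into the 180-degree window around that
  axis, and takes the ordinary population standard deviation — branch-cut
  safe, and identical to the naive computation for concentrated data away
  from the cut.  The ``circular`` estimator instead reports
  ``0.5 * sqrt(-2 ln R2)`` (in degrees), where R2 is the doubled-angle mean
  resultant length.

Color-map rendering mirrors the common display conventions: a sequential
map for DoLP with an adjustable saturation point (reflectance-mode maps are
often rescaled to 0-0.25 so their spatial patterns can be compared with
transmission maps on a 0-1 scale), and a cyclic map for AoP so that -90 and
+90 degrees render identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from matplotlib import colormaps

from qpli.pipeline import StokesImage

__all__ = [
    "RoiOutcome",
    "avg_dolp",
    "std_aop",
    "axial_mean_deg",
    "axial_std_deg",
    "render_map",
    "rectangle_mask",
    "roi_outcome",
]


@dataclass
class RoiOutcome:
    """Scalar outcomes for one ROI of one frame."""

    avg_dolp: float
    std_aop_deg: float
    n_pixels: int
    roi_id: str = "roi0"


def _resolve_mask(stokes: StokesImage, mask: Optional[np.ndarray]) -> np.ndarray:
    if mask is None:
        mask = np.ones(stokes.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stokes.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image shape {stokes.shape}")
    mask = mask & stokes.valid_mask
    if not mask.any():
        raise ValueError("ROI mask selects no valid pixels")
    return mask


def avg_dolp(stokes: StokesImage, mask: Optional[np.ndarray] = None) -> float:
    """Mean DoLP over the ROI (restricted to valid pixels)."""
    mask = _resolve_mask(stokes, mask)
    return float(stokes.dolp[mask].mean())


def axial_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean axis of axial angles, degrees in [-90, 90).

    Computed from the doubled-angle resultant; raises on a zero resultant
    (no preferred axis).
    """
    doubled = np.deg2rad(2.0 * np.asarray(angles_deg, dtype=float))
    z = np.exp(1j * doubled).mean()
    if np.abs(z) < 1e-12:
        raise ValueError("zero resultant: angles have no preferred axis")
    mu = 0.5 * np.degrees(np.angle(z))
    return float(mu - 180.0 * np.floor((mu + 90.0) / 180.0))


def axial_std_deg(angles_deg: np.ndarray, estimator: str = "recentred") -> float:
    """Dispersion of axial angles in degrees.

    ``recentred``: population SD after recentring all angles into the
    180-degree window around the circular mean axis.  ``circular``:
    ``0.5 * sqrt(-2 ln R2)`` where R2 is the doubled-angle mean resultant
    length.
    """
    angles = np.asarray(angles_deg, dtype=float).ravel()
    if angles.size == 0:
        raise ValueError("empty angle set")
    doubled = np.deg2rad(2.0 * angles)
    z = np.exp(1j * doubled).mean()
    r2 = float(np.abs(z))

    if estimator == "circular":
        if r2 <= 0:
            return np.inf
        return float(0.5 * np.sqrt(-2.0 * np.log(r2)) * 180.0 / np.pi)
    if estimator != "recentred":
        raise ValueError(f"unknown estimator {estimator!r}; expected 'recentred' or 'circular'")

    if r2 < 1e-12:
        warnings.warn(
            "zero axial resultant; recentring window centred at 0 deg", stacklevel=2
        )
        mu = 0.0
    else:
        mu = 0.5 * np.degrees(np.angle(z))
    # signed deviation from the mean axis, wrapped into [-90, 90)
    dev = angles - mu
    dev = dev - 180.0 * np.floor((dev + 90.0) / 180.0)
    return float(np.sqrt(np.mean(dev**2) - np.mean(dev) ** 2))


def std_aop(
    stokes: Union[StokesImage, np.ndarray],
    mask: Optional[np.ndarray] = None,
    estimator: str = "recentred",
) -> float:
    """STD AoP over the ROI, degrees.  See :func:`axial_std_deg`."""
    if isinstance(stokes, StokesImage):
        mask = _resolve_mask(stokes, mask)
        angles = stokes.aop_deg[mask]
    else:
        angles = np.asarray(stokes, dtype=float)
        if mask is not None:
            angles = angles[np.asarray(mask, dtype=bool)]
    return axial_std_deg(angles, estimator=estimator)


def roi_outcome(
    stokes: StokesImage,
    mask: Optional[np.ndarray] = None,
    roi_id: str = "roi0",
    estimator: str = "recentred",
) -> RoiOutcome:
    """AVG DoLP and STD AoP for one ROI."""
    resolved = _resolve_mask(stokes, mask)
    return RoiOutcome(
        avg_dolp=avg_dolp(stokes, resolved),
        std_aop_deg=std_aop(stokes, resolved, estimator=estimator),
        n_pixels=int(resolved.sum()),
        roi_id=roi_id,
    )


def rectangle_mask(shape: tuple, top: int, left: int, height: int, width: int) -> np.ndarray:
    """Binary rectangular ROI mask."""
    mask = np.zeros(shape, dtype=bool)
    mask[top : top + height, left : left + width] = True
    return mask


def render_map(
    map2d: np.ndarray,
    kind: str,
    scale_max: float = 1.0,
    cmap: Optional[str] = None,
) -> np.ndarray:
    """Render a DoLP or AoP map to an 8-bit RGB image.

    ``kind='dolp'`` uses a sequential colormap scaled to [0, scale_max];
    values at or above ``scale_max`` saturate at the top of the scale.
    ``kind='aop'`` uses a cyclic (hue-periodic) colormap over [-90, 90) so
    the two ends of the axial interval render identically.
    """
    map2d = np.asarray(map2d, dtype=float)
    if kind == "dolp":
        if not (0.0 < scale_max <= 1.0):
            raise ValueError(f"scale_max must lie in (0, 1], got {scale_max}")
        norm = np.clip(map2d / scale_max, 0.0, 1.0)
        cm = colormaps[cmap or "viridis"]
    elif kind == "aop":
        norm = ((map2d + 90.0) / 180.0) % 1.0
        cm = colormaps[cmap or "hsv"]
    else:
        raise ValueError(f"kind must be 'dolp' or 'aop', got {kind!r}")
    rgba = cm(norm)
    return (rgba[..., :3] * 255).round().astype(np.uint8)
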