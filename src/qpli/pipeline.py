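"""Raw DoFP mosaic to Stokes, DoLP, and AoP images.

The sensor records the four linear analyzer channels (0, 45, 90, 135
degrees) interleaved in 2x2 superpixels.  Processing is: demosaic the frame
into four co-registered channel images (either by direct superpixel
extraction at quarter resolution, or by per-channel bilinear interpolation
at full resolution), then compute the first three Stokes parameters and the
derived polarization maps

    S0   = (I0 + I45 + I90 + I135) / 2
    S1   = I0 - I90
    S2   = I45 - I135
    DoLP = sqrt(S1^2 + S2^2) / S0
    AoP  = 0.5 * atan2(S2, S1)   (degrees, mapped to [-90, 90))

S0 uses all four channels (the redundancy-averaged estimate) rather than
I0 + I90 alone.  Pixels whose S0 falls below a floor (default 1e-3 of the
frame maximum) are flagged invalid instead of propagating unstable ratios.
No gain or extinction-ratio calibration is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from qpli.synth import MosaicImage

__all__ = ["ChannelStack", "StokesImage", "demosaic", "compute_stokes", "process_mosaic"]


@dataclass
class ChannelStack:
    """The four analyzer-channel images on a common grid."""

    i0: np.ndarray
    i45: np.ndarray
    i90: np.ndarray
    i135: np.ndarray
    resolution_mode: str = "interpolated"

    def __post_init__(self) -> None:
        chans = [np.asarray(c, dtype=float) for c in (self.i0, self.i45, self.i90, self.i135)]
        shapes = {c.shape for c in chans}
        if len(shapes) != 1:
            raise ValueError(f"channel images must share one shape, got {shapes}")
        if any(c.min() < 0 for c in chans):
            raise ValueError("channel intensities must be non-negative")
        if self.resolution_mode not in ("interpolated", "superpixel"):
            raise ValueError(f"unknown resolution_mode {self.resolution_mode!r}")
        self.i0, self.i45, self.i90, self.i135 = chans


@dataclass
class StokesImage:
    """Per-pixel Stokes parameters and derived polarization maps."""

    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    dolp: np.ndarray
    aop_deg: np.ndarray
    valid_mask: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.s0.shape


def _interpolate_subgrid(pixels: np.ndarray, r0: int, c0: int) -> np.ndarray:
    """Bilinearly fill one analyzer channel from its stride-2 subgrid.

    Coordinates outside the subgrid's convex hull are clamped, i.e. the
    border is handled by edge replication along each axis.
    """
    h, w = pixels.shape
    rows = np.arange(r0, h, 2)
    cols = np.arange(c0, w, 2)
    interp = RegularGridInterpolator(
        (rows, cols), pixels[r0::2, c0::2], method="linear", bounds_error=True
    )
    rr = np.clip(np.arange(h), rows[0], rows[-1])
    cc = np.clip(np.arange(w), cols[0], cols[-1])
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    return interp(np.stack([grid_r, grid_c], axis=-1))


def demosaic(mosaic: MosaicImage, method: str = "bilinear") -> ChannelStack:
    """Split a raw mosaic into the four analyzer channels.

    ``method='superpixel'`` extracts each channel's native samples directly,
    producing a quarter-resolution stack (one value per 2x2 superpixel).
    ``method='bilinear'`` keeps full resolution: each channel's missing
    three-quarters of pixels are bilinearly interpolated from its own
    stride-2 subgrid, with edge replication at the border.
    """
    if method not in ("bilinear", "superpixel"):
        raise ValueError(f"unknown demosaic method {method!r}")
    pixels = np.asarray(mosaic.pixels, dtype=float)
    h, w = pixels.shape
    if h % 2 or w % 2:
        raise ValueError(f"mosaic dimensions must be even, got {pixels.shape}")

    offsets = {}
    for dr in (0, 1):
        for dc in (0, 1):
            offsets[mosaic.layout[dr][dc]] = (dr, dc)

    channels = {}
    for angle, (dr, dc) in offsets.items():
        if method == "superpixel":
            channels[angle] = pixels[dr::2, dc::2]
        else:
            channels[angle] = _interpolate_subgrid(pixels, dr, dc)
    return ChannelStack(
        i0=channels[0],
        i45=channels[45],
        i90=channels[90],
        i135=channels[135],
        resolution_mode="superpixel" if method == "superpixel" else "interpolated",
    )


def compute_stokes(channels: ChannelStack, s0_floor_frac: float = 1e-3) -> StokesImage:
    """Compute S0, S1, S2 and the DoLP/AoP maps from the channel stack.

    Pixels with ``S0 <= s0_floor_frac * max(S0)`` are masked invalid; their
    DoLP and AoP are set to zero rather than NaN.  DoLP is clipped to [0, 1]
    (noise can push the raw ratio marginally past 1).
    """
    s0 = 0.5 * (channels.i0 + channels.i45 + channels.i90 + channels.i135)
    s1 = channels.i0 - channels.i90
    s2 = channels.i45 - channels.i135

    floor = s0_floor_frac * s0.max() if s0.size else 0.0
    valid = s0 > floor

    lin = np.hypot(s1, s2)
    dolp = np.zeros_like(s0)
    np.divide(lin, s0, out=dolp, where=valid)
    dolp = np.clip(dolp, 0.0, 1.0)
    dolp[~valid] = 0.0

    aop = 0.5 * np.degrees(np.arctan2(s2, s1))
    aop = aop - 180.0 * np.floor((aop + 90.0) / 180.0)
    aop[~valid] = 0.0

    return StokesImage(s0=s0, s1=s1, s2=s2, dolp=dolp, aop_deg=aop, valid_mask=valid)


def process_mosaic(
    mosaic: Union[MosaicImage, np.ndarray],
    method: str = "bilinear",
    s0_floor_frac: float = 1e-3,
) -> StokesImage:
    """Convenience: demosaic then compute Stokes in one call."""
    if not isinstance(mosaic, MosaicImage):
        mosaic = MosaicImage(pixels=mosaic)
    return compute_stokes(demosaic(mosaic, method=method), s0_floor_frac=s0_floor_frac)
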