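"""File I/O and run configuration.

Formats:

* mosaics — HDF5 (dataset ``mosaic`` for single frames, or groups
  ``frames/<i>/mosaic`` for stacks; attributes ``layout`` (2x2 analyzer
  angles), ``mode``, ``handedness``, ``seed``) and 16-bit grayscale TIFF
  (which carries no layout metadata, so the layout must be supplied when
  reading);
* Stokes results — an HDF5 group with datasets ``S0, S1, S2, DoLP, AoP,
  valid_mask``;
* ROI outcomes — CSV with ``#``-prefixed provenance header lines;
* configuration — YAML/JSON documents; unknown keys are rejected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import h5py
import numpy as np
import tifffile
import yaml

from qpli.pipeline import StokesImage
from qpli.roi import RoiOutcome
from qpli.synth import MosaicImage

__all__ = [
    "write_mosaic",
    "read_mosaic",
    "write_mosaic_stack",
    "read_mosaic_stack",
    "write_stokes",
    "read_stokes",
    "write_outcomes_csv",
    "RunConfig",
    "load_config",
]


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk schema."""


def _layout_to_attr(layout) -> np.ndarray:
    return np.asarray(layout, dtype=np.int64)


def write_mosaic(path, mosaic: MosaicImage, config: Optional[dict] = None) -> None:
    """Write a single mosaic frame to HDF5 (``.h5``) or TIFF (``.tif``)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("mosaic", data=mosaic.pixels)
            ds.attrs["layout"] = _layout_to_attr(mosaic.layout)
            ds.attrs["mode"] = mosaic.mode
            ds.attrs["handedness"] = mosaic.handedness
            ds.attrs["seed"] = -1 if mosaic.seed is None else int(mosaic.seed)
            ds.attrs["scene_id"] = mosaic.scene_id
            if config is not None:
                f.attrs["config"] = json.dumps(config, sort_keys=True)
    elif path.suffix in (".tif", ".tiff"):
        pixels = mosaic.pixels
        if np.issubdtype(pixels.dtype, np.floating):
            peak = pixels.max() if pixels.max() > 0 else 1.0
            pixels = np.round(pixels / peak * 65535).astype(np.uint16)
        tifffile.imwrite(path, pixels.astype(np.uint16))
    else:
        raise FormatError(f"unsupported mosaic extension {path.suffix!r} (use .h5 or .tif)")


def read_mosaic(path, layout: Optional[Sequence] = None) -> MosaicImage:
    """Read a single mosaic frame.

    HDF5 files carry their layout as an attribute; TIFF files do not, so
    ``layout`` must be supplied for them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "mosaic" not in f:
                raise FormatError(f"{path}: no 'mosaic' dataset (is this a frame stack?)")
            ds = f["mosaic"]
            if "layout" not in ds.attrs:
                raise FormatError(
                    f"{path}: mosaic dataset lacks a 'layout' attribute; rewrite the file "
                    "with write_mosaic or pass layout= explicitly"
                )
            seed = int(ds.attrs.get("seed", -1))
            return MosaicImage(
                pixels=ds[()],
                layout=tuple(map(tuple, np.asarray(ds.attrs["layout"]))),
                mode=str(ds.attrs.get("mode", "transmission")),
                handedness=str(ds.attrs.get("handedness", "right")),
                seed=None if seed < 0 else seed,
                scene_id=str(ds.attrs.get("scene_id", "")),
            )
    if path.suffix in (".tif", ".tiff"):
        if layout is None:
            raise FormatError(
                f"{path}: TIFF mosaics carry no analyzer layout metadata; pass "
                "layout=((90,45),(135,0))-style 2x2 angles (or use the HDF5 format)"
            )
        return MosaicImage(pixels=tifffile.imread(path), layout=tuple(map(tuple, layout)))
    raise FormatError(f"unsupported mosaic extension {path.suffix!r}")


def write_mosaic_stack(path, mosaics: Sequence[MosaicImage], config: Optional[dict] = None) -> None:
    """Write an ordered stack of frames to ``frames/<i>/mosaic`` groups."""
    with h5py.File(path, "w") as f:
        frames = f.create_group("frames")
        for i, mosaic in enumerate(mosaics):
            ds = frames.create_group(str(i)).create_dataset("mosaic", data=mosaic.pixels)
            ds.attrs["layout"] = _layout_to_attr(mosaic.layout)
            ds.attrs["mode"] = mosaic.mode
            ds.attrs["handedness"] = mosaic.handedness
            ds.attrs["seed"] = -1 if mosaic.seed is None else int(mosaic.seed)
        if config is not None:
            f.attrs["config"] = json.dumps(config, sort_keys=True)


def read_mosaic_stack(path) -> List[MosaicImage]:
    """Read a frame stack, preserving frame order."""
    out = []
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise FormatError(f"{path}: no 'frames' group")
        for key in sorted(f["frames"], key=int):
            ds = f["frames"][key]["mosaic"]
            seed = int(ds.attrs.get("seed", -1))
            out.append(
                MosaicImage(
                    pixels=ds[()],
                    layout=tuple(map(tuple, np.asarray(ds.attrs["layout"]))),
                    mode=str(ds.attrs.get("mode", "transmission")),
                    handedness=str(ds.attrs.get("handedness", "right")),
                    seed=None if seed < 0 else seed,
                )
            )
    return out


def write_stokes(path, stokes: StokesImage, config: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("stokes")
        g.create_dataset("S0", data=stokes.s0)
        g.create_dataset("S1", data=stokes.s1)
        g.create_dataset("S2", data=stokes.s2)
        g.create_dataset("DoLP", data=stokes.dolp)
        g.create_dataset("AoP", data=stokes.aop_deg)
        g.create_dataset("valid_mask", data=stokes.valid_mask)
        if config is not None:
            f.attrs["config"] = json.dumps(config, sort_keys=True)


def read_stokes(path) -> StokesImage:
    with h5py.File(path, "r") as f:
        if "stokes" not in f:
            raise FormatError(f"{path}: no 'stokes' group")
        g = f["stokes"]
        return StokesImage(
            s0=g["S0"][()],
            s1=g["S1"][()],
            s2=g["S2"][()],
            dolp=g["DoLP"][()],
            aop_deg=g["AoP"][()],
            valid_mask=g["valid_mask"][()].astype(bool),
        )


def write_outcomes_csv(path, outcomes: Sequence[RoiOutcome], meta: Optional[dict] = None) -> None:
    """ROI outcomes as CSV with ``#`` provenance header comments."""
    lines = []
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    lines.append("roi_id,n_pixels,avg_dolp,std_aop_deg")
    for o in outcomes:
        lines.append(f"{o.roi_id},{o.n_pixels},{o.avg_dolp:.9f},{o.std_aop_deg:.9f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of one simulate-process-report run."""

    alignment: str = "aligned"
    mode: str = "transmission"
    shape: tuple = (128, 128)
    collagen_density: float = 1.5
    riboflavin_mm: float = 0.0
    transmission_level: float = 1.0
    handedness: str = "right"
    noise: bool = True
    seed: int = 0
    demosaic_method: str = "bilinear"
    estimator: str = "recentred"
    scale_max: float = 1.0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        extra = set(doc) - known
        if extra:
            raise FormatError(f"unknown config keys: {sorted(extra)}")
        doc = dict(doc)
        if "shape" in doc:
            doc["shape"] = tuple(doc["shape"])
        return cls(**doc)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration, rejecting unknown keys."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(doc)
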