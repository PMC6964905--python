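"""Image containers, physical-units bookkeeping and tabular I/O.

Every pipeline in this package consumes an :class:`ImageStack`: a scalar
intensity grid indexed ``[z][y][x]`` together with its physical voxel
spacing in micrometres.  2D images are stored as single-plane stacks
(``z = 1``) so that downstream code never branches on dimensionality for
plumbing reasons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("remodelkit")

__all__ = [
    "ImageStack",
    "BinaryMask",
    "read_image",
    "write_image",
    "write_results",
    "um_to_px",
]


@dataclass(frozen=True)
class ImageStack:
    """A 2D or 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (z, y, x)
        Non-negative, finite intensities. 2D images use ``z = 1``.
    spacing : (dx, dy, dz)
        Voxel pitch in μm along x, y and z. All components positive.
    bit_depth : int
        Nominal acquisition bit depth (8, 16, or 32 for float data).
    channel : str
        Free-text channel label (e.g. ``"TAMRA"``, ``"vinculin"``).
    time_index : int or None
        Frame index within a time-lapse, if applicable.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bit_depth: int = 16
    channel: str = ""
    time_index: int | None = None

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise ValueError(f"expected a 2D or 3D array, got ndim={arr.ndim}")
        if any(d < 1 for d in arr.shape):
            raise ValueError(f"all dimensions must be >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image values must be finite")
        if arr.size and arr.min() < 0:
            raise ValueError("image values must be >= 0")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_2d(self) -> bool:
        return self.values.shape[0] == 1

    @property
    def plane(self) -> np.ndarray:
        """The single (y, x) plane of a 2D stack."""
        if not self.is_2d:
            raise ValueError("stack has more than one plane")
        return self.values[0]

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def pixel_area_um2(self) -> float:
        dx, dy, _ = self.spacing
        return dx * dy

    def with_values(self, values: np.ndarray) -> "ImageStack":
        return replace(self, values=values)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid congruent with an :class:`ImageStack`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise ValueError(f"expected a 2D or 3D mask, got ndim={arr.ndim}")
        object.__setattr__(self, "values", arr.astype(bool))
        sp = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in sp):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_2d(self) -> bool:
        return self.values.shape[0] == 1

    @property
    def plane(self) -> np.ndarray:
        if not self.is_2d:
            raise ValueError("mask has more than one plane")
        return self.values[0]

    def congruent_with(self, img: "ImageStack | BinaryMask") -> bool:
        return self.values.shape == img.values.shape


def um_to_px(length_um: float, spacing_um: float) -> int:
    """Convert a physical length to a voxel count along one axis.

    Rounds to the nearest integer and clamps at a minimum of one voxel,
    so a sub-voxel physical length (e.g. a thin band) still selects a
    one-voxel rim.
    """
    if length_um <= 0:
        raise ValueError(f"length must be positive, got {length_um}")
    if spacing_um <= 0:
        raise ValueError(f"spacing must be positive, got {spacing_um}")
    return max(1, int(np.floor(length_um / spacing_um + 0.5)))


def read_image(
    path: str | Path,
    spacing: Sequence[float] | None = None,
    channel: str = "",
) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    Spacing resolution order: explicit ``spacing`` argument, then TIFF
    resolution tags / ImageJ metadata, then unit spacing (1, 1, 1) μm
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta_spacing = _spacing_from_tiff(tf)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2D or 3D TIFF payload, got shape {arr.shape}")
    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        logger.warning("%s: no spacing metadata found, assuming 1x1x1 um/voxel", path)
        spacing = (1.0, 1.0, 1.0)
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing {spacing}")
    bit_depth = arr.dtype.itemsize * 8 if arr.dtype.kind in "ui" else 32
    logger.info("read %s: shape=%s spacing=%s", path, arr.shape, spacing)
    return ImageStack(values=arr, spacing=spacing, bit_depth=bit_depth, channel=channel)


def _spacing_from_tiff(tf: "tifffile.TiffFile") -> tuple[float, float, float] | None:
    try:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is None or yres is None:
            return None
        xr = xres.value[0] / xres.value[1]
        yr = yres.value[0] / yres.value[1]
        if xr <= 0 or yr <= 0:
            return None
        dz = 1.0
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            dz = float(tf.imagej_metadata["spacing"])
        return (1.0 / xr, 1.0 / yr, dz)
    except Exception:
        return None


def write_image(img: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` to TIFF, preserving dtype and spacing."""
    path = Path(path)
    dx, dy, dz = img.spacing
    arr = img.values
    if arr.shape[0] == 1:
        arr = arr[0]
    tifffile.imwrite(
        path,
        arr,
        resolution=(1.0 / dx, 1.0 / dy),
        imagej=arr.dtype.kind in "uif" and arr.dtype.itemsize <= 4,
        metadata={"spacing": dz, "unit": "um"},
    )


def write_results(records: Iterable[Mapping], path: str | Path) -> None:
    """Write keyed measurement rows as CSV with a header.

    The row order of ``records`` is preserved; floats are written at
    full ``repr`` precision so that a round-trip read is lossless.
    An empty record list still produces a header-only file when the
    records iterable carries no rows (header inferred from nothing is
    an empty file with a newline).
    """
    records = list(records)
    df = pd.DataFrame.from_records(records)
    df.to_csv(path, index=False, float_format=None)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
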