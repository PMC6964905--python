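"""ECM remodeling: FFT fiber-alignment anisotropy and collagen densification.

Fiber alignment is quantified by a Fourier-transform orientation-tensor
method: the power spectrum of a square patch, restricted to a mid-frequency
radial band, is reduced to a 2x2 second-moment orientation tensor whose
eigenvalue contrast alpha = (l1 - l2) / (l1 + l2) is 0 for an isotropic
fiber network and 1 for a fully aligned one.

Densification is the fraction of pixels classed as fiber (moment-preserving
threshold of the whole image) inside regions of interest: 100x100 px
control and alignment windows and a 7-um-thick "doughnut" band around each
cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import ImageStack, BinaryMask
from .thresholds import moments_threshold

__all__ = [
    "AnisotropyResult",
    "RemodelingResult",
    "anisotropy_index",
    "make_band_roi",
    "fiber_density",
    "density_profile",
]


@dataclass(frozen=True)
class AnisotropyResult:
    alpha: float
    orientation_rad: float  # dominant real-space fiber orientation, axial [0, pi)


@dataclass(frozen=True)
class RemodelingResult:
    alpha_control: float
    alpha_alignment: float
    density_control: float
    density_alignment: float
    density_surrounding: float

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def anisotropy_index(
    window: np.ndarray,
    f_lo: float | None = None,
    f_hi: float = 0.45,
) -> AnisotropyResult:
    """Anisotropy index of a square image patch via the spectral orientation tensor.

    The patch is mean-subtracted, Hann-windowed and Fourier transformed;
    spectral power in the radial band ``[f_lo, f_hi]`` (cycles/px,
    defaults: 4/side to 0.45, excluding DC and the Nyquist corners) is
    accumulated into the second-moment orientation tensor over frequency
    direction (axial, period pi).  ``alpha`` is the eigenvalue contrast
    of that tensor; the dominant real-space orientation is the leading
    eigenvector rotated by 90 degrees, since the spectrum of a stripe
    pattern is perpendicular to the stripes.  A featureless patch has
    ``alpha = 0`` by convention.
    """
    patch = np.asarray(window, dtype=float)
    if patch.ndim == 3 and patch.shape[0] == 1:
        patch = patch[0]
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"expected a square 2D patch, got shape {patch.shape}")
    side = patch.shape[0]
    if side < 32:
        raise ValueError(f"patch side must be >= 32 px, got {side}")
    if f_lo is None:
        f_lo = 4.0 / side

    centred = patch - patch.mean()
    hann = np.hanning(side)
    tapered = centred * hann[:, None] * hann[None, :]
    power = np.abs(np.fft.fftshift(np.fft.fft2(tapered))) ** 2

    f = np.fft.fftshift(np.fft.fftfreq(side))
    fx = f[None, :]
    fy = f[:, None]
    r = np.hypot(fx, fy)
    band = (r >= f_lo) & (r <= f_hi)

    total = power[band].sum()
    scale = float(np.abs(patch).max()) + 1.0
    if total <= side * side * (1e-9 * scale) ** 2:
        return AnisotropyResult(alpha=0.0, orientation_rad=float("nan"))

    ux = np.where(r > 0, fx / np.where(r > 0, r, 1.0), 0.0)
    uy = np.where(r > 0, fy / np.where(r > 0, r, 1.0), 0.0)
    p = power[band]
    mxx = float(np.sum(p * ux[band] ** 2))
    myy = float(np.sum(p * uy[band] ** 2))
    mxy = float(np.sum(p * ux[band] * uy[band]))
    tensor = np.array([[mxx, mxy], [mxy, myy]]) / total
    evals, evecs = np.linalg.eigh(tensor)
    l1, l2 = evals[1], evals[0]
    alpha = float((l1 - l2) / (l1 + l2))
    v = evecs[:, 1]
    spectral_theta = np.arctan2(v[1], v[0])
    orientation = (spectral_theta + np.pi / 2.0) % np.pi
    return AnisotropyResult(alpha=alpha, orientation_rad=float(orientation))


def make_band_roi(cell_mask: BinaryMask, thickness_um: float = 7.0) -> BinaryMask:
    """Doughnut band of fixed physical thickness around a cell mask.

    The band is the set of background voxels within ``thickness_um`` of
    the cell (Euclidean distance with anisotropic spacing), excluding the
    cell itself and clipped at the image border.  A thickness below one
    voxel still produces a one-voxel rim.
    """
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    arr = cell_mask.values
    if not arr.any():
        raise ValueError("empty cell mask")
    dx, dy, dz = cell_mask.spacing
    is2d = arr.shape[0] == 1
    if is2d:
        dist = ndi.distance_transform_edt(~arr[0], sampling=(dy, dx))[np.newaxis]
        rim = max(dx, dy)
    else:
        dist = ndi.distance_transform_edt(~arr, sampling=(dz, dy, dx))
        rim = max(dx, dy, dz)
    eff = max(thickness_um, rim)  # clamp: never thinner than one voxel
    band = (dist > 0) & (dist <= eff)
    return BinaryMask(band, cell_mask.spacing)


def fiber_density(img: ImageStack, roi: BinaryMask | np.ndarray) -> float:
    """Fraction of ROI pixels occupied by fibers.

    The whole image is binarized once with the moment-preserving
    threshold (so densities of different ROIs are directly comparable),
    then the density is the fiber-pixel fraction within the ROI.
    """
    roi_arr = roi.values if isinstance(roi, BinaryMask) else np.asarray(roi, dtype=bool)
    if roi_arr.ndim == 2:
        roi_arr = roi_arr[np.newaxis]
    if roi_arr.shape != img.values.shape:
        raise ValueError("ROI shape does not match image")
    n_roi = int(roi_arr.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    t = moments_threshold(img.values).threshold
    fibers = img.values > t
    return float(np.logical_and(fibers, roi_arr).sum() / n_roi)


def window_roi(
    shape: tuple[int, int, int], y: int, x: int, side: int = 100, z: int = 0
) -> np.ndarray:
    """Boolean ROI for a square side x side window with top-left (y, x)."""
    nz, ny, nx = shape
    if y < 0 or x < 0 or y + side > ny or x + side > nx:
        raise ValueError("window must lie fully inside the image")
    roi = np.zeros(shape, dtype=bool)
    roi[z, y : y + side, x : x + side] = True
    return roi


def place_control_window(
    cell_mask: BinaryMask, side: int = 100, clearance_um: float = 7.0
) -> tuple[int, int]:
    """Automatic control-window placement in a non-cellular region.

    Returns the top-left (y, x) of the ``side x side`` window (on the
    first plane) with minimum overlap with the cell mask dilated by
    ``clearance_um``; ties resolve to the smallest (y, x).
    """
    arr = cell_mask.values[0]
    dx, dy, _ = cell_mask.spacing
    if arr.any():
        dist = ndi.distance_transform_edt(~arr, sampling=(dy, dx))
        occupied = (dist <= clearance_um).astype(float)
    else:
        occupied = np.zeros_like(arr, dtype=float)
    # Overlap of each window via a box sum (uniform filter).
    box = ndi.uniform_filter(occupied, size=side, mode="constant", origin=0)
    half = side // 2
    ny, nx = arr.shape
    centers = box[half : ny - side + half + 1, half : nx - side + half + 1]
    iy, ix = np.unravel_index(np.argmin(centers), centers.shape)
    return int(iy), int(ix)


def density_profile(
    img: ImageStack,
    cell_mask: BinaryMask,
    control_window: tuple[int, int] | None = None,
    alignment_window: tuple[int, int] | None = None,
    side: int = 100,
    band_thickness_um: float = 7.0,
    exclude_cells: bool = True,
) -> dict[str, float]:
    """Control / alignment / surrounding densities of one image.

    The surrounding density is measured in the doughnut band around the
    cells; window ROIs optionally exclude cell pixels from the
    denominator.
    """
    if control_window is None:
        control_window = place_control_window(cell_mask, side=side)
    rois: dict[str, np.ndarray] = {}
    rois["control"] = window_roi(img.shape, *control_window, side=side)
    if alignment_window is not None:
        rois["alignment"] = window_roi(img.shape, *alignment_window, side=side)
    rois["surrounding"] = make_band_roi(cell_mask, band_thickness_um).values
    out = {}
    for kind, roi in rois.items():
        if exclude_cells and kind != "surrounding":
            roi = roi & ~cell_mask.values
        out[f"density_{kind}"] = fiber_density(img, roi)
    return out
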