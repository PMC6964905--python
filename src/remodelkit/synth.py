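"""Ground-truthed synthetic fluorescence scenes.

Each generator emulates one acquisition used by the analysis pipelines:

* :func:`generate_fiber_image` — a TAMRA-like collagen fiber mesh, built
  from persistent random walks with a von Mises orientation model, so that
  both alignment (``kappa_orient``) and straightness (``kappa_step``) are
  controlled and known.
* :func:`generate_fa_scene` — a cell with vinculin-like punctae (2D or 3D).
* :func:`generate_dq_scene` — degradation blobs of exactly known voxel volume.
* :func:`generate_timelapse` — bright moving discs with known accumulated
  path length per cell.

All ground truth is computed from geometry *before* rasterization and
noise, and every generator is bitwise deterministic under a fixed seed.
Separation constraints (between punctae, blobs and cells) are enforced so
recovery tests have unambiguous expected values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .core import ImageStack, BinaryMask
from .motility import Track, TrackSet

__all__ = [
    "FiberFieldParams",
    "FaSceneParams",
    "TrackSimParams",
    "generate_fiber_image",
    "generate_fa_scene",
    "generate_dq_scene",
    "generate_timelapse",
]

# Treat any von Mises concentration at or above this as the aligned limit.
_KAPPA_INF = 1e6
# Gaussian HWHM in units of sigma.
_HWHM = math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class FiberFieldParams:
    """Parameters of the persistent-random-walk fiber field.

    ``kappa_orient`` concentrates initial fiber orientations about
    ``theta0`` (axial, modulo pi; 0 = isotropic), ``kappa_step``
    concentrates the per-step turning angle about zero and therefore
    controls persistence length.  ``length_um`` is the contour length of
    each fiber.
    """

    n_fibers: int = 150
    length_um: float = 15.0
    step_um: float = 0.5
    kappa_step: float = 50.0
    kappa_orient: float = 0.0
    theta0: float = 0.0
    radius_px: float = 1.5
    shape: tuple[int, int] = (256, 256)
    spacing: tuple[float, float, float] = (0.099, 0.099, 0.42)
    fiber_peak: float = 200.0
    background: float = 10.0
    noise: tuple[float, float] = (2.0, 0.0)  # (gaussian_sigma, poisson_scale)
    seed: int = 0

    def __post_init__(self):
        if self.kappa_orient < 0 or self.kappa_step < 0:
            raise ValueError("von Mises concentrations must be >= 0")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.radius_px < 0.5:
            raise ValueError("radius_px must be >= 0.5")


def _vonmises(rng: np.random.Generator, kappa: float, size: int) -> np.ndarray:
    """Von Mises(0, kappa) sample; the aligned limit collapses to zero."""
    if kappa >= _KAPPA_INF:
        return np.zeros(size)
    if kappa == 0.0:
        return rng.uniform(-np.pi, np.pi, size)
    return rng.vonmises(0.0, kappa, size)


def fiber_polylines(params: FiberFieldParams) -> list[np.ndarray]:
    """Ground-truth fiber polylines in um, columns (x, y)."""
    rng = np.random.default_rng(params.seed)
    ny, nx = params.shape
    dx, dy, _ = params.spacing
    extent = np.array([nx * dx, ny * dy])
    n_steps = max(1, int(round(params.length_um / params.step_um)))
    polylines = []
    for _ in range(params.n_fibers):
        # Axial von Mises: half of a doubled-angle sample about theta0.
        theta = (params.theta0 + 0.5 * _vonmises(rng, params.kappa_orient, 1)[0]) % np.pi
        if rng.random() < 0.5:
            theta += np.pi
        start = rng.uniform(0.0, 1.0, 2) * extent
        turns = _vonmises(rng, params.kappa_step, n_steps)
        angles = theta + np.concatenate([[0.0], np.cumsum(turns[1:])])
        steps = params.step_um * np.column_stack([np.cos(angles), np.sin(angles)])
        pts = start + np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        polylines.append(pts)
    return polylines


def rasterize_polylines(
    polylines: list[np.ndarray],
    shape: tuple[int, int],
    spacing: tuple[float, float, float],
    radius_px: float,
) -> np.ndarray:
    """Render polylines with a Gaussian cross profile, peak-normalized to 1."""
    ny, nx = shape
    dx, dy, _ = spacing
    canvas = np.zeros((ny, nx))
    for pts in polylines:
        cols = np.round(pts[:, 0] / dx).astype(int)
        rows = np.round(pts[:, 1] / dy).astype(int)
        for i in range(len(pts) - 1):
            rr, cc = draw_line(rows[i], cols[i], rows[i + 1], cols[i + 1])
            keep = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
            canvas[rr[keep], cc[keep]] = 1.0
    sigma = radius_px / _HWHM
    blurred = ndi.gaussian_filter(canvas, sigma)
    peak = blurred.max()
    return blurred / peak if peak > 0 else blurred


def _add_noise(img: np.ndarray, noise: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    gaussian_sigma, poisson_scale = noise
    out = img.astype(float)
    if poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * poisson_scale) / poisson_scale
    if gaussian_sigma > 0:
        out = out + rng.normal(0.0, gaussian_sigma, out.shape)
    return np.clip(out, 0.0, None)


def generate_fiber_image(params: FiberFieldParams) -> tuple[ImageStack, list[np.ndarray]]:
    """Render a fiber field and return it with its ground-truth polylines."""
    polylines = fiber_polylines(params)
    profile = rasterize_polylines(polylines, params.shape, params.spacing, params.radius_px)
    img = params.background + params.fiber_peak * profile
    rng = np.random.default_rng(params.seed + 1)
    img = _add_noise(img, params.noise, rng)
    stack = ImageStack(values=img, spacing=params.spacing, bit_depth=32, channel="TAMRA")
    return stack, polylines


# ---------------------------------------------------------------------------
# Focal-adhesion scenes


@dataclass(frozen=True)
class FaSceneParams:
    """A single cell with non-overlapping vinculin-like punctae.

    Sizes are the footprint at half maximum: area in px^2 for 2D scenes,
    volume in voxels for 3D scenes.  ``min_sep_px`` is the minimum
    in-plane centre separation enforced between punctae.
    """

    n_fa: int = 12
    # Half-maximum footprint: 100-200 px^2 is 1-2 um^2 at 0.099 um/px, the
    # size of a mature adhesion and the scale the LoG filter is matched to.
    fa_size_range: tuple[float, float] = (100.0, 200.0)  # px^2 (2D) or vox (3D)
    fa_peak: float = 200.0
    cell_intensity: float = 30.0
    background: float = 10.0
    noise_sigma: float = 20.0
    cell_axes_px: tuple[float, ...] = (200.0, 150.0)     # (a_x, a_y[, a_z vox])
    nucleus_radius_um: float = 5.0
    min_sep_px: float = 25.0
    shape: tuple[int, ...] = (512, 512)
    spacing: tuple[float, float, float] = (0.099, 0.099, 0.42)
    # Place punctae only beyond the 5-um perinuclear band (adhesions sit at
    # protrusions, not around the nucleus); 3D scenes only.
    avoid_perinuclear: bool = False
    max_tries: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.n_fa < 0:
            raise ValueError("n_fa must be >= 0")


def _ellipse_mask_2d(shape, center, axes):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((xx - center[0]) / axes[0]) ** 2 + ((yy - center[1]) / axes[1]) ** 2 <= 1.0


def _ellipsoid_mask(shape, center, axes):
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    return (
        ((xx - center[0]) / axes[0]) ** 2
        + ((yy - center[1]) / axes[1]) ** 2
        + ((zz - center[2]) / axes[2]) ** 2
        <= 1.0
    )


def generate_fa_scene(params: FaSceneParams, dims: int = 2):
    """Build a focal-adhesion scene.

    Returns ``(image, truth, cell_mask, nucleus_mask)`` where ``truth`` is
    a DataFrame with per-punctum centre (um and px), half-maximum footprint
    size, Gaussian sigma, and a ``perinuclear`` flag marking punctae whose
    centre lies within 5 um of the nucleus (dilated-nucleus membership).
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    rng = np.random.default_rng(params.seed)
    dx, dy, dz = params.spacing

    if dims == 2:
        ny, nx = params.shape[-2:]
        center = (nx / 2.0, ny / 2.0)
        ax, ay = params.cell_axes_px[:2]
        cell = _ellipse_mask_2d((ny, nx), center, (ax, ay))
        nuc_r_px = params.nucleus_radius_um / dx
        nucleus = _ellipse_mask_2d((ny, nx), center, (nuc_r_px, nuc_r_px))
        placements = _place_points_2d(rng, params, center, (ax, ay))
        img = np.full((ny, nx), params.background)
        img[cell] = params.cell_intensity
        records = []
        yy, xx = np.mgrid[0:ny, 0:nx]
        for cx, cy in placements:
            area = rng.uniform(*params.fa_size_range)
            sigma = math.sqrt(area / math.pi) / _HWHM
            img += params.fa_peak * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
            )
            d_nuc = math.hypot(cx - center[0], cy - center[1]) * dx
            records.append(
                dict(
                    x_px=cx, y_px=cy, x_um=cx * dx, y_um=cy * dy,
                    size=area, sigma_px=sigma,
                    perinuclear=d_nuc <= params.nucleus_radius_um + 5.0,
                )
            )
        img = _add_noise(img, (params.noise_sigma, 0.0), rng)
        truth = pd.DataFrame(records)
        return (
            ImageStack(img, params.spacing, 32, "vinculin"),
            truth,
            BinaryMask(cell, params.spacing),
            BinaryMask(nucleus, params.spacing),
        )

    nz, ny, nx = params.shape if len(params.shape) == 3 else (32, *params.shape)
    axes = params.cell_axes_px if len(params.cell_axes_px) == 3 else (50.0, 40.0, 10.0)
    center = (nx / 2.0, ny / 2.0, nz / 2.0)
    cell = _ellipsoid_mask((nz, ny, nx), center, axes)
    nuc_axes = (
        params.nucleus_radius_um / dx,
        params.nucleus_radius_um / dy,
        params.nucleus_radius_um / dz,
    )
    nucleus = _ellipsoid_mask((nz, ny, nx), center, nuc_axes)
    placements = _place_points_3d(rng, params, center, axes)
    img = np.full((nz, ny, nx), params.background)
    img[cell] = params.cell_intensity
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    records = []
    voxvol = dx * dy * dz
    for cx, cy, cz in placements:
        vol_vox = rng.uniform(*params.fa_size_range)
        # Half-maximum sphere of matching physical volume.
        r_um = (3.0 * vol_vox * voxvol / (4.0 * math.pi)) ** (1.0 / 3.0)
        sigma_um = r_um / _HWHM
        sx, sy, sz = sigma_um / dx, sigma_um / dy, sigma_um / dz
        img += params.fa_peak * np.exp(
            -(
                (xx - cx) ** 2 / (2 * sx**2)
                + (yy - cy) ** 2 / (2 * sy**2)
                + (zz - cz) ** 2 / (2 * sz**2)
            )
        )
        d_nuc_um = math.sqrt(
            ((cx - center[0]) * dx) ** 2
            + ((cy - center[1]) * dy) ** 2
            + ((cz - center[2]) * dz) ** 2
        )
        records.append(
            dict(
                x_px=cx, y_px=cy, z_px=cz,
                x_um=cx * dx, y_um=cy * dy, z_um=cz * dz,
                size=vol_vox, sigma_um=sigma_um,
                perinuclear=d_nuc_um <= params.nucleus_radius_um + 5.0,
            )
        )
    img = _add_noise(img, (params.noise_sigma, 0.0), rng)
    truth = pd.DataFrame(records)
    return (
        ImageStack(img, params.spacing, 32, "vinculin"),
        truth,
        BinaryMask(cell, params.spacing),
        BinaryMask(nucleus, params.spacing),
    )


def _place_points_2d(rng, params, center, axes):
    pts: list[tuple[float, float]] = []
    margin = 0.85  # keep punctae away from the cell rim
    for _ in range(params.max_tries):
        if len(pts) == params.n_fa:
            break
        u, v = rng.uniform(-1, 1, 2)
        if u * u + v * v > 1:
            continue
        cx = center[0] + u * axes[0] * margin
        cy = center[1] + v * axes[1] * margin
        if all(math.hypot(cx - px, cy - py) >= params.min_sep_px for px, py in pts):
            pts.append((cx, cy))
    if len(pts) < params.n_fa:
        raise RuntimeError(
            f"could not place {params.n_fa} punctae with separation "
            f">= {params.min_sep_px} px after {params.max_tries} tries"
        )
    return pts


def _place_points_3d(rng, params, center, axes):
    pts: list[tuple[float, float, float]] = []
    margin = 0.85
    for _ in range(params.max_tries):
        if len(pts) == params.n_fa:
            break
        u = rng.uniform(-1, 1, 3)
        if np.dot(u, u) > 1:
            continue
        cx = center[0] + u[0] * axes[0] * margin
        cy = center[1] + u[1] * axes[1] * margin
        cz = center[2] + u[2] * axes[2] * margin
        dxs, dys, dzs = params.spacing
        if params.avoid_perinuclear:
            d_nuc = math.sqrt(
                ((cx - center[0]) * dxs) ** 2
                + ((cy - center[1]) * dys) ** 2
                + ((cz - center[2]) * dzs) ** 2
            )
            # one blob radius of slack beyond the exclusion band
            if d_nuc <= params.nucleus_radius_um + 5.0 + 1.5:
                continue
        if all(
            math.sqrt(
                ((cx - px) * dxs) ** 2 + ((cy - py) * dys) ** 2 + ((cz - pz) * dzs) ** 2
            )
            >= params.min_sep_px * dxs
            for px, py, pz in pts
        ):
            pts.append((cx, cy, cz))
    if len(pts) < params.n_fa:
        raise RuntimeError("could not place all punctae; relax n_fa or min_sep_px")
    return pts


# ---------------------------------------------------------------------------
# DQ-collagen degradation scenes


def generate_dq_scene(
    n_blobs: int,
    blob_vox_each: int,
    n_cells: int,
    shape: tuple[int, int, int] = (40, 128, 128),
    spacing: tuple[float, float, float] = (0.312, 0.312, 0.49),
    blob_peak: float = 200.0,
    background: float = 10.0,
    noise_sigma: float = 4.0,
    min_gap_px: int = 8,
    seed: int = 0,
) -> tuple[ImageStack, float, int]:
    """Scatter compact clusters of exactly ``blob_vox_each`` voxels each.

    Blobs are raster-filled near-cubes, pairwise separated by more than
    ``min_gap_px`` voxels (must exceed the closing diameter used in
    segmentation), so the measured total volume has an exact expectation:
    ``n_blobs * blob_vox_each * voxel volume``.

    Returns ``(stack, truth_total_volume_um3, n_cells)``.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    dx, dy, dz = spacing
    side = max(1, int(math.ceil(blob_vox_each ** (1.0 / 3.0))))
    img = np.full(shape, background)

    centers: list[tuple[int, int, int]] = []
    tries = 0
    while len(centers) < n_blobs:
        tries += 1
        if tries > 10000:
            raise RuntimeError("could not place blobs with the required separation")
        cz = int(rng.integers(side, max(side + 1, nz - 2 * side)))
        cy = int(rng.integers(side, max(side + 1, ny - 2 * side)))
        cx = int(rng.integers(side, max(side + 1, nx - 2 * side)))
        min_sep = side + min_gap_px
        if all(
            max(abs(cz - z0), abs(cy - y0), abs(cx - x0)) > min_sep for z0, y0, x0 in centers
        ):
            centers.append((cz, cy, cx))

    for cz, cy, cx in centers:
        placed = 0
        for z in range(side + 1):
            for y in range(side):
                for x in range(side):
                    if placed == blob_vox_each:
                        break
                    img[cz + z, cy + y, cx + x] = blob_peak
                    placed += 1
                if placed == blob_vox_each:
                    break
            if placed == blob_vox_each:
                break

    img = _add_noise(img, (noise_sigma, 0.0), rng)
    truth_um3 = n_blobs * blob_vox_each * dx * dy * dz
    return ImageStack(img, spacing, 32, "DQ-collagen"), truth_um3, n_cells


# ---------------------------------------------------------------------------
# Migration time-lapses


@dataclass(frozen=True)
class TrackSimParams:
    """Moving bright discs with known per-frame displacements.

    The acquisition defaults mirror a 15-minute-interval, 12-hour
    time-lapse (49 frames).  Cells never come closer than
    ``4 * cell_radius`` (or ``min_separation_um`` if larger), which makes
    nearest-neighbour linking unambiguous.
    """

    n_cells: int = 4
    n_frames: int = 49
    dt_min: float = 15.0
    step_um: float = 2.0
    drift_um: tuple[float, float] = (0.0, 0.0)
    cell_radius_px: float = 8.0
    shape: tuple[int, int] = (256, 256)
    spacing: tuple[float, float, float] = (1.25, 1.25, 1.0)
    min_separation_um: float | None = None
    cell_peak: float = 200.0
    background: float = 10.0
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be > 0")


def generate_timelapse(params: TrackSimParams) -> tuple[list[ImageStack], TrackSet]:
    """Simulate a 2D time-lapse and its ground-truth tracks (um)."""
    rng = np.random.default_rng(params.seed)
    ny, nx = params.shape
    dx, dy, _ = params.spacing
    r_um = params.cell_radius_px * dx
    sep = 4.0 * r_um
    if params.min_separation_um is not None:
        sep = max(sep, params.min_separation_um)
    margin = r_um + 3.0 * dx
    extent = np.array([nx * dx - 2 * margin, ny * dy - 2 * margin])
    if np.any(extent <= 0):
        raise RuntimeError("image too small for the requested cell radius")

    # Initial placement by dart throwing.
    pos = []
    for _ in range(20000):
        if len(pos) == params.n_cells:
            break
        cand = margin + rng.uniform(0, 1, 2) * extent
        if all(np.hypot(*(cand - p)) >= sep for p in pos):
            pos.append(cand)
    if len(pos) < params.n_cells:
        raise RuntimeError("crowding constraint unsatisfiable at this density")
    positions = np.array(pos)  # (n_cells, 2) in um, columns (x, y)

    drift = np.asarray(params.drift_um, dtype=float)
    traj = np.empty((params.n_frames, params.n_cells, 2))
    traj[0] = positions
    for t in range(1, params.n_frames):
        cur = traj[t - 1].copy()
        for i in range(params.n_cells):
            for _ in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                step = params.step_um * np.array([np.cos(ang), np.sin(ang)]) + drift
                cand = cur[i] + step
                inside = np.all(cand >= margin) and cand[0] <= nx * dx - margin and cand[1] <= ny * dy - margin
                clear = all(
                    np.hypot(*(cand - cur[j])) >= sep for j in range(params.n_cells) if j != i
                )
                if inside and clear:
                    cur[i] = cand
                    break
            else:
                raise RuntimeError("crowding constraint unsatisfiable during the walk")
        traj[t] = cur

    frames = []
    yy, xx = np.mgrid[0:ny, 0:nx]
    for t in range(params.n_frames):
        img = np.full((ny, nx), params.background)
        for i in range(params.n_cells):
            cx, cy = traj[t, i] / (dx, dy)
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= params.cell_radius_px**2
            img[disc] = params.cell_peak
        img = _add_noise(img, (params.noise_sigma, 0.0), rng)
        frames.append(ImageStack(img, params.spacing, 32, "CellBrite", time_index=t))

    tracks = [
        Track(cell_id=i, frames=list(range(params.n_frames)), xy=traj[:, i, :].copy())
        for i in range(params.n_cells)
    ]
    return frames, TrackSet(tracks=tracks, dt_min=params.dt_min)
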