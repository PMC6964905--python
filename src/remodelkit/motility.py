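"""Cell segmentation, tracking and motility statistics for 2D time-lapses.

The measurement chain follows the standard time-lapse workflow: CLAHE
contrast enhancement, a region-mean (intermeans fixed point) two-phase
segmentation, constrained mutual-nearest-neighbour frame linking, and
per-track accumulated distance / speed statistics.  The headline numbers
are the mean accumulated distance (MAD, um) over tracks and the mean
speed in um/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import exposure

from .core import ImageStack
from .thresholds import intermeans_threshold

__all__ = [
    "Track",
    "TrackSet",
    "MotilityResult",
    "enhance_frame",
    "segment_cells",
    "link_tracks",
    "motility_stats",
    "track_timelapse",
]


@dataclass
class Track:
    """One cell's trajectory: frame indices and (x, y) positions in um."""

    cell_id: int
    frames: list[int]
    xy: np.ndarray  # (n, 2), columns (x_um, y_um)

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and positions differ in length")
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise ValueError("frame indices must strictly increase")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def accumulated_distance(self) -> float:
        """Total path length: sum of frame-to-frame displacements (um)."""
        if len(self.xy) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.xy, axis=0), axis=1).sum())


@dataclass
class TrackSet:
    tracks: list[Track]
    dt_min: float  # minutes between frames

    def __len__(self) -> int:
        return len(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for f, (x, y) in zip(tr.frames, tr.xy):
                rows.append(
                    dict(track_id=tr.cell_id, frame=f, t_min=f * self.dt_min, x_um=x, y_um=y)
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MotilityResult:
    mad_um: float
    mean_speed_um_per_h: float
    n_tracks: int


def enhance_frame(
    frame: ImageStack, block: int = 64, bins: int = 256, slope: float = 3.0
) -> ImageStack:
    """Contrast-limited adaptive histogram equalization of one 2D frame.

    Output is range-normalized to [0, 1].  A constant frame passes
    through unchanged (rescaled to zeros).
    """
    img = frame.plane.astype(float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return frame.with_values(np.zeros_like(img)[np.newaxis])
    norm = (img - lo) / (hi - lo)
    out = exposure.equalize_adapthist(
        norm, kernel_size=block, clip_limit=slope / bins, nbins=bins
    )
    return frame.with_values(out[np.newaxis])


def segment_cells(frame: ImageStack, min_area_px: int = 20) -> pd.DataFrame:
    """Segment bright cells by the region-mean two-phase partition.

    The foreground/background split is the intermeans fixed point (each
    region represented by its mean intensity); connected components of at
    least ``min_area_px`` pixels become detections.  Returns a DataFrame
    with columns label, area_px, x_um, y_um (centroids at pixel centres).
    """
    img = frame.plane.astype(float)
    if img.max() == img.min():
        return pd.DataFrame(columns=["label", "area_px", "x_um", "y_um"])
    t = intermeans_threshold(img)
    mask = img > t
    labels, n = ndi.label(mask)
    if n == 0:
        return pd.DataFrame(columns=["label", "area_px", "x_um", "y_um"])
    areas = ndi.sum_labels(np.ones_like(img), labels, index=np.arange(1, n + 1))
    centroids = ndi.center_of_mass(mask, labels, index=np.arange(1, n + 1))
    dx, dy, _ = frame.spacing
    rows = []
    for lab, area, (cy, cx) in zip(range(1, n + 1), areas, centroids):
        if area >= min_area_px:
            rows.append(dict(label=lab, area_px=float(area), x_um=cx * dx, y_um=cy * dy))
    return pd.DataFrame(rows)


def link_tracks(
    detections: list[pd.DataFrame], max_disp_um: float = 30.0, dt_min: float = 15.0
) -> TrackSet:
    """Greedy mutual-nearest-neighbour linking between consecutive frames.

    A link is made only when two detections are each other's nearest
    neighbour and their distance is at most ``max_disp_um``; ties are
    broken by smaller distance, then lower label id.  Unmatched
    detections start new tracks; there is no gap closing.
    """
    if len(detections) < 2:
        raise ValueError("need at least two frames of detections")
    next_id = 0
    open_tracks: dict[int, Track] = {}  # keyed by detection row index in previous frame
    all_tracks: list[Track] = []

    prev = detections[0].reset_index(drop=True)
    for i in range(len(prev)):
        tr = Track(cell_id=next_id, frames=[0], xy=prev.loc[[i], ["x_um", "y_um"]].values)
        open_tracks[i] = tr
        all_tracks.append(tr)
        next_id += 1

    for f in range(1, len(detections)):
        cur = detections[f].reset_index(drop=True)
        links: dict[int, int] = {}
        if len(prev) and len(cur):
            p = prev[["x_um", "y_um"]].values
            c = cur[["x_um", "y_um"]].values
            d = np.linalg.norm(p[:, None, :] - c[None, :, :], axis=2)
            nn_pc = d.argmin(axis=1)  # for each prev, closest cur
            nn_cp = d.argmin(axis=0)  # for each cur, closest prev
            candidates = [
                (d[i, nn_pc[i]], i, int(nn_pc[i]))
                for i in range(len(p))
                if nn_cp[nn_pc[i]] == i and d[i, nn_pc[i]] <= max_disp_um
            ]
            for _, i, j in sorted(candidates):
                if j not in links.values():
                    links[i] = j
        new_open: dict[int, Track] = {}
        for i, j in links.items():
            tr = open_tracks[i]
            tr.frames.append(f)
            tr.xy = np.vstack([tr.xy, cur.loc[j, ["x_um", "y_um"]].values])
            new_open[j] = tr
        for j in range(len(cur)):
            if j not in new_open:
                tr = Track(cell_id=next_id, frames=[f], xy=cur.loc[[j], ["x_um", "y_um"]].values)
                new_open[j] = tr
                all_tracks.append(tr)
                next_id += 1
        open_tracks = new_open
        prev = cur

    return TrackSet(tracks=all_tracks, dt_min=dt_min)


def motility_stats(tracks: TrackSet, min_track_frames: int = 2) -> MotilityResult:
    """Mean accumulated distance (MAD) and mean speed over qualifying tracks.

    Per track: accumulated distance is the summed frame-to-frame path
    length in um; speed is that distance divided by the track's elapsed
    time in hours.  MAD and mean speed average these over all tracks with
    at least ``min_track_frames`` frames.
    """
    ads, speeds = [], []
    for tr in tracks.tracks:
        if tr.n_frames < max(2, min_track_frames):
            continue
        ad = tr.accumulated_distance()
        hours = (tr.frames[-1] - tr.frames[0]) * tracks.dt_min / 60.0
        ads.append(ad)
        speeds.append(ad / hours)
    if not ads:
        raise ValueError("no qualifying tracks")
    return MotilityResult(
        mad_um=float(np.mean(ads)),
        mean_speed_um_per_h=float(np.mean(speeds)),
        n_tracks=len(ads),
    )


def track_timelapse(
    frames: list[ImageStack],
    min_area_px: int = 20,
    max_disp_um: float = 30.0,
    dt_min: float = 15.0,
    clahe_block: int = 64,
    clahe_bins: int = 256,
    clahe_slope: float = 3.0,
    min_track_fraction: float = 0.75,
) -> tuple[TrackSet, MotilityResult]:
    """Full pipeline: enhance, segment, link, and summarize a time-lapse.

    Tracks must span at least ``min_track_fraction`` of the acquisition
    to enter the MAD/speed averages.
    """
    detections = [
        segment_cells(enhance_frame(fr, clahe_block, clahe_bins, clahe_slope), min_area_px)
        for fr in frames
    ]
    tracks = link_tracks(detections, max_disp_um=max_disp_um, dt_min=dt_min)
    min_frames = max(2, int(np.ceil(min_track_fraction * len(frames))))
    stats = motility_stats(tracks, min_track_frames=min_frames)
    return tracks, stats
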