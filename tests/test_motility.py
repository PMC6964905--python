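import numpy as np
import pandas as pd
import pytest

import remodelkit as rk
from remodelkit.core import ImageStack
from remodelkit.motility import Track, TrackSet

# Published migration table: MAD (um) and speed (um/h) per hydrogel and
# treatment over the 12-hour acquisition.
TABLE4 = {
    ("C", "control"): (82.73, 6.89),
    ("CM", "control"): (150.52, 12.54),
    ("CM+", "control"): (57.80, 4.82),
    ("C", "gm6001"): (68.15, 5.68),
    ("CM", "gm6001"): (67.25, 5.60),
    ("CM+", "gm6001"): (38.49, 3.21),
}


def straight_track(ad_um: float, n_frames: int = 49, cell_id: int = 0) -> Track:
    xs = np.linspace(0.0, ad_um, n_frames)
    return Track(cell_id=cell_id, frames=list(range(n_frames)), xy=np.column_stack([xs, np.zeros(n_frames)]))


def shannon_entropy(img: np.ndarray, bins: int = 64) -> float:
    p, _ = np.histogram(img, bins=bins, range=(img.min(), img.max() + 1e-12))
    p = p / p.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class TestEnhanceFrame:
    def test_constant_frame_passes_through(self):
        frame = ImageStack(np.full((1, 64, 64), 42.0))
        out = rk.enhance_frame(frame)
        assert np.ptp(out.values) == 0.0

    def test_entropy_non_decreasing(self):
        rng = np.random.default_rng(2)
        img = np.clip(rng.normal(30, 5, (128, 128)), 0, None)
        img[40:60, 40:60] += 100
        frame = ImageStack(img)
        out = rk.enhance_frame(frame)
        assert shannon_entropy(out.plane) >= shannon_entropy(img / img.max()) - 1e-9

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        frame = ImageStack(np.clip(rng.normal(20, 4, (1, 64, 64)), 0, None))
        a = rk.enhance_frame(frame).values
        b = rk.enhance_frame(frame).values
        np.testing.assert_array_equal(a, b)


class TestSegmentCells:
    def test_single_disc_centroid(self):
        yy, xx = np.mgrid[0:128, 0:128]
        img = np.where((yy - 60.3) ** 2 + (xx - 70.6) ** 2 <= 64, 200.0, 10.0)
        det = rk.segment_cells(ImageStack(img, (1.25, 1.25, 1.0)))
        assert len(det) == 1
        assert det.x_um.iloc[0] == pytest.approx(70.6 * 1.25, abs=0.5 * 1.25)
        assert det.y_um.iloc[0] == pytest.approx(60.3 * 1.25, abs=0.5 * 1.25)

    def test_two_discs_two_labels(self):
        yy, xx = np.mgrid[0:128, 0:128]
        img = np.full((128, 128), 10.0)
        for c in ((40, 40), (90, 90)):
            img[(yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= 64] = 200.0
        det = rk.segment_cells(ImageStack(img))
        assert len(det) == 2

    def test_generator_frames_fully_detected(self):
        for seed in range(10):
            p = rk.TrackSimParams(n_cells=3, n_frames=2, seed=seed)
            frames, _ = rk.generate_timelapse(p)
            det = rk.segment_cells(rk.enhance_frame(frames[0]))
            assert len(det) == 3


class TestLinkTracks:
    def _detections(self, positions):
        """positions: list per frame of (x, y) tuples."""
        return [
            pd.DataFrame([dict(label=i + 1, x_um=x, y_um=y) for i, (x, y) in enumerate(pts)])
            for pts in positions
        ]

    def test_single_drifting_cell_single_track(self):
        pos = [[(10.0 + 2.0 * t, 20.0)] for t in range(10)]
        ts = rk.link_tracks(self._detections(pos), max_disp_um=10.0)
        assert len(ts.tracks) == 1
        assert ts.tracks[0].n_frames == 10

    def test_two_distant_cells_no_identity_swap(self):
        pos = [[(10.0 + 2 * t, 10.0), (110.0 - 2 * t, 110.0)] for t in range(20)]
        ts = rk.link_tracks(self._detections(pos), max_disp_um=10.0)
        assert len(ts.tracks) == 2
        for tr in ts.tracks:
            steps = np.linalg.norm(np.diff(tr.xy, axis=0), axis=1)
            assert steps.max() <= 2.0 + 1e-9

    def test_disappearance_ends_track_no_gap_closing(self):
        pos = [[(10.0, 10.0)], [(12.0, 10.0)], [], [(16.0, 10.0)]]
        ts = rk.link_tracks(self._detections(pos), max_disp_um=10.0)
        assert len(ts.tracks) == 2
        assert ts.tracks[0].frames == [0, 1]
        assert ts.tracks[1].frames == [3]

    def test_link_beyond_max_disp_refused(self):
        pos = [[(0.0, 0.0)], [(50.0, 0.0)]]
        ts = rk.link_tracks(self._detections(pos), max_disp_um=30.0)
        assert len(ts.tracks) == 2


class TestMotilityStats:
    def test_straight_track_speed(self):
        ts = TrackSet(tracks=[straight_track(96.0)], dt_min=15.0)
        res = rk.motility_stats(ts)
        assert res.mad_um == pytest.approx(96.0)
        assert res.mean_speed_um_per_h == pytest.approx(8.0)

    def test_stationary_cell(self):
        tr = Track(cell_id=0, frames=list(range(5)), xy=np.tile([3.0, 4.0], (5, 1)))
        res = rk.motility_stats(TrackSet(tracks=[tr], dt_min=15.0))
        assert res.mad_um == 0.0
        assert res.mean_speed_um_per_h == 0.0

    def test_published_column_consistency(self):
        """For every published hydrogel/treatment column, a track whose
        accumulated distance equals the printed MAD over the 12-hour
        acquisition yields the printed speed to 2 decimals."""
        for (gel, cond), (mad, speed) in TABLE4.items():
            ts = TrackSet(tracks=[straight_track(mad)], dt_min=15.0)
            res = rk.motility_stats(ts)
            assert res.mad_um == pytest.approx(mad, abs=1e-9)
            assert res.mean_speed_um_per_h == pytest.approx(speed, abs=0.005), (gel, cond)

    def test_no_qualifying_tracks_raises(self):
        ts = TrackSet(tracks=[straight_track(10.0, n_frames=3)], dt_min=15.0)
        with pytest.raises(ValueError):
            rk.motility_stats(ts, min_track_frames=10)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.normal(0, 2, (20, 2)), axis=0)
        tr = Track(0, list(range(20)), xy)
        tr_shift = Track(0, list(range(20)), xy + [123.0, -45.0])
        assert tr.accumulated_distance() == pytest.approx(tr_shift.accumulated_distance())

    def test_scaling_equivariance(self):
        xy = np.array([[0, 0], [3, 4], [6, 8]], dtype=float)
        tr = Track(0, [0, 1, 2], xy)
        tr2 = Track(0, [0, 1, 2], 2.5 * xy)
        assert tr2.accumulated_distance() == pytest.approx(2.5 * tr.accumulated_distance())


class TestEndToEndTracking:
    def test_mad_recovered_within_two_percent(self):
        p = rk.TrackSimParams(n_cells=4, n_frames=49, step_um=2.0, seed=7)
        frames, truth = rk.generate_timelapse(p)
        tracks, stats = rk.track_timelapse(frames)
        truth_mad = np.mean([t.accumulated_distance() for t in truth.tracks])
        assert stats.n_tracks == 4
        assert stats.mad_um == pytest.approx(truth_mad, rel=0.02)

    def test_track_invariants(self):
        p = rk.TrackSimParams(n_cells=3, n_frames=20, step_um=2.0, seed=9)
        frames, _ = rk.generate_timelapse(p)
        tracks, _ = rk.track_timelapse(frames)
        for tr in tracks.tracks:
            assert all(b > a for a, b in zip(tr.frames, tr.frames[1:]))
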