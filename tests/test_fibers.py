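import numpy as np
import pytest
from scipy.special import iv
from skimage.filters import threshold_otsu

import remodelkit as rk
from remodelkit.core import BinaryMask, ImageStack
from remodelkit.synth import fiber_polylines


def wlc_persistence_truth(kappa_step: float, step_um: float) -> float:
    """Closed-form 2D persistence length of a von Mises turning-angle walk:
    <cos dtheta(n steps)> = (I1/I0)^n, so Lp = -step / (2 ln(I1/I0))."""
    a = iv(1, kappa_step) / iv(0, kappa_step)
    return -step_um / (2.0 * np.log(a))


class TestBinarizeFibers:
    def test_uniform_image_all_background(self):
        img = ImageStack(np.full((1, 64, 64), 50.0))
        assert not rk.binarize_fibers(img, 31, 0).values.any()

    def test_two_level_matches_global_otsu(self, two_level_image):
        mask = rk.binarize_fibers(two_level_image, 31, 0)
        exact = two_level_image.values > threshold_otsu(two_level_image.values)
        np.testing.assert_array_equal(mask.values, exact)

    def test_noise_free_fiber_centerline_covered(self):
        p = rk.FiberFieldParams(
            n_fibers=1, kappa_orient=1e6, kappa_step=1e6, theta0=0.0,
            noise=(0.0, 0.0), seed=0,
        )
        img, truth = rk.generate_fiber_image(p)
        mask = rk.binarize_fibers(img, 31, 0)
        dx, dy, _ = p.spacing
        pts = truth[0]
        inside = (
            (pts[:, 0] > 0) & (pts[:, 0] < 256 * dx)
            & (pts[:, 1] > 0) & (pts[:, 1] < 256 * dy)
        )
        cols = np.round(pts[inside, 0] / dx).astype(int)
        rows = np.round(pts[inside, 1] / dy).astype(int)
        assert mask.values[0, rows, cols].all()

    def test_bad_window_rejected(self):
        img = ImageStack(np.zeros((1, 64, 64)))
        with pytest.raises(ValueError):
            rk.binarize_fibers(img, window_px=10)
        with pytest.raises(ValueError):
            rk.binarize_fibers(img, window_px=101)


class TestTraceFibers:
    def test_straight_rod_length(self):
        m = np.zeros((1, 40, 40), bool)
        m[0, 19:22, 10:31] = True  # 21 px run -> 20 um arc at 1 um/px
        net = rk.trace_fibers(BinaryMask(m), min_fiber_um=2)
        assert net.n_fibers == 1
        assert net.fiber_lengths()[0] == pytest.approx(20.0, abs=np.sqrt(2))

    def test_plus_junction_continues_straight_through(self):
        """Two perpendicular rods crossing at 90 deg give two ~20 um
        fibers, not four 10 um stubs."""
        m = np.zeros((1, 41, 41), bool)
        m[0, 20, 10:31] = True
        m[0, 10:31, 20] = True
        net = rk.trace_fibers(BinaryMask(m), min_fiber_um=2, max_turn_deg=35)
        assert net.n_fibers == 2
        np.testing.assert_allclose(net.fiber_lengths(), [20.0, 20.0], atol=np.sqrt(2))

    def test_shallow_crossing_resolved(self):
        """An X of two rods crossing at 30 deg with max_turn_deg=20 is traced
        as two through-going fibers."""
        m = np.zeros((1, 64, 64), bool)
        for t in np.linspace(-28, 28, 600):
            m[0, 32, int(round(32 + t))] = True
            y = int(round(32 + t * np.tan(np.deg2rad(30))))
            if 0 <= y < 64:
                m[0, y, int(round(32 + t))] = True
        net = rk.trace_fibers(BinaryMask(m), min_fiber_um=2, max_turn_deg=20)
        assert net.n_fibers == 2
        lens = np.sort(net.fiber_lengths())
        assert lens[0] == pytest.approx(56.0, rel=0.1)           # horizontal chord
        assert lens[1] == pytest.approx(56.0 / np.cos(np.deg2rad(30)), rel=0.1)

    def test_empty_mask_gives_empty_network(self):
        net = rk.trace_fibers(BinaryMask(np.zeros((1, 16, 16), bool)))
        assert net.n_fibers == 0

    def test_skeleton_partition(self):
        """Every traced voxel belongs to exactly one fiber (junction
        voxels may be shared between the fibers that pass through them)."""
        img, _ = rk.generate_fiber_image(
            rk.FiberFieldParams(n_fibers=40, noise=(0.0, 0.0), seed=8)
        )
        mask = rk.binarize_fibers(img, 31, 0)
        net = rk.trace_fibers(mask, min_fiber_um=0.0)
        seen = {}
        for fi, vox in enumerate(net.fiber_voxels):
            for v in map(tuple, vox):
                seen.setdefault(v, set()).add(fi)
        multi = [v for v, owners in seen.items() if len(owners) > 1]
        # only junction voxels may be multiply owned; they are rare
        assert len(multi) <= 0.05 * len(seen)


class TestLengthStats:
    def test_three_collinear_nodes(self):
        net = rk.FiberNetwork.from_polylines([np.array([[0, 0], [1, 0], [2, 0]])])
        assert rk.fiber_length_stats(net) == pytest.approx(2.0)

    def test_mean_of_two_fibers(self):
        net = rk.FiberNetwork.from_polylines(
            [np.array([[0, 0], [2, 0]]), np.array([[0, 1], [4, 1]])]
        )
        assert rk.fiber_length_stats(net) == pytest.approx(3.0)

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            rk.fiber_length_stats(rk.FiberNetwork.from_polylines([]))

    def test_generated_straight_fibers_recovered(self):
        """Tracing straight noise-free rasterized fibers recovers the true
        mean length within 5%."""
        p = rk.FiberFieldParams(
            n_fibers=25, length_um=10.0, kappa_step=1e6, kappa_orient=0.0,
            shape=(512, 512), noise=(0.0, 0.0), seed=4,
        )
        img, truth = rk.generate_fiber_image(p)
        mask = rk.binarize_fibers(img, 31, 0)
        net = rk.trace_fibers(mask, min_fiber_um=3.0)
        truth_mean = np.mean(
            [np.linalg.norm(np.diff(t, axis=0), axis=1).sum() for t in truth]
        )
        assert rk.fiber_length_stats(net) == pytest.approx(truth_mean, rel=0.05)


class TestPersistenceLength:
    def test_straight_fibers_return_inf(self):
        polys = fiber_polylines(
            rk.FiberFieldParams(n_fibers=20, kappa_step=1e6, kappa_orient=0, seed=0)
        )
        net = rk.FiberNetwork.from_polylines(polys)
        assert rk.persistence_length(net) == np.inf

    def test_wlc_parameter_recovery(self):
        """500 worm-like chains with known Lp ~ 2.4 um are recovered within
        20% by the tangent-correlation fit."""
        kappa, step = 10.0, 0.25
        lp_true = wlc_persistence_truth(kappa, step)
        polys = fiber_polylines(
            rk.FiberFieldParams(
                n_fibers=500, length_um=15.0, step_um=step, kappa_step=kappa,
                kappa_orient=0.0, seed=3,
            )
        )
        lp = rk.persistence_length(rk.FiberNetwork.from_polylines(polys))
        assert lp == pytest.approx(lp_true, rel=0.20)

    def test_monotone_in_step_concentration(self):
        lps = []
        for kappa in (5.0, 20.0):
            polys = fiber_polylines(
                rk.FiberFieldParams(
                    n_fibers=300, step_um=0.25, kappa_step=kappa, kappa_orient=0, seed=1
                )
            )
            lps.append(rk.persistence_length(rk.FiberNetwork.from_polylines(polys)))
        assert lps[1] > lps[0]

    def test_too_few_fibers_raises(self):
        net = rk.FiberNetwork.from_polylines([np.array([[0, 0], [1, 0], [2, 0]])])
        with pytest.raises(ValueError):
            rk.persistence_length(net)


class TestPoreSize:
    def test_parallel_slabs_closed_form(self):
        """Planes spaced S=12 px with thickness t=2 leave gaps of S-t=10."""
        m = np.zeros((1, 96, 96), bool)
        for y0 in range(0, 96, 12):
            m[0, y0 : y0 + 2, :] = True
        assert rk.pore_size(BinaryMask(m)) == pytest.approx(10.0, abs=1.0)

    def test_square_cavity(self):
        m = np.ones((1, 60, 60), bool)
        m[0, 20:40, 20:40] = False
        assert rk.pore_size(BinaryMask(m)) == pytest.approx(20.0, abs=1.0)

    def test_monotone_decreasing_in_fiber_density(self):
        pores = []
        for n in (60, 240):
            img, _ = rk.generate_fiber_image(
                rk.FiberFieldParams(n_fibers=n, noise=(0.0, 0.0), seed=5)
            )
            mask = rk.binarize_fibers(img, 31, 0)
            pores.append(rk.pore_size(mask))
        assert pores[1] < pores[0]

    def test_degenerate_masks_raise(self):
        with pytest.raises(ValueError):
            rk.pore_size(BinaryMask(np.zeros((1, 8, 8), bool)))
        with pytest.raises(ValueError):
            rk.pore_size(BinaryMask(np.ones((1, 8, 8), bool)))


class TestRotationInvariance:
    @pytest.mark.parametrize("seed", [12, 30])
    def test_metrics_stable_under_90_degree_rotation(self, seed):
        """Pore size is distance-transform based and rotation-exact; mean
        fiber length inherits the (slight) raster anisotropy of the
        thinning step, so it is held to 10% at moderate mesh density."""
        img, _ = rk.generate_fiber_image(
            rk.FiberFieldParams(n_fibers=40, noise=(0.0, 0.0), seed=seed)
        )
        rot = ImageStack(np.rot90(img.values[0]).copy(), img.spacing)
        results = []
        for im in (img, rot):
            mask = rk.binarize_fibers(im, 31, 0)
            net = rk.trace_fibers(mask, min_fiber_um=2.0)
            results.append((rk.fiber_length_stats(net), rk.pore_size(mask)))
        (l1, p1), (l2, p2) = results
        assert l2 == pytest.approx(l1, rel=0.10)
        assert p2 == pytest.approx(p1, rel=0.05)
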