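import numpy as np
import pandas as pd
import pytest

import remodelkit as rk
from remodelkit.core import BinaryMask, ImageStack

HALF_MAX_THRESHOLD = 0.5 ** (1 / 2.1)  # post-gamma value of the blob half maximum


def fa3d_scene(n_fa, seed):
    params = rk.FaSceneParams(
        n_fa=n_fa,
        shape=(32, 160, 160),
        cell_axes_px=(70.0, 55.0, 13.0),
        spacing=(0.312, 0.312, 0.49),
        nucleus_radius_um=4.0,
        min_sep_px=13.0,
        avoid_perinuclear=True,
        seed=seed,
    )
    return rk.generate_fa_scene(params, dims=3)


class TestDetectFa2d:
    def test_noise_only_image_yields_zero(self, disc_mask):
        rng = np.random.default_rng(0)
        img = ImageStack(
            np.clip(rng.normal(10, 2, (1, 128, 128)), 0, None), (0.099, 0.099, 0.42)
        )
        fas = rk.detect_fa_2d(img, disc_mask(shape=(128, 128), center=(64, 64), radius=50))
        assert fas.count == 0

    def test_count_and_area_recovery(self):
        img, truth, cell, _ = rk.generate_fa_scene(rk.FaSceneParams(n_fa=12, seed=2), dims=2)
        fas = rk.detect_fa_2d(img, cell)
        summary = rk.fa_summary(fas)
        assert summary["count"] == 12
        assert summary["mean_size"] == pytest.approx(truth["size"].mean(), rel=0.30)

    def test_small_punctae_rejected_by_size_filter(self):
        """Adding sub-threshold punctae (< 20 px^2 footprint, well below the
        50 px^2 particle filter) does not change the count."""
        base = rk.FaSceneParams(n_fa=12, seed=2)
        img, truth, cell, _ = rk.generate_fa_scene(base, dims=2)
        small = rk.FaSceneParams(
            n_fa=8, fa_size_range=(8.0, 16.0), noise_sigma=0.0, seed=77
        )
        img_small, _, _, _ = rk.generate_fa_scene(small, dims=2)
        # keep only the small punctae (strip their scene's background/cell)
        combined = ImageStack(
            img.values + np.clip(img_small.values - 30.0, 0, None), img.spacing
        )
        fas = rk.detect_fa_2d(combined, cell)
        assert fas.count == 12

    def test_min_size_sweep_is_monotone(self):
        img, _, cell, _ = rk.generate_fa_scene(rk.FaSceneParams(n_fa=15, seed=4), dims=2)
        counts = [
            rk.detect_fa_2d(img, cell, rk.Fa2dParams(min_size=s)).count
            for s in (0, 50, 150, 400, 2000)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_empty_cell_mask_raises(self):
        img = ImageStack(np.zeros((1, 64, 64)))
        with pytest.raises(ValueError):
            rk.detect_fa_2d(img, BinaryMask(np.zeros((1, 64, 64), bool)))

    def test_default_scene_regression(self):
        """Pins the full default pipeline on a fixed scene: a silent change
        in processing order or parameters shows up as a count change."""
        img, _, cell, _ = rk.generate_fa_scene(rk.FaSceneParams(n_fa=12, seed=42), dims=2)
        fas = rk.detect_fa_2d(img, cell)
        assert fas.count == 12


class TestDetectFa3d:
    def test_blank_stack_yields_zero(self):
        rng = np.random.default_rng(1)
        stack = ImageStack(
            np.clip(rng.normal(10, 2, (16, 64, 64)), 0, None), (0.312, 0.312, 0.49)
        )
        fas = rk.detect_fa_3d(stack, None, rk.Fa3dParams(threshold=0.9))
        assert fas.count == 0

    def test_count_and_volume_recovery(self):
        img, truth, _, nucleus = fa3d_scene(15, seed=15)
        fas = rk.detect_fa_3d(img, nucleus, rk.Fa3dParams(threshold=HALF_MAX_THRESHOLD))
        assert fas.count == 15
        voxvol = np.prod(img.spacing)
        assert fas.table["volume_um3"].sum() == pytest.approx(
            truth["size"].sum() * voxvol, rel=0.20
        )

    def test_perinuclear_band_exclusion(self):
        """A punctum inside the 5 um perinuclear band is never reported; a
        punctum farther away always is (noise-free scene)."""
        spacing = (0.312, 0.312, 0.49)
        shape = (32, 160, 160)
        zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
        nucleus = BinaryMask(
            ((xx - 80) * 0.312) ** 2 + ((yy - 80) * 0.312) ** 2 + ((zz - 16) * 0.49) ** 2
            <= 4.0**2,
            spacing,
        )
        img = np.full(shape, 10.0)

        def add_blob(cx_um, sigma_um=0.6, peak=200.0):
            img_local = peak * np.exp(
                -(
                    ((xx - cx_um / 0.312) * 0.312) ** 2
                    + ((yy - 80) * 0.312) ** 2
                    + ((zz - 16) * 0.49) ** 2
                )
                / (2 * sigma_um**2)
            )
            return img_local

        center_um = 80 * 0.312  # 24.96
        img = img + add_blob(center_um + 6.0)   # 6 um from nucleus centre: inside band
        img = img + add_blob(center_um + 15.0)  # 15 um: outside band
        stack = ImageStack(img, spacing)
        fas = rk.detect_fa_3d(stack, nucleus, rk.Fa3dParams(threshold=HALF_MAX_THRESHOLD))
        assert fas.count == 1
        assert fas.table["x_um"].iloc[0] == pytest.approx(center_um + 15.0, abs=0.5)

    def test_dumbbell_watershed_split_and_merge(self):
        """Two unequal fused lobes (EDT dynamic of the smaller ~1.8) are
        split at a small watershed dynamic and merged when the dynamic
        exceeds the neck depth."""
        zz, yy, xx = np.mgrid[0:24, 0:24, 0:40]
        s1 = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 13) ** 2 <= 36
        s2 = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 27) ** 2 <= 16
        neck = ((zz - 12) ** 2 + (yy - 12) ** 2 <= 4) & (xx >= 13) & (xx <= 27)
        stack = ImageStack(np.where(s1 | s2 | neck, 200.0, 0.0), (1, 1, 1))
        split = rk.detect_fa_3d(stack, None, rk.Fa3dParams(threshold=0.5, watershed_dynamic=1.0))
        merged = rk.detect_fa_3d(stack, None, rk.Fa3dParams(threshold=0.5, watershed_dynamic=3.0))
        assert split.count == 2
        assert merged.count == 1

    def test_threshold_out_of_range_rejected(self):
        stack = ImageStack(np.zeros((4, 16, 16)))
        with pytest.raises(ValueError):
            rk.detect_fa_3d(stack, None, rk.Fa3dParams(threshold=2.0))


class TestFaSummary:
    def test_two_sizes(self):
        table = pd.DataFrame(dict(area_px2=[100.0, 200.0]))
        fset = rk.FocalAdhesionSet(table=table, dims=2, spacing=(1, 1, 1))
        s = rk.fa_summary(fset)
        assert s["count"] == 2
        assert s["mean_size"] == 150.0

    def test_empty_reports_missing_mean(self):
        fset = rk.FocalAdhesionSet(
            table=pd.DataFrame(columns=["area_px2"]), dims=2, spacing=(1, 1, 1)
        )
        s = rk.fa_summary(fset)
        assert s["count"] == 0
        assert np.isnan(s["mean_size"])

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(0)
        sizes = rng.uniform(50, 500, 1000)
        fset = rk.FocalAdhesionSet(
            table=pd.DataFrame(dict(area_px2=sizes)), dims=2, spacing=(1, 1, 1)
        )
        assert rk.fa_summary(fset)["mean_size"] == pytest.approx(sizes.sum() / 1000)
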