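"""3D focal-adhesion quantification with perinuclear exclusion.

Renders an embedded cell whose vinculin punctae sit at protrusions
(outside the 5-um perinuclear band), runs the 3D chain (3D median,
per-slice rolling ball, gamma 2.1, fixed threshold, EDM watershed) and
reports per-adhesion volumes.  The fixed threshold is set at the blob
half maximum on the post-gamma scale, as a user would set it for
hyperintense adhesions.
"""

import numpy as np

import remodelkit as rk

scene = rk.FaSceneParams(
    n_fa=15, shape=(32, 160, 160), cell_axes_px=(70.0, 55.0, 13.0),
    spacing=(0.312, 0.312, 0.49), nucleus_radius_um=4.0, min_sep_px=13.0,
    avoid_perinuclear=True, seed=15,
)
stack, truth, _, nucleus_mask = rk.generate_fa_scene(scene, dims=3)

params = rk.Fa3dParams(threshold=0.5 ** (1 / 2.1))
fas = rk.detect_fa_3d(stack, nucleus_mask, params)
summary = rk.fa_summary(fas)

voxvol = float(np.prod(stack.spacing))
print(f"adhesions detected   : {summary['count']} (generated: {len(truth)})")
print(f"total volume         : {fas.table['volume_um3'].sum():.1f} um^3 "
      f"(truth {truth['size'].sum() * voxvol:.1f})")
print(f"mean volume          : {summary['mean_size']:.2f} um^3 per adhesion")
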