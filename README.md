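# remodelkit

Quantification pipelines for ECM remodeling and cell–matrix interaction
in collagen and collagen–Matrigel hydrogels, from fluorescence
microscopy.

Cancer cells remodel the fibrous matrix around them — they align,
compact, and proteolytically degrade collagen, grip it through focal
adhesions, and migrate through the pores they find or make.  Each of
these behaviours has a standard image-based readout, and `remodelkit`
implements the full set as one tested Python library:

| Readout | Module | Quantity |
|---|---|---|
| Fiber-network morphometry | `fibers` | mean fiber length, persistence length Lp, pore size (μm) |
| Fiber alignment | `remodeling` | FFT orientation-tensor anisotropy index α ∈ [0, 1] |
| Matrix compaction | `remodeling` | fiber-pixel density in control windows and 7-μm peri-cellular "doughnut" bands |
| Matrix degradation | `degradation` | DQ-collagen volume per cell (μm³), via Tsai moment-preserving thresholding |
| Focal adhesions, 2D & 3D | `adhesions` | count, area (px²/μm²) or volume (μm³) per cell |
| Cell motility | `motility` | mean accumulated distance MAD (μm) and speed (μm/h) from time-lapse tracking |

A ground-truthed synthetic-scene generator (`synth`) emulates each input
— fiber meshes with tunable von Mises alignment and persistence,
vinculin punctae, degradation blobs, moving cells — so every pipeline is
validated end to end against known geometry.

The core estimators, briefly: the anisotropy index is the eigenvalue
contrast α = (λ₁ − λ₂)/(λ₁ + λ₂) of the spectral second-moment
orientation tensor of a Hann-windowed patch (α = 0 isotropic, 1
aligned); persistence length is fit from pooled tangent correlations
⟨cos Δθ(s)⟩ = e^(−s/2Lp); pore size is 2× the median inscribed-sphere
radius of the background distance map; Tsai's threshold preserves the
first three grey-level moments of the image in its binary counterpart;
tracking is constrained mutual-nearest-neighbour linking with
AD = Σ‖Δp‖ per track.  `docs/methods.md` has the full account.

## Worked example

Track four simulated cells through a 12-hour, 15-minute-interval
time-lapse (the acquisition geometry of hydrogel migration assays):

```python
import numpy as np
import remodelkit as rk

params = rk.TrackSimParams(n_cells=4, n_frames=49, dt_min=15.0, step_um=2.0, seed=7)
frames, truth = rk.generate_timelapse(params)
tracks, stats = rk.track_timelapse(frames)

truth_mad = np.mean([t.accumulated_distance() for t in truth.tracks])
print(f"tracks recovered     : {stats.n_tracks} of {len(truth.tracks)} cells")
print(f"MAD                  : {stats.mad_um:.2f} um (truth {truth_mad:.2f} um)")
print(f"mean speed           : {stats.mean_speed_um_per_h:.2f} um/h")
```

prints

```
tracks recovered     : 4 of 4 cells
MAD                  : 95.90 um (truth 96.00 um)
mean speed           : 7.99 um/h
```

Each cell takes 48 steps of 2 μm, so the true accumulated distance is
96 μm; the tracker recovers it to 0.1% (the residual is centroid
quantization), and speed is MAD divided by the 12-hour span.  The
`examples/` directory has one such narrative script per capability
(morphometry, anisotropy and densification, degradation, 2D/3D
adhesions, tracking).

A thin CLI mirrors the library for shell use:

```sh
remodelkit simulate fibers --out mesh.tif --seed 1
remodelkit fibers --in mesh.tif --spacing 0.099,0.099,0.42 --out metrics.csv
remodelkit track --in timelapse.tif --dt 15 --spacing 1.25,1.25 --out tracks.csv
```

Subcommands: `fibers | anisotropy | density | degradation | fa2d | fa3d
| track | simulate`, with `--config` (YAML parameter blocks) and
`--spacing` overrides.

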