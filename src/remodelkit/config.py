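"""Per-pipeline analysis configuration.

One flat parameter block per pipeline, each pre-populated with the
defaults the analyses were designed around (the 2D focal-adhesion block
reproduces the published parameter table verbatim).  Unknown keys are
rejected so that typos in a config file fail loudly.
"""

from __future__ import annotations

from copy import deepcopy
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["DEFAULTS", "AnalysisConfig"]

DEFAULTS: dict[str, dict[str, Any]] = {
    "fiber": {
        "window_px": 65,            # local-Otsu window (~6.4 um at 0.099 um/px)
        "prefilter_sigma": 1.0,     # Gaussian prefilter, voxels
        "min_fiber_um": 2.0,
        "max_turn_deg": 35.0,
        "length_unit": "a.u.",      # fiber length / persistence unit label
    },
    "remodeling": {
        "roi_side_px": 100,
        "band_thickness_um": 7.0,
        "f_lo": None,               # None -> 4 / patch side (cycles/px)
        "f_hi": 0.45,
        "projection": "slice",      # "slice" or "mip" for 3D stacks
    },
    "degradation": {
        "closing_r_px": 2,
        "median_r_px": 1,
        "per_slice": False,
    },
    "fa2d": {
        "median_radius": 2,
        "background_radius": 50,
        "clahe_block": 19,
        "clahe_bins": 256,
        "clahe_slope": 6,
        "contrast_saturation": 0.35,
        "log_sigma": (5.0, 5.0),
        "min_size": 50,
        "circularity": (0.0, 1.0),
    },
    "fa3d": {
        "median_radius_vox": 1,
        "rollball_radius_px": 10,
        "gamma": 2.1,
        "threshold": None,          # None -> threshold_percentile of post-gamma stack
        "threshold_percentile": 99.0,
        "watershed_dynamic": 0.5,   # h-minima depth, um
        "perinuclear_band_um": 5.0,
    },
    "motility": {
        "clahe_block": 64,
        "clahe_bins": 256,
        "clahe_slope": 3,
        "min_area_px": 20,
        "max_disp_um": 30.0,
        "dt_min": 15.0,
        "min_track_fraction": 0.75,
    },
}


class AnalysisConfig:
    """Named parameter blocks, defaulting to the pipelines' design values.

    Construct empty (all defaults), from a mapping, or from a YAML file
    whose top-level keys are pipeline names.  Unknown pipeline names or
    parameter keys raise ``KeyError``.
    """

    def __init__(self, overrides: Mapping[str, Mapping[str, Any]] | None = None):
        self._blocks = deepcopy(DEFAULTS)
        if overrides:
            self.update(overrides)

    def update(self, overrides: Mapping[str, Mapping[str, Any]]) -> None:
        for block, params in overrides.items():
            if block not in self._blocks:
                raise KeyError(f"unknown pipeline block {block!r}")
            for key, value in params.items():
                if key not in self._blocks[block]:
                    raise KeyError(f"unknown parameter {block}.{key}")
                self._blocks[block][key] = value

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)

    def __getitem__(self, block: str) -> dict[str, Any]:
        return self._blocks[block]

    def as_dict(self) -> dict[str, dict[str, Any]]:
        return deepcopy(self._blocks)
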