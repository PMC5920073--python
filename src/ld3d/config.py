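"""Run configuration: defaults, deep merge, JSON round trip.

Every pipeline run resolves its configuration against these defaults and
writes the resolved copy beside its outputs, so a run is reproducible from
its artifacts alone.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

__all__ = ["default_config", "merge_config", "load_config", "save_config"]

_DEFAULTS = {
    "calibration": {"dx_um": 0.159, "dy_um": 0.159, "dz_um": 0.38},
    "seed": 0,
    "preprocess": {
        # Gaussian is the default: a symmetric blur preserves the half-level
        # contour of blob boundaries, so thresholded volumes stay unbiased,
        # whereas a median window systematically erodes convex blobs.
        "method": "gaussian",       # gaussian | median | None
        "radius_vox": [0.5, 0.5, 0.5],  # sigma (gaussian) / half-window (median), per (z, y, x)
        "sigma_um": None,           # illumination-flattening scale; None = off
    },
    "segment": {
        "threshold": {"method": "otsu", "value": None},
        "connectivity": 26,
        "min_volume_um3": 0.05,
        "split": {"enabled": True, "min_sep_um": 3.0},
    },
    "cells": {
        "source": "brightfield",  # brightfield | label_file
        "wall_cutoff": None,      # None = Otsu on the smoothed boundary channel
        "seed_sigma_um": 2.0,
        "min_seed_sep_um": 12.0,
    },
    "metrics": {
        "large_diam_um": 5.0,
        "small_class_um3": 100.0,
        "max_gap_um": 15.0,
    },
    "report": {"test": "welch"},
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def merge_config(base: dict, override: dict) -> dict:
    """Recursively merge ``override`` into a deep copy of ``base``."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict:
    """Defaults merged with a JSON config file, when one is given."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            cfg = merge_config(cfg, json.load(fh))
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
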