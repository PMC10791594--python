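"""YAML run configuration with strict key validation.

A run configuration nests geometry, phantom, fitting, similarity, surrogate
and reconstruction settings.  Unknown keys are rejected so typos fail loudly,
and the defaults reproduce the published protocol (control grid spacing of
8 voxels, resolution levels 1/4 and 1/2, at most 6 motion-compensated
reconstructions per level, at most 100 fit iterations, one-tenth subsets).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .lncc import LnccConfig
from .model import FitConfig

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "geometry": {
        "sid": 1000.0,
        "sdd": 1536.0,
        "n_detector": 128,
        "n_frames": 310,
        "frame_rate_hz": 5.4,
        "arc_deg": 360.0,
    },
    "phantom": {
        "shape": [128, 128, 128],
        "spacing": 2.0,
        "tumor_radius": 15.0,
        "regime": "regular",
        "poisson_flux": None,
    },
    "fit": {
        "levels": [0.25, 0.5],
        "max_mcr_per_level": 6,
        "max_fit_iters": 100,
        "subset_fraction": 0.1,
        "grid_spacing_voxels": 8,
        "initial_update_mm": 5.0,
        "epoch_tol": 1.0e-5,
        "outer_tol": 1.0e-5,
    },
    "lncc": {
        "sigma_px": 5.0,
        "variance_floor_rel": 1.0e-6,
    },
    "surrogate": {
        "band_split_hz": 0.1,
    },
    "reconstruction": {
        "shape": None,  # None -> match the phantom / projection resolution
        "spacing": None,
        "filter_window": "hann",
    },
}


def _merge_strict(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_strict(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults merged with an optional YAML file and an overrides dict."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("configuration file must hold a mapping")
        cfg = _merge_strict(cfg, user)
    if overrides:
        cfg = _merge_strict(cfg, overrides)
    return cfg


def save_config(cfg: dict, path) -> None:
    """Write the fully resolved configuration (for run provenance)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def fit_config_from(cfg: dict) -> FitConfig:
    f = cfg["fit"]
    return FitConfig(
        levels=tuple(f["levels"]),
        max_mcr_per_level=int(f["max_mcr_per_level"]),
        max_fit_iters=int(f["max_fit_iters"]),
        subset_fraction=float(f["subset_fraction"]),
        grid_spacing_voxels=int(f["grid_spacing_voxels"]),
        lncc=LnccConfig(
            sigma_px=float(cfg["lncc"]["sigma_px"]),
            variance_floor_rel=float(cfg["lncc"]["variance_floor_rel"]),
        ),
        initial_update_mm=float(f["initial_update_mm"]),
        epoch_tol=float(f["epoch_tol"]),
        outer_tol=float(f["outer_tol"]),
        seed=int(cfg["seed"]),
    )
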