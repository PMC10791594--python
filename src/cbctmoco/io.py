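"""Readers and writers for volumes, projection stacks, fields, signals, models.

Volumes and displacement fields go through SimpleITK (MetaImage ``.mha`` or
NIfTI ``.nii``/``.nii.gz``); projection stacks are stored as a 3-D MetaImage
or a multi-page TIFF with a sidecar geometry JSON; surrogate signals as CSV;
correspondence models as an ``.npz`` container; evaluation reports as JSON.
All numeric payloads round-trip losslessly and grid metadata (spacing,
origin, timestamps) is preserved.

The in-memory axis convention is ``(x, y, z)`` with world position
``origin + index * spacing``; SimpleITK's array view is ``(z, y, x)``, so
arrays are transposed at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .bspline import ControlPointGrid
from .geometry import ProjectionStack, ScanGeometry, Volume3D
from .model import CorrespondenceModel
from .surrogate import SurrogateMatrix, Trace


# ---------------------------------------------------------------------------
# Volumes and vector fields
# ---------------------------------------------------------------------------


def write_volume(vol: Volume3D, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> Volume3D:
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).T
    return Volume3D(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


def write_dvf(dvf: np.ndarray, grid: Volume3D, path) -> None:
    """Write a (nx, ny, nz, 3) displacement field (mm) as a vector image."""
    if dvf.shape != grid.shape + (3,):
        raise ValueError("DVF shape does not match the grid")
    arr = np.ascontiguousarray(np.transpose(dvf, (2, 1, 0, 3)))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path))


def read_dvf(path) -> tuple[np.ndarray, Volume3D]:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    dvf = np.transpose(arr, (2, 1, 0, 3))
    grid = Volume3D(
        np.zeros(dvf.shape[:3]), np.array(img.GetSpacing()), np.array(img.GetOrigin())
    )
    return dvf, grid


# ---------------------------------------------------------------------------
# Geometry and projections
# ---------------------------------------------------------------------------


def write_geometry(geom: ScanGeometry, path) -> None:
    with open(path, "w") as fh:
        json.dump(geom.to_dict(), fh, indent=2)


def read_geometry(path) -> ScanGeometry:
    with open(path) as fh:
        return ScanGeometry.from_dict(json.load(fh))


def write_projections(projs: ProjectionStack, path, geometry_path=None) -> None:
    """Store a stack as .mha (frames along the third axis) or multipage .tif."""
    path = Path(path)
    if geometry_path is None:
        geometry_path = path.with_suffix(".geometry.json")
    write_geometry(projs.geometry, geometry_path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), projs.data.astype(np.float32))
    else:
        img = sitk.GetImageFromArray(projs.data.astype(np.float32))
        sitk.WriteImage(img, str(path))


def read_projections(path, geometry_path=None) -> ProjectionStack:
    path = Path(path)
    if geometry_path is None:
        geometry_path = path.with_suffix(".geometry.json")
    geom = read_geometry(geometry_path)
    if path.suffix in (".tif", ".tiff"):
        data = tifffile.imread(str(path))
    else:
        data = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    return ProjectionStack(np.asarray(data, dtype=np.float64), geom)


def log_convert(raw: np.ndarray, flat: np.ndarray | float | None = None) -> np.ndarray:
    """Convert raw intensity projections to line integrals: -log(I / I_flat).

    Without a flat field the per-stack maximum serves as the unattenuated
    intensity (adequate when unblocked rays reach the detector).
    """
    raw = np.asarray(raw, dtype=np.float64)
    if np.any(raw <= 0):
        raise ValueError("raw intensities must be positive for log conversion")
    if flat is None:
        flat = float(raw.max())
    return -np.log(raw / flat)


# ---------------------------------------------------------------------------
# Signals
# ---------------------------------------------------------------------------


def write_signals(surrogates: SurrogateMatrix, times: np.ndarray, path) -> None:
    cols = {"time_s": np.asarray(times, dtype=float)}
    for i in range(surrogates.n_signals):
        cols[f"s{i + 1}"] = surrogates.values[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_signals(path) -> tuple[SurrogateMatrix, np.ndarray]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("signals CSV must have a time_s column")
    names = [c for c in df.columns if c != "time_s"]
    values = df[names].to_numpy(dtype=float)
    return SurrogateMatrix(values, names), df["time_s"].to_numpy(dtype=float)


def traces_from_csv(path) -> list[Trace]:
    surrogates, times = read_signals(path)
    return [
        Trace(surrogates.values[:, i], times, surrogates.names[i])
        for i in range(surrogates.n_signals)
    ]


# ---------------------------------------------------------------------------
# Correspondence models
# ---------------------------------------------------------------------------


def write_model(model: CorrespondenceModel, path) -> None:
    np.savez_compressed(
        path,
        components=model.components,
        node_spacing=model.lattice.node_spacing,
        node_origin=model.lattice.node_origin,
        level=np.array([model.level]),
    )


def read_model(path) -> CorrespondenceModel:
    with np.load(path) as z:
        comps = z["components"]
        lattice = ControlPointGrid(
            np.zeros(comps.shape[1:]), z["node_spacing"], z["node_origin"]
        )
        return CorrespondenceModel(comps, lattice, float(z["level"][0]))
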