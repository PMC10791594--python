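"""Circular-trajectory cone-beam geometry and a matched projector pair.

The forward projector computes line integrals of a volume along the rays from
the x-ray source to each detector pixel (ray-driven, trilinear sampling at a
fixed step of half the smallest voxel spacing).  The backprojector is the
*exact* adjoint of the forward projector: it scatters each detector value back
along the same ray samples through the transposed trilinear weights.  An exact
adjoint pair is required so that the analytic gradient of the projection-domain
fitting loss is consistent with the forward model.

Conventions
-----------
* World frame: isocenter at the origin; the gantry rotates in the axial
  (x, y) plane; z is the rotation (superior-inferior) axis.
* At gantry angle ``theta`` (degrees) the source sits at
  ``sid * (cos t, sin t, 0)`` and the flat panel is centered on the
  source-isocenter line at distance ``sdd`` from the source, with in-plane
  axis ``e_u = (-sin t, cos t, 0)`` and axial axis ``e_v = (0, 0, 1)``.
* Volumes are scalar arrays indexed ``(ix, iy, iz)``; the world position of a
  voxel center is ``origin + index * spacing`` (mm).
* Voxels outside the reconstruction field of view (the inscribed axial
  cylinder) carry NaN as the null marker; projectors treat null as a zero
  contribution and the validity mask flags detector pixels whose rays cross
  the null region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

NULL_VALUE = np.nan


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ScanGeometry:
    """Circular cone-beam scan geometry (flat panel, no detector offset).

    Parameters
    ----------
    sid, sdd:
        Source-to-isocenter and source-to-detector distances in mm
        (``sdd > sid > 0``).
    detector_rows, detector_cols:
        Panel size in pixels; rows run along ``e_v`` (axial), columns along
        ``e_u`` (in-plane).
    detector_spacing:
        Pixel pitch in mm as ``(row_spacing, col_spacing)``.
    angles, times:
        Per-projection gantry angle (degrees) and timestamp (seconds);
        both of length ``N_t``.
    """

    sid: float
    sdd: float
    detector_rows: int
    detector_cols: int
    detector_spacing: tuple[float, float]
    angles: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if not (self.sdd > self.sid > 0):
            raise ValueError(f"require sdd > sid > 0, got sid={self.sid}, sdd={self.sdd}")
        if self.angles.ndim != 1 or self.angles.shape != self.times.shape:
            raise ValueError("angles and times must be 1-D arrays of equal length")
        if self.detector_rows <= 0 or self.detector_cols <= 0:
            raise ValueError("detector shape must be positive")
        ds = tuple(float(s) for s in self.detector_spacing)
        if len(ds) != 2 or min(ds) <= 0:
            raise ValueError("detector_spacing must be two positive floats")
        self.detector_spacing = ds

    @property
    def n_frames(self) -> int:
        return int(self.angles.size)

    def frame_vectors(self, frame_index: int):
        """Source position, detector center and panel axes for one frame."""
        if not 0 <= frame_index < self.n_frames:
            raise IndexError(f"frame_index {frame_index} out of range [0, {self.n_frames})")
        t = math.radians(float(self.angles[frame_index]))
        e_s = np.array([math.cos(t), math.sin(t), 0.0])
        source = self.sid * e_s
        det_center = (self.sid - self.sdd) * e_s
        e_u = np.array([-math.sin(t), math.cos(t), 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        return source, det_center, e_u, e_v

    def rescale_detector(self, factor: int) -> "ScanGeometry":
        """Geometry with the panel binned by an integer factor (same physical size)."""
        if self.detector_rows % factor or self.detector_cols % factor:
            raise ValueError("detector shape not divisible by binning factor")
        return replace(
            self,
            detector_rows=self.detector_rows // factor,
            detector_cols=self.detector_cols // factor,
            detector_spacing=(
                self.detector_spacing[0] * factor,
                self.detector_spacing[1] * factor,
            ),
        )

    def to_dict(self) -> dict:
        return {
            "sid": self.sid,
            "sdd": self.sdd,
            "detector_rows": self.detector_rows,
            "detector_cols": self.detector_cols,
            "detector_spacing": list(self.detector_spacing),
            "angles_deg": self.angles.tolist(),
            "times_s": self.times.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            sid=float(d["sid"]),
            sdd=float(d["sdd"]),
            detector_rows=int(d["detector_rows"]),
            detector_cols=int(d["detector_cols"]),
            detector_spacing=tuple(d["detector_spacing"]),
            angles=np.asarray(d["angles_deg"], dtype=np.float64),
            times=np.asarray(d["times_s"], dtype=np.float64),
        )


@dataclass
class Volume3D:
    """Scalar image on a regular grid; ``data`` indexed ``(ix, iy, iz)``.

    NaN is the reserved null value marking voxels outside the reconstruction
    field of view.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive floats")
        if self.origin.shape != (3,):
            raise ValueError("origin must be three floats")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing.copy(), self.origin.copy())

    def like(self, data: np.ndarray) -> "Volume3D":
        if data.shape[:3] != self.data.shape:
            raise ValueError("data shape mismatch")
        return Volume3D(data, self.spacing.copy(), self.origin.copy())

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def filled(self, value: float = 0.0) -> np.ndarray:
        """Data with null voxels replaced by ``value`` (float64)."""
        return np.nan_to_num(self.data.astype(np.float64), nan=value)

    def null_mask(self) -> np.ndarray:
        return np.isnan(self.data)

    def world_coordinates(self):
        """Per-axis 1-D world coordinates of voxel centers (mm)."""
        return [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        ]

    def fov_radius(self) -> float:
        """Radius (mm) of the axial cylinder inscribed in the x-y extent."""
        return 0.5 * min(self.shape[0] * self.spacing[0], self.shape[1] * self.spacing[1])

    def fov_mask(self, radius: float | None = None) -> np.ndarray:
        """Boolean mask of voxels inside the reconstruction FOV cylinder."""
        r = self.fov_radius() if radius is None else radius
        cx, cy, _ = self.world_coordinates()
        return (cx[:, None] ** 2 + cy[None, :] ** 2 <= r * r)[:, :, None] * np.ones(
            self.shape[2], dtype=bool
        )

    @classmethod
    def centered(cls, shape, spacing, dtype=np.float64) -> "Volume3D":
        """Zero volume whose grid is centered on the world origin."""
        shape = tuple(int(s) for s in shape)
        spacing = np.asarray(spacing, dtype=np.float64)
        if spacing.shape == ():
            spacing = np.full(3, float(spacing))
        origin = -0.5 * (np.asarray(shape) - 1) * spacing
        return cls(np.zeros(shape, dtype=dtype), spacing, origin)


@dataclass
class ProjectionStack:
    """Ordered stack of 2-D line-integral images with their scan geometry."""

    data: np.ndarray  # (N_t, rows, cols)
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("projection data must be (N_t, rows, cols)")
        nt, rows, cols = self.data.shape
        g = self.geometry
        if nt != g.n_frames or rows != g.detector_rows or cols != g.detector_cols:
            raise ValueError(
                f"projection shape {self.data.shape} does not match geometry "
                f"({g.n_frames}, {g.detector_rows}, {g.detector_cols})"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


# ---------------------------------------------------------------------------
# Ray-driven projector kernels (numba)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _ray_bounds(px, py, pz, dx, dy, dz, nx, ny, nz):
    """Intersection of the ray p + t*d (index coordinates) with the padded
    volume box [-1, n] per axis.  Returns (tmin, tmax)."""
    tmin = -1.0e30
    tmax = 1.0e30
    for a in range(3):
        if a == 0:
            p, d, n = px, dx, nx
        elif a == 1:
            p, d, n = py, dy, ny
        else:
            p, d, n = pz, dz, nz
        lo = -1.0
        hi = float(n)
        if abs(d) < 1e-12:
            if p < lo or p > hi:
                return 1.0, 0.0
        else:
            t0 = (lo - p) / d
            t1 = (hi - p) / d
            if t0 > t1:
                t0, t1 = t1, t0
            if t0 > tmin:
                tmin = t0
            if t1 < tmax:
                tmax = t1
    return tmin, tmax


@njit(cache=True, fastmath=False)
def _trilinear_gather(vol, x, y, z):
    nx, ny, nz = vol.shape
    ix = int(math.floor(x))
    iy = int(math.floor(y))
    iz = int(math.floor(z))
    fx = x - ix
    fy = y - iy
    fz = z - iz
    acc = 0.0
    for a in range(2):
        wx = fx if a == 1 else 1.0 - fx
        jx = ix + a
        if jx < 0 or jx >= nx or wx == 0.0:
            continue
        for b in range(2):
            wy = fy if b == 1 else 1.0 - fy
            jy = iy + b
            if jy < 0 or jy >= ny or wy == 0.0:
                continue
            for c in range(2):
                wz = fz if c == 1 else 1.0 - fz
                jz = iz + c
                if jz < 0 or jz >= nz or wz == 0.0:
                    continue
                acc += wx * wy * wz * vol[jx, jy, jz]
    return acc


@njit(cache=True, fastmath=False)
def _trilinear_scatter(vol, x, y, z, value):
    nx, ny, nz = vol.shape
    ix = int(math.floor(x))
    iy = int(math.floor(y))
    iz = int(math.floor(z))
    fx = x - ix
    fy = y - iy
    fz = z - iz
    for a in range(2):
        wx = fx if a == 1 else 1.0 - fx
        jx = ix + a
        if jx < 0 or jx >= nx or wx == 0.0:
            continue
        for b in range(2):
            wy = fy if b == 1 else 1.0 - fy
            jy = iy + b
            if jy < 0 or jy >= ny or wy == 0.0:
                continue
            for c in range(2):
                wz = fz if c == 1 else 1.0 - fz
                jz = iz + c
                if jz < 0 or jz >= nz or wz == 0.0:
                    continue
                vol[jx, jy, jz] += wx * wy * wz * value


@njit(cache=True, fastmath=False)
def _project_kernel(
    vol, origin, spacing, source, det_center, e_u, e_v, du, dv, rows, cols, step, out,
    adjoint, weights,
):
    """Shared ray loop.  adjoint == 0: gather line integrals of ``vol`` into
    ``out`` (rows x cols).  adjoint == 1: scatter ``weights`` (rows x cols)
    into ``vol`` along the identical samples — the exact transpose."""
    nx, ny, nz = vol.shape
    half_r = 0.5 * (rows - 1)
    half_c = 0.5 * (cols - 1)
    for r in range(rows):
        for c in range(cols):
            # physical pixel position -> unit ray direction
            pxw = det_center[0] + (c - half_c) * du * e_u[0] + (r - half_r) * dv * e_v[0]
            pyw = det_center[1] + (c - half_c) * du * e_u[1] + (r - half_r) * dv * e_v[1]
            pzw = det_center[2] + (c - half_c) * du * e_u[2] + (r - half_r) * dv * e_v[2]
            dxw = pxw - source[0]
            dyw = pyw - source[1]
            dzw = pzw - source[2]
            norm = math.sqrt(dxw * dxw + dyw * dyw + dzw * dzw)
            dxw /= norm
            dyw /= norm
            dzw /= norm
            # index coordinates of the source and per-mm index step
            sx = (source[0] - origin[0]) / spacing[0]
            sy = (source[1] - origin[1]) / spacing[1]
            sz = (source[2] - origin[2]) / spacing[2]
            rx = dxw / spacing[0]
            ry = dyw / spacing[1]
            rz = dzw / spacing[2]
            tmin, tmax = _ray_bounds(sx, sy, sz, rx, ry, rz, nx, ny, nz)
            if tmax <= tmin:
                if adjoint == 0:
                    out[r, c] = 0.0
                continue
            nstep = int(math.ceil((tmax - tmin) / step))
            dt = (tmax - tmin) / nstep
            if adjoint == 0:
                acc = 0.0
                for k in range(nstep):
                    t = tmin + (k + 0.5) * dt
                    acc += _trilinear_gather(vol, sx + t * rx, sy + t * ry, sz + t * rz)
                out[r, c] = acc * dt
            else:
                w = weights[r, c] * dt
                if w != 0.0:
                    for k in range(nstep):
                        t = tmin + (k + 0.5) * dt
                        _trilinear_scatter(vol, sx + t * rx, sy + t * ry, sz + t * rz, w)


def _step_length(spacing: np.ndarray) -> float:
    return 0.5 * float(np.min(spacing))


def forward_project(vol: Volume3D, geom: ScanGeometry, frame_index: int) -> np.ndarray:
    """Line integrals of ``vol`` along the rays of one frame.

    Null (NaN) voxels contribute zero; use :func:`fov_validity_mask` to
    exclude detector pixels whose rays cross the null region from loss sums.
    """
    source, det_center, e_u, e_v = geom.frame_vectors(frame_index)
    data = vol.filled(0.0)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite, non-null values")
    out = np.zeros((geom.detector_rows, geom.detector_cols), dtype=np.float64)
    _project_kernel(
        data, vol.origin, vol.spacing, source, det_center, e_u, e_v,
        geom.detector_spacing[1], geom.detector_spacing[0],
        geom.detector_rows, geom.detector_cols,
        _step_length(vol.spacing), out, 0, out,
    )
    return out


def back_project(
    proj: np.ndarray, geom: ScanGeometry, frame_index: int, target_grid: Volume3D
) -> Volume3D:
    """Exact adjoint of :func:`forward_project` onto ``target_grid``'s grid."""
    proj = np.asarray(proj, dtype=np.float64)
    if proj.shape != (geom.detector_rows, geom.detector_cols):
        raise ValueError(
            f"projection shape {proj.shape} does not match detector "
            f"({geom.detector_rows}, {geom.detector_cols})"
        )
    source, det_center, e_u, e_v = geom.frame_vectors(frame_index)
    out = np.zeros(target_grid.shape, dtype=np.float64)
    dummy = np.zeros((geom.detector_rows, geom.detector_cols), dtype=np.float64)
    _project_kernel(
        out, target_grid.origin, target_grid.spacing, source, det_center, e_u, e_v,
        geom.detector_spacing[1], geom.detector_spacing[0],
        geom.detector_rows, geom.detector_cols,
        _step_length(target_grid.spacing), dummy, 1, proj,
    )
    return target_grid.like(out)


def fov_validity_mask(
    vol: Volume3D, geom: ScanGeometry, frame_index: int, fov_radius: float | None = None,
    tol: float = 1e-9, mode: str = "intersects",
) -> np.ndarray:
    """Validity mask over detector pixels with respect to the FOV cylinder.

    ``mode="intersects"`` (default, used by the fitting loss): a pixel is
    valid when its ray intersects the reconstruction FOV at all — pixels that
    see nothing of the reconstructed volume carry no information about it.
    ``mode="strict"``: a pixel is valid only when its ray never touches the
    null (outside-FOV) region of the volume's bounding box; appropriate when
    the data may contain attenuation outside the FOV.  Both are computed by
    forward-projecting region indicators.
    """
    if mode == "strict":
        indicator = (~vol.fov_mask(fov_radius)).astype(np.float64)
        hit = forward_project(vol.like(indicator), geom, frame_index)
        return hit <= tol
    if mode == "intersects":
        indicator = vol.fov_mask(fov_radius).astype(np.float64)
        hit = forward_project(vol.like(indicator), geom, frame_index)
        return hit > tol
    raise ValueError(f"unknown validity mode {mode!r}")


def apply_fov_null(vol: Volume3D, fov_radius: float | None = None) -> Volume3D:
    """Return a copy with voxels outside the FOV cylinder set to the null value."""
    out = vol.copy()
    out.data = out.data.astype(np.float64)
    out.data[~vol.fov_mask(fov_radius)] = NULL_VALUE
    return out
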