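"""Cubic B-spline free-form deformation (FFD) and image warping.

The transform is parameterized by 3-vector displacements (mm) on a coarse
control-point lattice.  ``ffd_to_dvf`` evaluates the tensor-product cubic
B-spline interpolant on a voxel grid; ``dvf_adjoint_to_cpg`` is its exact
adjoint, needed to pull projection-domain loss gradients back onto the control
points.  ``warp_image`` resamples an image through the pull-back convention

    out(x) = vol(x + D(x))

with trilinear interpolation (zero outside the volume), and
``warp_position_gradient`` returns the exact derivative of that resampling
with respect to the sample position, i.e. the chain-rule factor linking the
image to the deformation field.  Using the exact interpolant derivative (the
per-cell slope, not a smoothed central difference) keeps the analytic loss
gradient consistent with finite differences of the loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import Volume3D

DEFAULT_GRID_SPACING_VOXELS = 8  # control-point spacing in level-image voxels


# ---------------------------------------------------------------------------
# Control-point grid
# ---------------------------------------------------------------------------


@dataclass
class ControlPointGrid:
    """Cubic B-spline control lattice with 3-vector node displacements (mm).

    ``displacements`` has shape ``(nnx, nny, nnz, 3)``; node ``(i, j, k)``
    sits at world position ``node_origin + (i, j, k) * node_spacing``.
    The lattice must cover the image domain plus one support margin so that
    every voxel has a full 4x4x4 stencil.
    """

    displacements: np.ndarray
    node_spacing: np.ndarray  # mm, (3,)
    node_origin: np.ndarray  # mm, world position of node (0, 0, 0)

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        self.node_spacing = np.asarray(self.node_spacing, dtype=np.float64)
        self.node_origin = np.asarray(self.node_origin, dtype=np.float64)
        if self.displacements.ndim != 4 or self.displacements.shape[3] != 3:
            raise ValueError("displacements must have shape (nnx, nny, nnz, 3)")
        if np.any(self.node_spacing <= 0):
            raise ValueError("node spacing must be positive")

    @property
    def node_shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]  # type: ignore[return-value]

    def zeros_like(self) -> "ControlPointGrid":
        return ControlPointGrid(
            np.zeros_like(self.displacements), self.node_spacing.copy(), self.node_origin.copy()
        )

    def copy(self) -> "ControlPointGrid":
        return ControlPointGrid(
            self.displacements.copy(), self.node_spacing.copy(), self.node_origin.copy()
        )

    @classmethod
    def covering(
        cls, grid: Volume3D, spacing_voxels: int = DEFAULT_GRID_SPACING_VOXELS
    ) -> "ControlPointGrid":
        """Zero-displacement lattice covering ``grid`` with one-node margin.

        Node spacing is ``spacing_voxels`` image voxels per axis; nodes run
        from index -1 (one before the image origin) past the far image edge
        so the cubic support is complete everywhere inside the image.
        """
        shape = np.asarray(grid.shape)
        node_spacing = grid.spacing * spacing_voxels
        # highest lattice coordinate needed: u_max = (shape-1)/spacing_voxels
        n_hi = np.floor((shape - 1) / spacing_voxels).astype(int) + 2
        n_nodes = n_hi + 2  # indices -1 .. n_hi  ->  n_hi + 2 nodes
        node_origin = grid.origin - node_spacing
        return cls(
            np.zeros((n_nodes[0], n_nodes[1], n_nodes[2], 3)), node_spacing, node_origin
        )

    def check_covers(self, grid: Volume3D) -> None:
        eps = 1e-9  # guard against float dust on exact node boundaries
        lo = (grid.origin - self.node_origin) / self.node_spacing
        hi = lo + (np.asarray(grid.shape) - 1) * grid.spacing / self.node_spacing
        nn = np.asarray(self.node_shape)
        if np.any(np.floor(lo + eps) - 1 < 0) or np.any(np.floor(hi - eps) + 2 > nn - 1):
            raise ValueError("control-point grid does not cover the image domain with margin")


def cubic_bspline_weights(t: float) -> np.ndarray:
    """The four cubic B-spline basis values for fractional offset ``t`` in [0, 1)."""
    return np.array(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t**3 - 6 * t**2 + 4) / 6.0,
            (-3 * t**3 + 3 * t**2 + 3 * t + 1) / 6.0,
            t**3 / 6.0,
        ]
    )


@njit(cache=True, fastmath=False)
def _bspline_w(t, w):
    w[0] = (1.0 - t) ** 3 / 6.0
    w[1] = (3.0 * t * t * t - 6.0 * t * t + 4.0) / 6.0
    w[2] = (-3.0 * t * t * t + 3.0 * t * t + 3.0 * t + 1.0) / 6.0
    w[3] = t * t * t / 6.0


@njit(cache=True, fastmath=False)
def _ffd_kernel(nodes, node_origin, node_spacing, grid_origin, grid_spacing, out, adjoint):
    """adjoint == 0: evaluate the FFD on the voxel grid into ``out``
    (nx, ny, nz, 3).  adjoint == 1: scatter ``out`` back onto ``nodes``."""
    nx, ny, nz = out.shape[:3]
    nnx, nny, nnz = nodes.shape[:3]
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    for ix in range(nx):
        ux = (grid_origin[0] + ix * grid_spacing[0] - node_origin[0]) / node_spacing[0]
        bx = int(math.floor(ux))
        bx = min(max(bx, 1), nnx - 3)  # clamp float dust at lattice edges
        _bspline_w(ux - bx, wx)
        for iy in range(ny):
            uy = (grid_origin[1] + iy * grid_spacing[1] - node_origin[1]) / node_spacing[1]
            by = int(math.floor(uy))
            by = min(max(by, 1), nny - 3)
            _bspline_w(uy - by, wy)
            for iz in range(nz):
                uz = (grid_origin[2] + iz * grid_spacing[2] - node_origin[2]) / node_spacing[2]
                bz = int(math.floor(uz))
                bz = min(max(bz, 1), nnz - 3)
                _bspline_w(uz - bz, wz)
                if adjoint == 0:
                    vx = 0.0
                    vy = 0.0
                    vz = 0.0
                    for a in range(4):
                        ja = bx - 1 + a
                        for b in range(4):
                            jb = by - 1 + b
                            wab = wx[a] * wy[b]
                            for c in range(4):
                                jc = bz - 1 + c
                                w = wab * wz[c]
                                vx += w * nodes[ja, jb, jc, 0]
                                vy += w * nodes[ja, jb, jc, 1]
                                vz += w * nodes[ja, jb, jc, 2]
                    out[ix, iy, iz, 0] = vx
                    out[ix, iy, iz, 1] = vy
                    out[ix, iy, iz, 2] = vz
                else:
                    gx = out[ix, iy, iz, 0]
                    gy = out[ix, iy, iz, 1]
                    gz = out[ix, iy, iz, 2]
                    for a in range(4):
                        ja = bx - 1 + a
                        for b in range(4):
                            jb = by - 1 + b
                            wab = wx[a] * wy[b]
                            for c in range(4):
                                jc = bz - 1 + c
                                w = wab * wz[c]
                                nodes[ja, jb, jc, 0] += w * gx
                                nodes[ja, jb, jc, 1] += w * gy
                                nodes[ja, jb, jc, 2] += w * gz


def ffd_to_dvf(cpg: ControlPointGrid, grid: Volume3D) -> np.ndarray:
    """Dense displacement field (mm) of shape ``grid.shape + (3,)``."""
    cpg.check_covers(grid)
    out = np.zeros(grid.shape + (3,), dtype=np.float64)
    _ffd_kernel(
        cpg.displacements, cpg.node_origin, cpg.node_spacing,
        grid.origin, grid.spacing, out, 0,
    )
    return out


def dvf_adjoint_to_cpg(voxel_field: np.ndarray, cpg_meta: ControlPointGrid, grid: Volume3D) -> np.ndarray:
    """Exact adjoint of :func:`ffd_to_dvf`: voxel 3-vector field -> node-shaped gradient."""
    cpg_meta.check_covers(grid)
    voxel_field = np.ascontiguousarray(voxel_field, dtype=np.float64)
    if voxel_field.shape != grid.shape + (3,):
        raise ValueError("voxel field shape does not match the grid")
    nodes = np.zeros(cpg_meta.node_shape + (3,), dtype=np.float64)
    _ffd_kernel(
        nodes, cpg_meta.node_origin, cpg_meta.node_spacing,
        grid.origin, grid.spacing, voxel_field, 1,
    )
    return nodes


# ---------------------------------------------------------------------------
# Warping and its position derivative
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _warp_kernel(vol, dvf, spacing, out, grad, want_grad):
    """Pull-back warp out(x) = vol(x + D(x)/spacing) with zero padding.

    want_grad == 1 additionally fills ``grad`` (nx, ny, nz, 3) with the exact
    derivative of the trilinear sample w.r.t. the *world* (mm) position.
    """
    nx, ny, nz = vol.shape
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                x = ix + dvf[ix, iy, iz, 0] / spacing[0]
                y = iy + dvf[ix, iy, iz, 1] / spacing[1]
                z = iz + dvf[ix, iy, iz, 2] / spacing[2]
                jx = int(math.floor(x))
                jy = int(math.floor(y))
                jz = int(math.floor(z))
                fx = x - jx
                fy = y - jy
                fz = z - jz
                # gather the 2x2x2 neighbourhood with zero padding
                v = np.zeros((2, 2, 2))
                for a in range(2):
                    ja = jx + a
                    if ja < 0 or ja >= nx:
                        continue
                    for b in range(2):
                        jb = jy + b
                        if jb < 0 or jb >= ny:
                            continue
                        for c in range(2):
                            jc = jz + c
                            if jc < 0 or jc >= nz:
                                continue
                            v[a, b, c] = vol[ja, jb, jc]
                c00 = v[0, 0, 0] * (1 - fx) + v[1, 0, 0] * fx
                c01 = v[0, 0, 1] * (1 - fx) + v[1, 0, 1] * fx
                c10 = v[0, 1, 0] * (1 - fx) + v[1, 1, 0] * fx
                c11 = v[0, 1, 1] * (1 - fx) + v[1, 1, 1] * fx
                c0 = c00 * (1 - fy) + c10 * fy
                c1 = c01 * (1 - fy) + c11 * fy
                out[ix, iy, iz] = c0 * (1 - fz) + c1 * fz
                if want_grad == 1:
                    # d/dfx
                    d00 = v[1, 0, 0] - v[0, 0, 0]
                    d01 = v[1, 0, 1] - v[0, 0, 1]
                    d10 = v[1, 1, 0] - v[0, 1, 0]
                    d11 = v[1, 1, 1] - v[0, 1, 1]
                    gx = ((d00 * (1 - fy) + d10 * fy) * (1 - fz)
                          + (d01 * (1 - fy) + d11 * fy) * fz)
                    gy = ((c10 - c00) * (1 - fz) + (c11 - c01) * fz)
                    gz = c1 - c0
                    grad[ix, iy, iz, 0] = gx / spacing[0]
                    grad[ix, iy, iz, 1] = gy / spacing[1]
                    grad[ix, iy, iz, 2] = gz / spacing[2]


def warp_image(vol: Volume3D, dvf: np.ndarray) -> Volume3D:
    """Resample ``vol`` through the pull-back convention out(x) = vol(x + D(x)).

    ``dvf`` is in mm on ``vol``'s grid.  Samples outside the volume return the
    null contribution (zero); null voxels in ``vol`` are treated as zero.
    """
    dvf = np.ascontiguousarray(dvf, dtype=np.float64)
    if dvf.shape != vol.shape + (3,):
        raise ValueError("DVF shape does not match the volume grid")
    data = vol.filled(0.0)
    out = np.zeros_like(data)
    dummy = np.zeros((1, 1, 1, 3))
    _warp_kernel(data, dvf, vol.spacing, out, dummy, 0)
    return vol.like(out)


def warp_position_gradient(vol: Volume3D, dvf: np.ndarray) -> np.ndarray:
    """Exact derivative (mm^-1) of the warped sample w.r.t. the displacement.

    Returns the per-voxel 3-vector field d[vol(x + D(x))]/dD(x) — the spatial
    slope of the trilinear interpolant evaluated at the warped positions.
    """
    dvf = np.ascontiguousarray(dvf, dtype=np.float64)
    if dvf.shape != vol.shape + (3,):
        raise ValueError("DVF shape does not match the volume grid")
    data = vol.filled(0.0)
    out = np.zeros_like(data)
    grad = np.zeros(vol.shape + (3,), dtype=np.float64)
    _warp_kernel(data, dvf, vol.spacing, out, grad, 1)
    return grad


# ---------------------------------------------------------------------------
# DVF inversion (fixed point) and vector-field sampling
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _sample_vector_field(field, spacing, positions_mm_offset, out):
    """out(x) = field(x + offset(x)) with trilinear interpolation, zero padded.

    ``field`` and ``positions_mm_offset`` are (nx, ny, nz, 3) in mm.
    """
    nx, ny, nz = field.shape[:3]
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                x = ix + positions_mm_offset[ix, iy, iz, 0] / spacing[0]
                y = iy + positions_mm_offset[ix, iy, iz, 1] / spacing[1]
                z = iz + positions_mm_offset[ix, iy, iz, 2] / spacing[2]
                jx = int(math.floor(x))
                jy = int(math.floor(y))
                jz = int(math.floor(z))
                fx = x - jx
                fy = y - jy
                fz = z - jz
                for comp in range(3):
                    acc = 0.0
                    for a in range(2):
                        ja = jx + a
                        if ja < 0 or ja >= nx:
                            continue
                        wa = fx if a == 1 else 1.0 - fx
                        for b in range(2):
                            jb = jy + b
                            if jb < 0 or jb >= ny:
                                continue
                            wb = fy if b == 1 else 1.0 - fy
                            for c in range(2):
                                jc = jz + c
                                if jc < 0 or jc >= nz:
                                    continue
                                wc = fz if c == 1 else 1.0 - fz
                                acc += wa * wb * wc * field[ja, jb, jc, comp]
                    out[ix, iy, iz, comp] = acc


def invert_dvf(
    dvf: np.ndarray,
    spacing: np.ndarray,
    max_iters: int = 20,
    tol_voxel: float = 0.01,
) -> np.ndarray:
    """Fixed-point inverse of a displacement field.

    Solves E(x) = -D(x + E(x)) so that (x + E(x)) + D(x + E(x)) = x, i.e. the
    returned field composes with ``dvf`` to the identity.  Iterates at most
    ``max_iters`` times, stopping when the mean update falls below
    ``tol_voxel`` voxels.
    """
    dvf = np.ascontiguousarray(dvf, dtype=np.float64)
    spacing = np.asarray(spacing, dtype=np.float64)
    inv = np.zeros_like(dvf)
    sampled = np.zeros_like(dvf)
    mean_spacing = float(np.mean(spacing))
    for _ in range(max_iters):
        _sample_vector_field(dvf, spacing, inv, sampled)
        new = -sampled
        update = float(np.mean(np.abs(new - inv))) / mean_spacing
        inv = new
        if update < tol_voxel:
            break
    return inv


# ---------------------------------------------------------------------------
# Dyadic refinement (level transfer)
# ---------------------------------------------------------------------------


def refine_cpg(cpg: ControlPointGrid, fine_grid: Volume3D, spacing_voxels: int = DEFAULT_GRID_SPACING_VOXELS) -> ControlPointGrid:
    """Transfer node displacements to the lattice of a finer resolution level.

    Halving the node spacing uses the exact cubic B-spline subdivision masks
    (odd: (c_{i-1} + 6 c_i + c_{i+1})/8, even: (c_i + c_{i+1})/2), so the
    represented deformation is preserved up to lattice-boundary effects.
    """
    fine = ControlPointGrid.covering(fine_grid, spacing_voxels)
    ratio = cpg.node_spacing / fine.node_spacing
    if not np.allclose(ratio, 2.0, atol=1e-9):
        raise ValueError("refine_cpg supports exact dyadic refinement only")
    coeff = cpg.displacements
    for axis in range(3):
        coeff = _subdivide_axis(coeff, axis)
    # coarse node j sits at node_origin_c + j*h_c; subdivided node k at
    # node_origin_c + k*h_f.  Map onto the fine lattice by integer offset.
    offset = (cpg.node_origin - fine.node_origin) / fine.node_spacing
    off = np.round(offset).astype(int)
    if not np.allclose(offset, off, atol=1e-6):
        raise ValueError("coarse and fine lattices are not aligned")
    out = np.zeros(fine.node_shape + (3,))
    src_lo = np.maximum(0, -off)
    dst_lo = np.maximum(0, off)
    count = np.minimum(np.asarray(coeff.shape[:3]) - src_lo, np.asarray(out.shape[:3]) - dst_lo)
    sl_src = tuple(slice(src_lo[a], src_lo[a] + count[a]) for a in range(3))
    sl_dst = tuple(slice(dst_lo[a], dst_lo[a] + count[a]) for a in range(3))
    out[sl_dst] = coeff[sl_src]
    fine.displacements = out
    return fine


def _subdivide_axis(coeff: np.ndarray, axis: int) -> np.ndarray:
    """One level of cubic B-spline knot-insertion along ``axis`` (edge padded)."""
    c = np.moveaxis(coeff, axis, 0)
    padded = np.concatenate([c[:1], c, c[-1:]], axis=0)
    n = c.shape[0]
    even = 0.125 * (padded[:-2] + 6.0 * padded[1:-1] + padded[2:])  # at coarse nodes
    odd = 0.5 * (padded[1:-1][: n - 1] + padded[2:][: n - 1])  # at midpoints
    out = np.empty((2 * n - 1,) + c.shape[1:], dtype=coeff.dtype)
    out[0::2] = even
    out[1::2] = odd
    return np.moveaxis(out, 0, axis)
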