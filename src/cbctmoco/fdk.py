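"""FDK reconstruction and its motion-compensated variant.

Standard Feldkamp-Davis-Kress reconstruction for a full circular scan with a
flat panel: cosine weighting, row-wise ramp filtering (band-limited Ram-Lak
kernel with a Hann rolloff, applied in the frequency domain with zero padding)
and distance-weighted voxel-driven backprojection with the 2*pi/N_t angular
weight.  Detector coordinates are rescaled to the isocenter plane so the
classic flat-detector weighting applies directly.

The motion-compensated variant resamples each per-projection filtered
backprojection volume through the reference-to-frame mapping before
accumulation.  Stored deformation fields follow the pull-back convention
(frame coordinates + D_t = reference sampling position), so the needed
reference-to-frame maps are obtained by fixed-point inversion of D_t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .bspline import invert_dvf, _sample_vector_field
from .geometry import NULL_VALUE, ProjectionStack, ScanGeometry, Volume3D


@dataclass
class ReconstructionConfig:
    """Output grid and filter settings for (MC-)FDK reconstruction."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] | None = None  # None -> centered on isocenter
    filter_window: str = "hann"  # "hann" or "ramlak"
    short_scan: bool = False  # fixed False; full-arc scans only
    fov_radius: float | None = None  # mm; None -> inscribed cylinder

    def __post_init__(self) -> None:
        if self.short_scan:
            raise NotImplementedError("short-scan (Parker) weighting is not supported")
        if self.filter_window not in ("hann", "ramlak"):
            raise ValueError(f"unknown filter window {self.filter_window!r}")

    def make_grid(self) -> Volume3D:
        if self.origin is None:
            vol = Volume3D.centered(self.shape, self.spacing)
        else:
            vol = Volume3D(
                np.zeros(self.shape), np.asarray(self.spacing), np.asarray(self.origin)
            )
        r = vol.fov_radius() if self.fov_radius is None else self.fov_radius
        if self.fov_radius is not None and self.fov_radius > vol.fov_radius() + 1e-6:
            raise ValueError("fov_radius exceeds the grid's inscribed cylinder")
        return vol


# ---------------------------------------------------------------------------
# Ramp filtering
# ---------------------------------------------------------------------------


def _ramp_kernel(n: int, spacing: float) -> np.ndarray:
    """Band-limited spatial ramp kernel h[k] on ``n`` taps (Kak-Slaney)."""
    k = np.arange(-(n // 2), n - n // 2)
    h = np.zeros(n, dtype=np.float64)
    h[k == 0] = 1.0 / (4.0 * spacing**2)
    odd = k % 2 != 0
    h[odd] = -1.0 / (np.pi * k[odd] * spacing) ** 2
    return np.roll(h, -(n // 2))  # zero lag first, ready for FFT


def filter_projection(
    proj: np.ndarray, geom: ScanGeometry, window: str = "hann"
) -> np.ndarray:
    """Cosine weighting and ramp filtering of one projection (rows x cols).

    Works in detector coordinates rescaled to the isocenter plane; the output
    is ready for distance-weighted backprojection.
    """
    rows, cols = proj.shape
    dv, du = geom.detector_spacing
    scale = geom.sid / geom.sdd
    da = du * scale
    db = dv * scale
    u = (np.arange(cols) - 0.5 * (cols - 1)) * da
    v = (np.arange(rows) - 0.5 * (rows - 1)) * db
    cosw = geom.sid / np.sqrt(geom.sid**2 + u[None, :] ** 2 + v[:, None] ** 2)
    weighted = proj * cosw

    nfft = 1 << int(math.ceil(math.log2(2 * cols)))
    H = np.fft.rfft(_ramp_kernel(nfft, da)).real
    if window == "hann":
        f = np.fft.rfftfreq(nfft, d=da)
        fmax = 0.5 / da
        H = H * (0.5 * (1.0 + np.cos(np.pi * f / fmax)))
    spec = np.fft.rfft(weighted, n=nfft, axis=1)
    filtered = np.fft.irfft(spec * H[None, :], n=nfft, axis=1)[:, :cols]
    return filtered * da  # convolution integral scaling


# ---------------------------------------------------------------------------
# Voxel-driven FDK backprojection
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _fdk_backproject_kernel(
    Q, sid, sdd, du, dv, rows, cols, cos_t, sin_t, origin, spacing, dbeta, out
):
    nx, ny, nz = out.shape
    mag = sdd / sid
    half_r = 0.5 * (rows - 1)
    half_c = 0.5 * (cols - 1)
    for ix in range(nx):
        px = origin[0] + ix * spacing[0]
        for iy in range(ny):
            py = origin[1] + iy * spacing[1]
            # distance from the source plane along the central-ray axis
            d = sid - (px * cos_t + py * sin_t)
            if d <= 1e-6:
                continue
            U = d / sid
            a = (-px * sin_t + py * cos_t) / U  # isocenter-plane coordinate
            cf = a * mag / du + half_c
            ic = int(math.floor(cf))
            fc = cf - ic
            if ic < -1 or ic > cols - 1:
                continue
            w = dbeta / (2.0 * U * U)
            for iz in range(nz):
                pz = origin[2] + iz * spacing[2]
                b = pz / U
                rf = b * mag / dv + half_r
                ir = int(math.floor(rf))
                fr = rf - ir
                if ir < -1 or ir > rows - 1:
                    continue
                acc = 0.0
                for aa in range(2):
                    jr = ir + aa
                    if jr < 0 or jr >= rows:
                        continue
                    wr = fr if aa == 1 else 1.0 - fr
                    for bb in range(2):
                        jc = ic + bb
                        if jc < 0 or jc >= cols:
                            continue
                        wc = fc if bb == 1 else 1.0 - fc
                        acc += wr * wc * Q[jr, jc]
                out[ix, iy, iz] += w * acc


def fdk_frame_backprojection(
    filtered: np.ndarray, geom: ScanGeometry, frame_index: int, grid: Volume3D
) -> np.ndarray:
    """Distance-weighted backprojection of one filtered projection (float64)."""
    t = math.radians(float(geom.angles[frame_index]))
    out = np.zeros(grid.shape, dtype=np.float64)
    dbeta = 2.0 * math.pi / geom.n_frames
    _fdk_backproject_kernel(
        np.ascontiguousarray(filtered, dtype=np.float64),
        geom.sid, geom.sdd,
        geom.detector_spacing[1], geom.detector_spacing[0],
        geom.detector_rows, geom.detector_cols,
        math.cos(t), math.sin(t),
        grid.origin, grid.spacing, dbeta, out,
    )
    return out


def _null_outside_fov(data: np.ndarray, grid: Volume3D, fov_radius: float | None) -> np.ndarray:
    out = data.astype(np.float32)
    out[~grid.fov_mask(fov_radius)] = NULL_VALUE
    return out


def fdk_reconstruct(projs: ProjectionStack, cfg: ReconstructionConfig) -> Volume3D:
    """Standard full-scan FDK reconstruction.

    Accumulates in double precision and casts to single; voxels outside the
    FOV cylinder are set to the null value.
    """
    if projs.n_frames == 0:
        raise ValueError("empty projection stack")
    grid = cfg.make_grid()
    geom = projs.geometry
    acc = np.zeros(grid.shape, dtype=np.float64)
    for t in range(projs.n_frames):
        filtered = filter_projection(projs.frame(t), geom, cfg.filter_window)
        acc += fdk_frame_backprojection(filtered, geom, t, grid)
    return grid.like(_null_outside_fov(acc, grid, cfg.fov_radius))


def motion_compensated_fdk(
    projs: ProjectionStack,
    cfg: ReconstructionConfig,
    dvf_for_frame: Callable[[int, Volume3D], np.ndarray] | Sequence[np.ndarray],
    invert_max_iters: int = 20,
    invert_tol_voxel: float = 0.01,
) -> Volume3D:
    """Motion-compensated FDK.

    ``dvf_for_frame`` supplies the pull-back displacement field D_t (mm, on
    the output grid) for every frame — either a callable ``(t, grid) -> dvf``
    or a sequence of precomputed fields.  Each per-frame filtered
    backprojection volume is resampled through the fixed-point inverse of
    D_t (the reference-to-frame map) before accumulation, yielding the
    motion-free estimate.
    """
    if projs.n_frames == 0:
        raise ValueError("empty projection stack")
    grid = cfg.make_grid()
    geom = projs.geometry
    acc = np.zeros(grid.shape, dtype=np.float64)
    warped = np.zeros(grid.shape + (3,), dtype=np.float64)
    for t in range(projs.n_frames):
        if callable(dvf_for_frame):
            dvf = dvf_for_frame(t, grid)
        else:
            dvf = dvf_for_frame[t]
        if dvf is None:
            raise ValueError(f"missing deformation field for frame {t}")
        dvf = np.ascontiguousarray(dvf, dtype=np.float64)
        if dvf.shape != grid.shape + (3,):
            raise ValueError("deformation field shape does not match the output grid")
        filtered = filter_projection(projs.frame(t), geom, cfg.filter_window)
        bp = fdk_frame_backprojection(filtered, geom, t, grid)
        if np.any(dvf):
            inv = invert_dvf(dvf, grid.spacing, invert_max_iters, invert_tol_voxel)
            # resample the frame-t backprojection at x + inv(x)
            bp_field = np.zeros(grid.shape + (3,), dtype=np.float64)
            bp_field[..., 0] = bp
            _sample_vector_field(bp_field, grid.spacing, inv, warped)
            acc += warped[..., 0]
        else:
            acc += bp
    return grid.like(_null_outside_fov(acc, grid, cfg.fov_radius))
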