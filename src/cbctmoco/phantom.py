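"""Analytic 4-D thorax phantom and cone-beam scan simulator.

A digital stand-in for anthropomorphic-phantom pipelines: a static thorax of
smoothed ellipsoids (body, two lungs, a liver dome under the right lung, a
spine column) with a 15 mm spherical tumor in the lower left lung; two
breathing traces (superior-inferior diaphragm motion and anterior-posterior
chest-surface motion); smooth, invertible ground-truth deformation fields
driven by those traces; and simulated line-integral projections in an
Elekta-style geometry (SID 1000 mm, SDD 1536 mm, 360 degree arc, 310 frames
at 5.4 fps by default).

Two motion mechanisms are available.  ``model-class`` drives a fixed
ground-truth correspondence model (two B-spline components: an SI field
peaking at the diaphragm and an AP field peaking at the anterior chest) with
the traces, so a two-signal surrogate fit has an exact solution in its own
search space.  ``analytic`` evaluates the same smooth envelope fields per
voxel without the B-spline lattice.  Displacement amplitudes default to
typical respiratory magnitudes (diaphragm 25 mm SI peak-to-peak in the
large-motion regular regime, 15 mm in the irregular regime; chest 3 mm AP)
and stay small enough by construction that the deformation Jacobian remains
positive.

The generated fields are globally smooth: sliding motion at the chest wall is
deliberately not reproduced, consistent with what a B-spline transform can
represent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .bspline import ControlPointGrid, ffd_to_dvf, warp_image
from .geometry import ProjectionStack, ScanGeometry, Volume3D

FULL_RES_SHAPE = (375, 375, 343)  # 1 mm isotropic full-scale option
DEFAULT_SHAPE = (128, 128, 128)  # 2 mm desk-scale default
PANEL_SIZE_MM = 409.6  # 512 x 0.8 mm flat panel
DEFAULT_SID = 1000.0
DEFAULT_SDD = 1536.0
DEFAULT_N_FRAMES = 310
DEFAULT_FPS = 5.4


# ---------------------------------------------------------------------------
# Reference phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry (mm) and attenuation (mm^-1) of the analytic thorax."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: float = 2.0
    body_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_axes: tuple[float, float, float] = (110.0, 85.0, 120.0)
    body_mu: float = 0.020
    lung_axes: tuple[float, float, float] = (42.0, 55.0, 78.0)
    lung_offset: tuple[float, float, float] = (55.0, 5.0, 20.0)  # +/-x mirrored
    lung_mu: float = 0.004
    liver_center: tuple[float, float, float] = (50.0, 0.0, -70.0)
    liver_axes: tuple[float, float, float] = (48.0, 48.0, 38.0)
    liver_mu: float = 0.022
    spine_center_y: float = 55.0
    spine_radius: float = 14.0
    spine_mu: float = 0.035
    tumor_center: tuple[float, float, float] = (-55.0, 5.0, -30.0)
    tumor_radius: float = 15.0
    tumor_mu: float = 0.020
    edge_smoothing_voxels: float = 0.8
    # heterogeneous soft-tissue texture: real thoraces are not piecewise
    # constant, and without internal texture projection-domain similarity
    # cannot observe motion inside homogeneous regions at all
    texture_amplitude: float = 0.2
    texture_scale_mm: float = 12.0
    texture_seed: int = 42

    def grid(self) -> Volume3D:
        return Volume3D.centered(self.shape, self.spacing)

    def validate(self) -> None:
        if min(self.body_mu, self.lung_mu, self.liver_mu, self.spine_mu, self.tumor_mu) < 0:
            raise ValueError("attenuations must be non-negative")
        # tumor sphere strictly inside the left lung ellipsoid
        lc = np.array([-self.lung_offset[0], self.lung_offset[1], self.lung_offset[2]])
        d = np.abs(np.asarray(self.tumor_center) - lc) + self.tumor_radius
        if np.sum((d / np.asarray(self.lung_axes)) ** 2) > 1.0:
            raise ValueError("tumor is not strictly inside the left lung")


def _ellipsoid(coords, center, axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = axes
    return (
        ((x[:, None, None] - cx) / ax) ** 2
        + ((y[None, :, None] - cy) / ay) ** 2
        + ((z[None, None, :] - cz) / az) ** 2
    ) <= 1.0


def make_reference_phantom(spec: PhantomSpec) -> tuple[Volume3D, Volume3D]:
    """Reference-state attenuation volume and binary tumor mask."""
    spec.validate()
    grid = spec.grid()
    coords = grid.world_coordinates()
    x, y, z = coords

    mu = np.zeros(grid.shape, dtype=np.float64)
    body = _ellipsoid(coords, spec.body_center, spec.body_axes)
    mu[body] = spec.body_mu
    ox, oy, oz = spec.lung_offset
    for sx in (-1.0, 1.0):
        lung = _ellipsoid(coords, (sx * ox, oy, oz), spec.lung_axes)
        mu[lung & body] = spec.lung_mu
    liver = _ellipsoid(coords, spec.liver_center, spec.liver_axes)
    mu[liver & body] = spec.liver_mu
    spine = (
        (x[:, None, None] ** 2 + (y[None, :, None] - spec.spine_center_y) ** 2)
        <= spec.spine_radius**2
    ) & (np.abs(z[None, None, :]) <= spec.body_axes[2] - 10.0)
    mu[spine & body] = spec.spine_mu
    tumor = _ellipsoid(coords, spec.tumor_center, (spec.tumor_radius,) * 3)
    mu[tumor] = spec.tumor_mu

    if spec.texture_amplitude > 0:
        t_rng = np.random.default_rng(spec.texture_seed)
        sigma_vox = spec.texture_scale_mm / spec.spacing
        noise = gaussian_filter(t_rng.standard_normal(grid.shape), sigma_vox)
        noise /= max(np.abs(noise).max(), 1e-12)
        mu = mu * (1.0 + spec.texture_amplitude * noise * body)
    if spec.edge_smoothing_voxels > 0:
        mu = gaussian_filter(mu, spec.edge_smoothing_voxels)
    return grid.like(mu), grid.like(tumor.astype(np.float64))


# ---------------------------------------------------------------------------
# Breathing traces
# ---------------------------------------------------------------------------


@dataclass
class BreathingTraces:
    """Diaphragm (SI) and chest-surface (AP) traces in mm, zero-mean.

    ``regular``: in-phase quasi-sinusoids with fixed amplitude (the chest
    waveform carries a mild harmonic difference so the two signals are not
    numerically collinear).  ``irregular``: the chest lags the diaphragm by
    a configurable phase offset (hysteresis; default 40 degrees) and both
    traces carry seeded per-cycle amplitude variability, emulating
    inter-cycle variation.
    """

    s_diaphragm: "np.ndarray"
    s_chest: "np.ndarray"
    times: np.ndarray
    regime: Literal["regular", "irregular"]
    diaphragm_amplitude_mm: float
    chest_amplitude_mm: float
    phase_offset_deg: float
    cycle_variability: float


def make_breathing_traces(
    regime: Literal["regular", "irregular"],
    n_frames: int = DEFAULT_N_FRAMES,
    frame_rate_hz: float = DEFAULT_FPS,
    seed: int = 0,
    period_s: float = 4.0,
    diaphragm_amplitude_mm: float | None = None,
    chest_amplitude_mm: float = 3.0,
    phase_offset_deg: float | None = None,
    cycle_variability: float | None = None,
) -> BreathingTraces:
    if regime not in ("regular", "irregular"):
        raise ValueError(f"unknown breathing regime {regime!r}")
    if diaphragm_amplitude_mm is None:
        # the regular regime carries the larger, deep-breathing excursion;
        # the irregular regime is shallower but variable
        diaphragm_amplitude_mm = 25.0 if regime == "regular" else 15.0
    if phase_offset_deg is None:
        # hysteresis: the chest lags the diaphragm by a fraction of a cycle
        phase_offset_deg = 0.0 if regime == "regular" else 40.0
    if cycle_variability is None:
        cycle_variability = 0.0 if regime == "regular" else 0.3
    if regime == "regular" and (phase_offset_deg != 0.0 or cycle_variability != 0.0):
        raise ValueError("the regular regime is in-phase with fixed amplitude")
    if regime == "irregular" and (phase_offset_deg == 0.0 or cycle_variability == 0.0):
        raise ValueError("the irregular regime needs a phase offset and variability")
    if n_frames < 2:
        raise ValueError("need at least two frames")
    t = np.arange(n_frames) / frame_rate_hz
    rng = np.random.default_rng(seed)

    variability = cycle_variability
    delta = np.deg2rad(phase_offset_deg) / 2.0  # sin^2 halves the angular rate

    def envelope(column_seed_shift: int) -> np.ndarray:
        if variability == 0.0:
            return np.ones(n_frames)
        n_cycles = int(np.ceil(t[-1] / period_s)) + 2
        amps = 1.0 + variability * rng.uniform(-1.0, 1.0, size=n_cycles)
        centers = (np.arange(n_cycles) + 0.5) * period_s
        return np.interp(t, centers, amps)

    shape_d = np.sin(np.pi * t / period_s) ** 2
    s_d = -diaphragm_amplitude_mm * envelope(0) * shape_d
    if regime == "regular":
        shape_c = 0.85 * shape_d + 0.15 * shape_d**2
        s_c = -chest_amplitude_mm * shape_c
    else:
        shape_c = np.sin(np.pi * t / period_s + delta) ** 2
        s_c = -chest_amplitude_mm * envelope(1) * shape_c
    s_d = s_d - s_d.mean()
    s_c = s_c - s_c.mean()
    return BreathingTraces(
        s_d, s_c, t, regime, diaphragm_amplitude_mm, chest_amplitude_mm,
        phase_offset_deg, variability,
    )


# ---------------------------------------------------------------------------
# Ground-truth motion
# ---------------------------------------------------------------------------


def _si_envelope(x, y, z) -> np.ndarray:
    """Dimensionless SI motion weight: peaks at the diaphragm dome.

    Broad so that lower-lobe structures (the tumor sits just above the
    diaphragm) ride the diaphragm excursion nearly one-to-one.
    """
    return np.exp(-((z + 45.0) ** 2) / (2 * 55.0**2)) * np.exp(
        -(x**2 + y**2) / (2 * 110.0**2)
    )


def _ap_envelope(x, y, z) -> np.ndarray:
    """Dimensionless AP motion weight: peaks at the anterior chest surface."""
    return (
        np.exp(-((y + 70.0) ** 2) / (2 * 55.0**2))
        * np.exp(-((z - 0.0) ** 2) / (2 * 90.0**2))
        * np.exp(-(x**2) / (2 * 110.0**2))
    )


@dataclass
class GroundTruthMotion:
    """Per-frame ground-truth deformations in the pull-back convention.

    ``dvf(t, grid)`` returns D_t (mm) on the requested grid, satisfying
    I_t(x) = I_0(x + D_t(x)); D_t is zero whenever both trace values are
    zero, and the generating fields are smooth with positive Jacobian.
    """

    traces: BreathingTraces
    mechanism: Literal["model-class", "analytic"]
    components: list[ControlPointGrid] | None  # model-class C_true (per signal)

    @property
    def n_frames(self) -> int:
        return self.traces.times.size

    def signal_row(self, t: int) -> np.ndarray:
        return np.array([self.traces.s_diaphragm[t], self.traces.s_chest[t]])

    def component_fields(self, grid: Volume3D) -> np.ndarray:
        """Per-signal unit-amplitude displacement fields, shape (2, nx, ny, nz, 3)."""
        if self.mechanism == "model-class":
            assert self.components is not None
            return np.stack([ffd_to_dvf(c, grid) for c in self.components])
        x, y, z = grid.world_coordinates()
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        out = np.zeros((2,) + grid.shape + (3,))
        out[0, ..., 2] = _si_envelope(X, Y, Z)
        out[1, ..., 1] = _ap_envelope(X, Y, Z)
        return out

    def dvf(self, t: int, grid: Volume3D, _cache={}) -> np.ndarray:
        key = (id(self), grid.shape, tuple(grid.spacing), tuple(grid.origin))
        fields = _cache.get(key)
        if fields is None:
            fields = self.component_fields(grid)
            _cache.clear()  # keep at most one grid's worth of fields
            _cache[key] = fields
        s = self.signal_row(t)
        return s[0] * fields[0] + s[1] * fields[1]

    def tumor_mask(self, t: int, ref_mask: Volume3D) -> Volume3D:
        """Ground-truth tumor mask at frame t (pull-back warp, 0.5 threshold)."""
        warped = warp_image(ref_mask, self.dvf(t, ref_mask))
        return ref_mask.like((warped.data > 0.5).astype(np.float64))


def make_gt_motion(
    traces: BreathingTraces,
    spec: PhantomSpec,
    mechanism: Literal["model-class", "analytic"] = "model-class",
) -> GroundTruthMotion:
    """Build the ground-truth motion generator for a phantom.

    For ``model-class`` the two components live on a B-spline lattice whose
    node spacing is 16 phantom voxels — exactly the lattice of the finest
    (half-resolution) fitting level — so a two-signal surrogate fit can in
    principle represent the truth exactly.
    """
    if mechanism == "analytic":
        return GroundTruthMotion(traces, mechanism, None)
    if mechanism != "model-class":
        raise ValueError(f"unknown motion mechanism {mechanism!r}")
    grid = spec.grid()
    cpg = ControlPointGrid.covering(grid, spacing_voxels=16)
    nn = cpg.node_shape
    idx = [np.arange(nn[a]) for a in range(3)]
    pos = [cpg.node_origin[a] + idx[a] * cpg.node_spacing[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*pos, indexing="ij")
    c_si = cpg.zeros_like()
    c_si.displacements[..., 2] = _si_envelope(X, Y, Z)
    c_ap = cpg.zeros_like()
    c_ap.displacements[..., 1] = _ap_envelope(X, Y, Z)
    motion = GroundTruthMotion(traces, mechanism, [c_si, c_ap])
    _check_jacobian(motion, spec)
    return motion


def _check_jacobian(motion: GroundTruthMotion, spec: PhantomSpec) -> None:
    """Numeric Jacobian-determinant check at the extreme trace values."""
    grid = spec.grid()
    fields = motion.component_fields(grid)
    tr = motion.traces
    for s in (
        (tr.s_diaphragm.min(), tr.s_chest.min()),
        (tr.s_diaphragm.max(), tr.s_chest.max()),
        (tr.s_diaphragm.min(), tr.s_chest.max()),
        (tr.s_diaphragm.max(), tr.s_chest.min()),
    ):
        d = s[0] * fields[0] + s[1] * fields[1]
        if min_jacobian_det(d, grid.spacing) <= 0.0:
            raise ValueError("ground-truth deformation is not invertible")


def min_jacobian_det(dvf: np.ndarray, spacing: np.ndarray) -> float:
    """Minimum determinant of I + grad(D) over the field (central differences)."""
    grads = np.empty(dvf.shape[:3] + (3, 3))
    for comp in range(3):
        gx, gy, gz = np.gradient(dvf[..., comp], *spacing)
        grads[..., comp, 0] = gx
        grads[..., comp, 1] = gy
        grads[..., comp, 2] = gz
    jac = grads + np.eye(3)
    return float(np.linalg.det(jac).min())


# ---------------------------------------------------------------------------
# Scan simulation
# ---------------------------------------------------------------------------


def default_geometry(
    n_detector: int,
    n_frames: int = DEFAULT_N_FRAMES,
    frame_rate_hz: float = DEFAULT_FPS,
    arc_deg: float = 360.0,
    sid: float = DEFAULT_SID,
    sdd: float = DEFAULT_SDD,
) -> ScanGeometry:
    """Elekta-style scan geometry with the 409.6 mm panel sampled n x n."""
    px = PANEL_SIZE_MM / n_detector
    return ScanGeometry(
        sid=sid,
        sdd=sdd,
        detector_rows=n_detector,
        detector_cols=n_detector,
        detector_spacing=(px, px),
        angles=np.arange(n_frames) * (arc_deg / n_frames),
        times=np.arange(n_frames) / frame_rate_hz,
    )


def simulate_scan(
    phantom: Volume3D,
    motion: GroundTruthMotion,
    geom: ScanGeometry,
    poisson_flux: float | None = None,
    seed: int = 0,
) -> ProjectionStack:
    """Per frame: warp the reference by D_t^gt, then forward-project at angle_t.

    ``poisson_flux`` (photons per unmodulated ray) optionally adds Poisson
    noise in the intensity domain before log conversion.
    """
    from .geometry import forward_project

    if geom.n_frames != motion.n_frames:
        raise ValueError(
            f"geometry has {geom.n_frames} frames but motion has {motion.n_frames}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty((geom.n_frames, geom.detector_rows, geom.detector_cols))
    for t in range(geom.n_frames):
        dvf = motion.dvf(t, phantom)
        frame_vol = warp_image(phantom, dvf) if np.any(dvf) else phantom
        p = forward_project(frame_vol, geom, t)
        if poisson_flux is not None:
            counts = rng.poisson(poisson_flux * np.exp(-p))
            p = -np.log(np.maximum(counts, 1) / poisson_flux)
        out[t] = p
    return ProjectionStack(out, geom)


# ---------------------------------------------------------------------------
# One-call simulation bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulationBundle:
    """Everything a fitting/evaluation run needs about one simulated scan."""

    spec: PhantomSpec
    reference: Volume3D
    tumor_mask: Volume3D
    traces: BreathingTraces
    motion: GroundTruthMotion
    projections: ProjectionStack


def simulate_study(
    spec: PhantomSpec | None = None,
    regime: Literal["regular", "irregular"] = "regular",
    n_frames: int = DEFAULT_N_FRAMES,
    frame_rate_hz: float = DEFAULT_FPS,
    seed: int = 0,
    mechanism: Literal["model-class", "analytic"] = "model-class",
    poisson_flux: float | None = None,
) -> SimulationBundle:
    spec = spec or PhantomSpec()
    reference, tumor = make_reference_phantom(spec)
    traces = make_breathing_traces(regime, n_frames, frame_rate_hz, seed)
    motion = make_gt_motion(traces, spec, mechanism)
    geom = default_geometry(spec.shape[0], n_frames, frame_rate_hz)
    projs = simulate_scan(reference, motion, geom, poisson_flux, seed)
    return SimulationBundle(spec, reference, tumor, traces, motion, projs)
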