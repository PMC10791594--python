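"""Surrogate-driven correspondence model and projection-domain fitting.

The motion at frame t is parameterized by control-point displacements that are
a linear combination of per-signal components weighted by the surrogate
values:

    M_t = sum_i S_it * C_i        (correspondence model)
    D_t = FFD(M_t)                (cubic B-spline transform)
    I_t = I_0(x + D_t(x))         (pull-back warp of the reference)
    P'_t = A_t I_t                (cone-beam forward projection)

The components C_i are found by minimizing f = -sum_t LNCC(P_t, P'_t) with
stochastic gradient descent over evenly spaced projection subsets.  The
gradient is assembled analytically through the full chain: LNCC gradient ->
adjoint projection -> exact warp position derivative -> FFD adjoint ->
surrogate weighting.  Model fitting alternates with motion-compensated FDK
reconstruction of I_0 in a two-level multi-resolution schedule (1/4 and 1/2
of the native resolution; fitting at full resolution buys little accuracy for
a large run-time cost).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.measure import block_reduce

from .bspline import (
    ControlPointGrid,
    DEFAULT_GRID_SPACING_VOXELS,
    dvf_adjoint_to_cpg,
    ffd_to_dvf,
    refine_cpg,
    warp_image,
    warp_position_gradient,
)
from .fdk import ReconstructionConfig, fdk_reconstruct, motion_compensated_fdk
from .geometry import (
    ProjectionStack,
    Volume3D,
    back_project,
    forward_project,
    fov_validity_mask,
)
from .lncc import LnccConfig, lncc_and_gradient
from .surrogate import SurrogateMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Correspondence model
# ---------------------------------------------------------------------------


@dataclass
class CorrespondenceModel:
    """N_s control-point displacement components sharing one lattice.

    ``components`` has shape ``(N_s, nnx, nny, nnz, 3)`` (mm per unit
    surrogate value); the lattice metadata is carried by ``lattice`` (whose
    own displacements are ignored).  ``level`` records the resolution level
    the model was fitted at.
    """

    components: np.ndarray
    lattice: ControlPointGrid
    level: float = 1.0

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.float64)
        if self.components.ndim != 5 or self.components.shape[4] != 3:
            raise ValueError("components must have shape (N_s, nnx, nny, nnz, 3)")
        if self.components.shape[1:4] != self.lattice.node_shape:
            raise ValueError("components do not match the lattice")

    @property
    def n_signals(self) -> int:
        return self.components.shape[0]

    @classmethod
    def zeros(cls, lattice: ControlPointGrid, n_signals: int, level: float = 1.0):
        return cls(
            np.zeros((n_signals,) + lattice.node_shape + (3,)), lattice, level
        )

    def cpg_at(self, surrogate_row: np.ndarray) -> ControlPointGrid:
        """M_t = sum_i S_it C_i as a control-point grid (linear in both args)."""
        s = np.asarray(surrogate_row, dtype=np.float64)
        if s.shape != (self.n_signals,):
            raise ValueError(
                f"surrogate row has length {s.size}, model expects {self.n_signals}"
            )
        m = np.tensordot(s, self.components, axes=(0, 0))
        return ControlPointGrid(
            m, self.lattice.node_spacing.copy(), self.lattice.node_origin.copy()
        )

    def dvf_at(self, surrogate_row: np.ndarray, grid: Volume3D) -> np.ndarray:
        """Dense displacement field (mm) for one surrogate row on ``grid``."""
        return ffd_to_dvf(self.cpg_at(surrogate_row), grid)

    def dvf_for_frame(self, t: int, surrogates: SurrogateMatrix, grid: Volume3D) -> np.ndarray:
        return self.dvf_at(surrogates.row(t), grid)


def model_cpg_at_time(model: CorrespondenceModel, surrogate_row: np.ndarray) -> ControlPointGrid:
    """Functional alias for :meth:`CorrespondenceModel.cpg_at`."""
    return model.cpg_at(surrogate_row)


# ---------------------------------------------------------------------------
# Subsets
# ---------------------------------------------------------------------------


def subset_indices(n_t: int, fraction: float, offset: int) -> np.ndarray:
    """Evenly spaced frame indices starting at ``offset``.

    With fraction 1/k, the offsets 0..k-1 partition all frames into disjoint
    subsets of near-equal size.
    """
    if not 0 < fraction <= 1:
        raise ValueError("subset fraction must lie in (0, 1]")
    stride = int(round(1.0 / fraction))
    if not 0 <= offset < stride:
        raise ValueError(f"offset must lie in [0, {stride})")
    return np.arange(offset, n_t, stride)


# ---------------------------------------------------------------------------
# Loss and gradient
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Hyperparameters of the alternating fit / MC-FDK schedule.

    Defaults follow the published protocol: control grid spacing of 8 level
    voxels, at most 6 motion-compensated reconstructions per level, at most
    100 fitting iterations (subset gradient steps) per fit phase, evenly
    spaced one-tenth subsets, and resolution levels at 1/4 and 1/2 of
    native resolution.
    """

    levels: tuple[float, ...] = (0.25, 0.5)
    max_mcr_per_level: int = 6
    max_fit_iters: int = 100
    subset_fraction: float = 0.1
    grid_spacing_voxels: int = DEFAULT_GRID_SPACING_VOXELS
    lncc: LnccConfig = field(default_factory=LnccConfig)
    initial_update_mm: float = 5.0
    max_step_halvings: int = 20
    epoch_tol: float = 1e-5
    outer_tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subset_fraction <= 1:
            raise ValueError("subset_fraction must lie in (0, 1]")
        if list(self.levels) != sorted(self.levels) or len(set(self.levels)) != len(self.levels):
            raise ValueError("levels must be strictly increasing")
        if any(not 0 < f <= 1 for f in self.levels):
            raise ValueError("levels are fractions of native resolution in (0, 1]")


@dataclass
class _LevelProblem:
    """Everything needed to evaluate the loss at one resolution level."""

    grid: Volume3D  # level reconstruction grid (metadata)
    projs: ProjectionStack
    masks: np.ndarray  # (N_t, rows, cols) validity
    lncc_cfg: LnccConfig
    recon_cfg: ReconstructionConfig


def loss_and_gradient(
    model: CorrespondenceModel,
    I0: Volume3D,
    projs: ProjectionStack,
    surrogates: SurrogateMatrix,
    subset: np.ndarray,
    lncc_cfg: LnccConfig,
    masks: np.ndarray | None = None,
    want_gradient: bool = True,
):
    """Subset loss f = -sum_t LNCC(P_t, P'_t) and its exact gradient in C.

    The gradient is assembled per frame as
    ``-S_it * FFDadj( backproject(dLNCC/dP') * dI/dD )`` and accumulated into
    the matching component.  ``want_gradient=False`` skips the adjoint chain
    (the returned gradient is zero) for cheap line-search evaluations.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset is empty")
    if surrogates.n_frames != projs.n_frames:
        raise ValueError("surrogate matrix does not cover every frame")
    geom = projs.geometry
    grad = np.zeros_like(model.components)
    loss = 0.0
    for t in subset:
        s_row = surrogates.row(int(t))
        cpg = model.cpg_at(s_row)
        dvf = ffd_to_dvf(cpg, I0)
        I_t = warp_image(I0, dvf)
        Pp = forward_project(I_t, geom, int(t))
        mask = None if masks is None else masks[int(t)]
        value, gL = lncc_and_gradient(
            projs.frame(int(t)), Pp, lncc_cfg, mask, want_gradient
        )
        loss -= value
        if not want_gradient:
            continue
        gP = -gL  # d f / d P'
        v = back_project(gP, geom, int(t), I0).data  # d f / d I_t
        pos_grad = warp_position_gradient(I0, dvf)  # d I_t / d D
        voxel_field = v[..., None] * pos_grad
        node_grad = dvf_adjoint_to_cpg(voxel_field, cpg, I0)
        for i in range(model.n_signals):
            grad[i] += s_row[i] * node_grad
    return loss, grad


# ---------------------------------------------------------------------------
# Level construction
# ---------------------------------------------------------------------------


def _level_grid(full: Volume3D, factor: float) -> Volume3D:
    shape = tuple(int(math.ceil(n * factor)) for n in full.shape)
    spacing = full.spacing / factor
    return Volume3D(np.zeros(shape), spacing, full.origin.copy())


def _level_projections(projs: ProjectionStack, factor: float) -> ProjectionStack:
    k = int(round(1.0 / factor))
    if k == 1:
        return projs
    geom = projs.geometry.rescale_detector(k)
    data = block_reduce(projs.data, (1, k, k), np.mean)
    return ProjectionStack(data, geom)


def _build_level(
    projs: ProjectionStack, full_grid: Volume3D, factor: float, cfg: FitConfig
) -> _LevelProblem:
    grid = _level_grid(full_grid, factor)
    lprojs = _level_projections(projs, factor)
    masks = np.stack(
        [fov_validity_mask(grid, lprojs.geometry, t) for t in range(lprojs.n_frames)]
    )
    lncc_cfg = replace(cfg.lncc, sigma_px=max(cfg.lncc.sigma_px * factor, 1.0))
    recon_cfg = ReconstructionConfig(
        shape=grid.shape,
        spacing=tuple(grid.spacing),
        origin=tuple(grid.origin),
    )
    return _LevelProblem(grid, lprojs, masks, lncc_cfg, recon_cfg)


# ---------------------------------------------------------------------------
# Alternating fit / reconstruction schedule
# ---------------------------------------------------------------------------


def _gradient_step(
    model: CorrespondenceModel,
    I0: Volume3D,
    level: _LevelProblem,
    surrogates: SurrogateMatrix,
    subset: np.ndarray,
    cfg: FitConfig,
    loss: float,
    g: np.ndarray,
    step: float | None,
) -> tuple[float, bool]:
    """One backtracking gradient step on ``subset``.

    Starting from ``step`` (or a scale moving the largest node by
    ``initial_update_mm`` when None), halve until the subset loss decreases,
    then apply the update in place.  Returns the step to warm-start the next
    iteration (grown slightly after an immediate acceptance) and whether any
    update was accepted.
    """

    def loss_at(components: np.ndarray) -> float:
        trial = CorrespondenceModel(components, model.lattice, model.level)
        value, _ = loss_and_gradient(
            trial, I0, level.projs, surrogates, subset, level.lncc_cfg, level.masks,
            want_gradient=False,
        )
        return value

    gscale = float(np.max(np.abs(g)))
    if gscale == 0.0 or not np.isfinite(gscale):
        return 0.0 if step is None else step, False
    if step is None or step <= 0.0:
        step = cfg.initial_update_mm / gscale
    for attempt in range(cfg.max_step_halvings):
        trial = model.components - step * g
        trial_loss = loss_at(trial)
        if np.isfinite(trial_loss) and trial_loss < loss:
            model.components = trial
            if attempt == 0:
                step *= 1.5  # accepted immediately: probe a larger step next
            return step, True
        step *= 0.5
    return step, False


def fit_motion_model(
    projs: ProjectionStack,
    surrogates: SurrogateMatrix,
    cfg: FitConfig,
    full_grid: Volume3D | None = None,
):
    """Alternating model fitting and motion-compensated reconstruction.

    Per level: resample projections (and the model) to the level, reconstruct
    I_0 (standard FDK at the first level, MC-FDK with the carried-over model
    afterwards), then alternate stochastic-subset gradient descent on C with
    MC-FDK updates of I_0, at most ``max_mcr_per_level`` times.

    Returns ``(model, I0, log)`` where ``log`` is a DataFrame with one row
    per subset gradient step (phase "fit") or reconstruction (phase "recon"),
    recording step, level, mcr_iter, subset_offset and loss.
    """
    if full_grid is None:
        geom = projs.geometry
        n = geom.detector_cols
        iso_px = geom.detector_spacing[1] * geom.sid / geom.sdd
        full_grid = Volume3D.centered((n, n, n), iso_px)
    rng = np.random.default_rng(cfg.seed)
    stride = int(round(1.0 / cfg.subset_fraction))
    records: list[dict] = []
    model: CorrespondenceModel | None = None
    I0: Volume3D | None = None
    step_counter = 0

    for level_idx, factor in enumerate(cfg.levels, start=1):
        level = _build_level(projs, full_grid, factor, cfg)
        lattice = ControlPointGrid.covering(level.grid, cfg.grid_spacing_voxels)
        if model is None:
            model = CorrespondenceModel.zeros(lattice, surrogates.n_signals, factor)
            I0 = fdk_reconstruct(level.projs, level.recon_cfg)
        else:
            comps = []
            for i in range(model.n_signals):
                coarse = ControlPointGrid(
                    model.components[i], model.lattice.node_spacing, model.lattice.node_origin
                )
                comps.append(
                    refine_cpg(coarse, level.grid, cfg.grid_spacing_voxels).displacements
                )
            model = CorrespondenceModel(np.stack(comps), lattice, factor)
            I0 = _reconstruct(model, surrogates, level)
            records.append(_recon_record(step_counter, level_idx, 0))
        logger.info("level %d (factor %.3g): grid %s", level_idx, factor, level.grid.shape)

        step: float | None = None
        for mcr_iter in range(1, cfg.max_mcr_per_level + 1):
            epoch_means: list[float] = []
            any_accepted = False
            it = 0
            while it < cfg.max_fit_iters:
                offsets = rng.permutation(stride)
                epoch_losses: list[float] = []
                for offset in offsets:
                    subset = subset_indices(
                        level.projs.n_frames, cfg.subset_fraction, int(offset)
                    )
                    loss, g = loss_and_gradient(
                        model, I0, level.projs, surrogates, subset, level.lncc_cfg, level.masks
                    )
                    if not np.isfinite(loss):
                        raise RuntimeError(
                            f"fit diverged (non-finite loss) at level {level_idx}, "
                            f"mcr {mcr_iter}, iteration {it}"
                        )
                    step, accepted = _gradient_step(
                        model, I0, level, surrogates, subset, cfg, loss, g, step
                    )
                    any_accepted = any_accepted or accepted
                    step_counter += 1
                    it += 1
                    epoch_losses.append(loss)
                    records.append(
                        {
                            "step": step_counter,
                            "level": level_idx,
                            "mcr_iter": mcr_iter,
                            "subset_offset": int(offset),
                            "loss": loss,
                            "phase": "fit",
                        }
                    )
                    if it >= cfg.max_fit_iters:
                        break
                epoch_means.append(float(np.mean(epoch_losses)))
                # stop when two consecutive epochs improve the epoch-mean
                # loss by less than epoch_tol relative
                if len(epoch_means) >= 3:
                    scale = abs(epoch_means[-3]) + 1e-12
                    if (epoch_means[-3] - epoch_means[-1]) / scale < 2 * cfg.epoch_tol:
                        break

            I0 = _reconstruct(model, surrogates, level)
            records.append(_recon_record(step_counter, level_idx, mcr_iter))
            logger.info(
                "level %d mcr %d epoch-mean loss %.6g -> %.6g",
                level_idx, mcr_iter, epoch_means[0], epoch_means[-1],
            )
            # stop the level when a whole fit phase achieved essentially
            # no improvement
            if not any_accepted or (
                len(epoch_means) >= 2
                and (epoch_means[0] - epoch_means[-1]) / (abs(epoch_means[0]) + 1e-12)
                < cfg.outer_tol
            ):
                logger.info("level %d converged after %d reconstructions", level_idx, mcr_iter)
                break

    log = pd.DataFrame.from_records(records)
    return model, I0, log


def _reconstruct(
    model: CorrespondenceModel, surrogates: SurrogateMatrix, level: _LevelProblem
) -> Volume3D:
    return motion_compensated_fdk(
        level.projs,
        level.recon_cfg,
        lambda t, grid: model.dvf_for_frame(t, surrogates, grid),
    )


def _recon_record(step: int, level: int, mcr_iter: int) -> dict:
    return {
        "step": step,
        "level": level,
        "mcr_iter": mcr_iter,
        "subset_offset": -1,
        "loss": float("nan"),
        "phase": "recon",
    }


# ---------------------------------------------------------------------------
# Animation
# ---------------------------------------------------------------------------


def animate(
    I0: Volume3D,
    model: CorrespondenceModel,
    surrogates: SurrogateMatrix,
    frames: "list[int] | None" = None,
):
    """Warp the motion-compensated image to each frame's anatomical state.

    Yields ``(t, Volume3D)`` with frame t = I0 resampled through D_t.  Equal
    surrogate rows produce identical volumes.
    """
    idx = range(surrogates.n_frames) if frames is None else frames
    for t in idx:
        dvf = model.dvf_for_frame(int(t), surrogates, I0)
        yield int(t), warp_image(I0, dvf)


def phase_binned_volumes(
    I0: Volume3D,
    model: CorrespondenceModel,
    surrogates: SurrogateMatrix,
    n_bins: int = 8,
    bin_signal: int = 0,
):
    """Synthetic respiratory-phase volumes: animate with per-bin mean surrogates.

    Frames are binned on the amplitude of one surrogate column and I0 is
    warped with the average surrogate row of each bin.
    """
    s = surrogates.values[:, bin_signal]
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    volumes = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        sel = (s >= lo) & (s <= hi if b == n_bins - 1 else s < hi)
        if not sel.any():
            continue
        row = surrogates.values[sel].mean(axis=0)
        volumes.append(warp_image(I0, model.dvf_at(row, I0)))
    return volumes
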