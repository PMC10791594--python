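"""Evaluation metrics and the three-scenario comparison harness.

Metrics follow the standard repertoire for motion-model validation on
simulated scans:

* ``dvf_error`` (E_D, mm): mean L2 norm of the difference between estimated
  and ground-truth displacement fields over all frames and a volume of
  interest (the body within the reconstruction FOV).
* ``dice`` (DSC): Dice overlap of estimated vs ground-truth tumor masks,
  averaged over frames.
* ``centroid_error`` (E_center, mm): Euclidean distance between tumor mask
  centroids, averaged over frames.
* ``nrmse``: RMS image difference over the VOI, normalized to the maximum of
  the ground-truth image.
* ``ssim_volume``: mean structural similarity.

The harness compares three scenarios on one simulated scan: ``S_uncorr``
(zero motion everywhere, standard FDK, static tumor mask),
``S_truth_signals`` (model fitted with the traces that generated the
simulation) and ``S_IA`` (model fitted with the signal extracted from the
projections plus its temporal gradient).  For the model scenarios the
reference image pair is I0_est = MC-FDK with model motion vs I0_gt = MC-FDK
with ground-truth motion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .bspline import warp_image
from .fdk import ReconstructionConfig, fdk_reconstruct, motion_compensated_fdk
from .geometry import Volume3D
from .model import CorrespondenceModel, FitConfig, fit_motion_model
from .phantom import SimulationBundle
from .surrogate import SurrogateMatrix, Trace, ia_surrogates

logger = logging.getLogger(__name__)

SCENARIO_UNCORRECTED = "S_uncorr"
SCENARIO_TRUTH = "S_truth_signals"
SCENARIO_IA = "S_IA"


# ---------------------------------------------------------------------------
# Individual metrics
# ---------------------------------------------------------------------------


def dvf_error(est: list[np.ndarray], gt: list[np.ndarray], voi: np.ndarray) -> float:
    """Mean |D_est - D_gt| (mm) over frames and VOI voxels."""
    if len(est) != len(gt) or not est:
        raise ValueError("estimated and ground-truth DVF lists must match")
    voi = np.asarray(voi, dtype=bool)
    total = 0.0
    for d_est, d_gt in zip(est, gt):
        if d_est.shape != d_gt.shape or d_est.shape[:3] != voi.shape:
            raise ValueError("DVF grids do not match")
        diff = np.linalg.norm(d_est - d_gt, axis=-1)
        total += float(diff[voi].mean())
    return total / len(est)


def dice(est_masks: list[np.ndarray], gt_masks: list[np.ndarray]) -> float:
    """Dice similarity of binary masks, averaged over frames."""
    if len(est_masks) != len(gt_masks) or not est_masks:
        raise ValueError("mask lists must match")
    total = 0.0
    for a, b in zip(est_masks, gt_masks):
        a = np.asarray(a, dtype=bool)
        b = np.asarray(b, dtype=bool)
        denom = a.sum() + b.sum()
        if denom == 0:
            raise ValueError("empty masks at a frame")
        total += 2.0 * np.logical_and(a, b).sum() / denom
    return total / len(est_masks)


def mask_centroid(mask: np.ndarray, grid: Volume3D) -> np.ndarray:
    """World-coordinate centroid (mm) of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    idx = np.argwhere(mask).mean(axis=0)
    return grid.origin + idx * grid.spacing


def centroid_error(
    est_masks: list[np.ndarray], gt_masks: list[np.ndarray], grid: Volume3D
) -> float:
    """Mean Euclidean centroid distance (mm) over frames."""
    if len(est_masks) != len(gt_masks) or not est_masks:
        raise ValueError("mask lists must match")
    total = 0.0
    for a, b in zip(est_masks, gt_masks):
        total += float(np.linalg.norm(mask_centroid(a, grid) - mask_centroid(b, grid)))
    return total / len(est_masks)


def nrmse(est: Volume3D, gt: Volume3D, voi: np.ndarray) -> float:
    """RMS difference over the VOI normalized to max(gt)."""
    if not est.same_grid(gt):
        raise ValueError("grids do not match")
    voi = np.asarray(voi, dtype=bool)
    g = gt.filled(0.0)
    e = est.filled(0.0)
    gmax = float(np.nanmax(gt.data))
    if gmax <= 0:
        raise ValueError("ground-truth maximum must be positive")
    return float(np.sqrt(np.mean((e[voi] - g[voi]) ** 2)) / gmax)


def ssim_volume(est: Volume3D, gt: Volume3D, voi: np.ndarray | None = None) -> float:
    """Mean structural similarity with standard constants.

    With ``voi`` given, the SSIM map is averaged over those voxels only —
    consistent with the other metrics, which are averaged over the body
    within the reconstruction FOV.
    """
    if not est.same_grid(gt):
        raise ValueError("grids do not match")
    e = est.filled(0.0)
    g = gt.filled(0.0)
    rng = float(g.max() - g.min())
    if rng == 0:
        rng = 1.0
    mean_ssim, ssim_map = structural_similarity(e, g, data_range=rng, full=True)
    if voi is None:
        return float(mean_ssim)
    return float(ssim_map[np.asarray(voi, dtype=bool)].mean())


# ---------------------------------------------------------------------------
# Scenario harness
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Metric values and per-frame tumor-centroid series for one scenario."""

    scenario: str
    e_d: float
    dsc: float
    e_center: float
    nrmse: float
    ssim: float
    tumor_si_mm: list[float] = field(default_factory=list)
    tumor_ap_mm: list[float] = field(default_factory=list)
    tumor_si_gt_mm: list[float] = field(default_factory=list)
    tumor_ap_gt_mm: list[float] = field(default_factory=list)
    pearson_si: float = float("nan")
    pearson_ap: float = float("nan")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            return cls(**json.load(fh))

    def frame_series(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tumor_si_mm": self.tumor_si_mm,
                "tumor_ap_mm": self.tumor_ap_mm,
                "tumor_si_gt_mm": self.tumor_si_gt_mm,
                "tumor_ap_gt_mm": self.tumor_ap_gt_mm,
            }
        )


def body_voi(reference: Volume3D, threshold: float = 0.01) -> np.ndarray:
    """Body voxels (attenuation above threshold) inside the FOV cylinder."""
    return (reference.filled(0.0) > threshold) & reference.fov_mask()


def _estimated_masks_and_dvfs(
    sim: SimulationBundle,
    model: CorrespondenceModel | None,
    surrogates: SurrogateMatrix | None,
):
    """Per-frame estimated DVFs and tumor masks on the simulation grid."""
    grid = sim.reference
    n_t = sim.projections.n_frames
    dvfs: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for t in range(n_t):
        if model is None:
            dvf = np.zeros(grid.shape + (3,))
        else:
            dvf = model.dvf_for_frame(t, surrogates, grid)
        dvfs.append(dvf)
        if model is None:
            masks.append(sim.tumor_mask.data > 0.5)
        else:
            warped = warp_image(sim.tumor_mask, dvf)
            masks.append(warped.data > 0.5)
    return dvfs, masks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_scenario(
    sim: SimulationBundle,
    scenario: str,
    model: CorrespondenceModel | None,
    surrogates: SurrogateMatrix | None,
    recon_cfg: ReconstructionConfig | None = None,
    i0_gt: Volume3D | None = None,
) -> EvaluationReport:
    """All five metrics plus the per-frame tumor-centroid series.

    ``model is None`` denotes the uncorrected scenario (zero DVFs, static
    mask, standard FDK).  ``i0_gt`` (MC-FDK with ground-truth motion) can be
    passed in to avoid recomputation across scenarios.
    """
    grid = sim.reference
    if recon_cfg is None:
        recon_cfg = ReconstructionConfig(
            shape=grid.shape, spacing=tuple(grid.spacing), origin=tuple(grid.origin)
        )
    voi = body_voi(sim.reference)
    n_t = sim.projections.n_frames
    gt_dvfs = [sim.motion.dvf(t, grid) for t in range(n_t)]
    gt_masks = [sim.motion.tumor_mask(t, sim.tumor_mask).data > 0.5 for t in range(n_t)]
    est_dvfs, est_masks = _estimated_masks_and_dvfs(sim, model, surrogates)

    if i0_gt is None:
        i0_gt = motion_compensated_fdk(sim.projections, recon_cfg, gt_dvfs)
    if model is None:
        i0_est = fdk_reconstruct(sim.projections, recon_cfg)
    else:
        i0_est = motion_compensated_fdk(
            sim.projections, recon_cfg,
            lambda t, g: model.dvf_for_frame(t, surrogates, g),
        )

    ref_centroid = mask_centroid(sim.tumor_mask.data > 0.5, grid)
    si = np.array([mask_centroid(m, grid)[2] - ref_centroid[2] for m in est_masks])
    ap = np.array([mask_centroid(m, grid)[1] - ref_centroid[1] for m in est_masks])
    si_gt = np.array([mask_centroid(m, grid)[2] - ref_centroid[2] for m in gt_masks])
    ap_gt = np.array([mask_centroid(m, grid)[1] - ref_centroid[1] for m in gt_masks])

    return EvaluationReport(
        scenario=scenario,
        e_d=dvf_error(est_dvfs, gt_dvfs, voi),
        dsc=dice(est_masks, gt_masks),
        e_center=centroid_error(est_masks, gt_masks, grid),
        nrmse=nrmse(i0_est, i0_gt, voi),
        ssim=ssim_volume(i0_est, i0_gt, voi),
        tumor_si_mm=si.tolist(),
        tumor_ap_mm=ap.tolist(),
        tumor_si_gt_mm=si_gt.tolist(),
        tumor_ap_gt_mm=ap_gt.tolist(),
        pearson_si=_pearson(si, si_gt),
        pearson_ap=_pearson(ap, ap_gt),
    )


def truth_surrogates(sim: SimulationBundle) -> SurrogateMatrix:
    """The generating breathing traces, normalized, as surrogate signals."""
    tr = sim.traces
    return SurrogateMatrix.from_traces(
        [
            Trace(tr.s_diaphragm, tr.times, "diaphragm_si"),
            Trace(tr.s_chest, tr.times, "chest_ap"),
        ],
        normalize=True,
    )


def run_scenarios(
    sim: SimulationBundle,
    fit_cfg: FitConfig | None = None,
    scenarios: tuple[str, ...] = (SCENARIO_UNCORRECTED, SCENARIO_TRUTH, SCENARIO_IA),
    fitted: dict[str, tuple[CorrespondenceModel, SurrogateMatrix]] | None = None,
) -> dict[str, EvaluationReport]:
    """Fit (where needed) and evaluate the requested scenarios.

    Pre-fitted models may be supplied through ``fitted`` keyed by scenario
    name; otherwise the harness fits them with ``fit_cfg``.
    """
    fit_cfg = fit_cfg or FitConfig()
    fitted = dict(fitted or {})
    grid = sim.reference
    recon_cfg = ReconstructionConfig(
        shape=grid.shape, spacing=tuple(grid.spacing), origin=tuple(grid.origin)
    )
    n_t = sim.projections.n_frames
    i0_gt = motion_compensated_fdk(
        sim.projections, recon_cfg, [sim.motion.dvf(t, grid) for t in range(n_t)]
    )
    reports: dict[str, EvaluationReport] = {}
    for name in scenarios:
        if name == SCENARIO_UNCORRECTED:
            model, surrogates = None, None
        elif name in fitted:
            model, surrogates = fitted[name]
        elif name == SCENARIO_TRUTH:
            surrogates = truth_surrogates(sim)
            model, _, _ = fit_motion_model(sim.projections, surrogates, fit_cfg, grid)
        elif name == SCENARIO_IA:
            surrogates = ia_surrogates(sim.projections)
            model, _, _ = fit_motion_model(sim.projections, surrogates, fit_cfg, grid)
        else:
            raise ValueError(f"unknown scenario {name!r}")
        logger.info("evaluating scenario %s", name)
        reports[name] = evaluate_scenario(sim, name, model, surrogates, recon_cfg, i0_gt)
    return reports
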