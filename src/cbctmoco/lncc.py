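"""Localized normalized cross-correlation (LNCC) and its analytic gradient.

LNCC scores the agreement of a measured and an estimated projection through
Gaussian-windowed local statistics, making it invariant to intensity maps that
are affine within each window — the property that lets projection-domain model
fitting survive the intensity mismatch between measured and simulated
projections on real scanners.

Local means, variances and the covariance are computed with a Gaussian window
restricted to the validity mask (normalized convolution), so pixels whose
rays leave the reconstruction FOV influence neither the value nor the
gradient.  Windows with no texture in the *measured* image (local variance at
or below the floor) carry no correlation information and are excluded from
the mean — flat background would otherwise read as zero correlation even for
a perfect match and its near-zero variances would dominate the gradient.
Because that exclusion depends only on the measured image, the loss remains a
smooth function of the estimated projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter


@dataclass
class LnccConfig:
    """Gaussian window standard deviation (pixels) and variance floor.

    Both thresholds are relative to the squared dynamic range of the
    measured image: ``variance_floor_rel`` guards the denominators, while
    ``texture_rel`` (local standard deviation of at least 1% of the range by
    default) decides which windows carry enough texture to enter the mean.
    """

    sigma_px: float = 5.0
    variance_floor_rel: float = 1e-6
    texture_rel: float = 1e-4

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("window sigma must be positive")
        if self.variance_floor_rel <= 0:
            raise ValueError("variance floor must be positive")
        if self.texture_rel < self.variance_floor_rel:
            raise ValueError("texture threshold must not undercut the variance floor")

    def floor(self, reference: np.ndarray) -> float:
        rng = float(np.max(reference) - np.min(reference))
        if rng == 0.0:
            rng = 1.0
        return self.variance_floor_rel * rng * rng

    def texture_threshold(self, reference: np.ndarray) -> float:
        rng = float(np.max(reference) - np.min(reference))
        if rng == 0.0:
            rng = 1.0
        return self.texture_rel * rng * rng


def _local_stats(P: np.ndarray, Pp: np.ndarray, mask: np.ndarray, cfg: LnccConfig):
    m = mask.astype(np.float64)
    sig = cfg.sigma_px
    W = gaussian_filter(m, sig, mode="constant")
    W = np.maximum(W, 1e-12)
    mu_p = gaussian_filter(m * P, sig, mode="constant") / W
    mu_q = gaussian_filter(m * Pp, sig, mode="constant") / W
    s_pp = gaussian_filter(m * P * P, sig, mode="constant") / W - mu_p**2
    s_qq = gaussian_filter(m * Pp * Pp, sig, mode="constant") / W - mu_q**2
    s_pq = gaussian_filter(m * P * Pp, sig, mode="constant") / W - mu_p * mu_q
    return W, mu_p, mu_q, s_pp, s_qq, s_pq


def _check(P: np.ndarray, Pp: np.ndarray, mask: np.ndarray | None):
    P = np.asarray(P, dtype=np.float64)
    Pp = np.asarray(Pp, dtype=np.float64)
    if P.shape != Pp.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Pp.shape}")
    if mask is None:
        mask = np.ones(P.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != P.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("validity mask is empty")
    return P, Pp, mask


def lncc(P: np.ndarray, Pp: np.ndarray, cfg: LnccConfig, mask: np.ndarray | None = None) -> float:
    """Mean windowed correlation over valid, textured pixels; in [-1, 1].

    Returns 0.0 when the measured image has no textured window at all (a
    blank frame carries no correlation information).
    """
    value, _ = lncc_and_gradient(P, Pp, cfg, mask, want_gradient=False)
    return value


def lncc_and_gradient(
    P: np.ndarray,
    Pp: np.ndarray,
    cfg: LnccConfig,
    mask: np.ndarray | None = None,
    want_gradient: bool = True,
):
    """LNCC value and its analytic gradient with respect to ``Pp``.

    The gradient accounts for the masked normalized convolution and for the
    variance floor on the estimated image (windows floored there contribute
    no variance derivative).  Masked-out pixels receive an exactly zero
    gradient.
    """
    P, Pp, mask = _check(P, Pp, mask)
    W, mu_p, mu_q, s_pp, s_qq, s_pq = _local_stats(P, Pp, mask, cfg)
    floor = cfg.floor(P)
    textured = mask & (s_pp > cfg.texture_threshold(P))
    if not textured.any():
        return 0.0, np.zeros_like(Pp)
    s_qq_f = np.maximum(s_qq, floor)
    s = np.sqrt(np.maximum(s_pp, floor) * s_qq_f)
    cc = s_pq / s
    n_valid = int(textured.sum())
    value = float(np.mean(cc[textured]))
    if not want_gradient:
        return value, np.zeros_like(Pp)

    m_weight = textured.astype(np.float64) / n_valid
    active = (s_qq > floor).astype(np.float64)
    alpha = m_weight / (W * s)
    beta = m_weight * cc * active / (W * s_qq_f)
    sig = cfg.sigma_px
    g = (
        P * gaussian_filter(alpha, sig, mode="constant")
        - gaussian_filter(alpha * mu_p, sig, mode="constant")
        - Pp * gaussian_filter(beta, sig, mode="constant")
        + gaussian_filter(beta * mu_q, sig, mode="constant")
    )
    g = np.where(mask, g, 0.0)
    return value, g


def lncc_gradient(
    P: np.ndarray, Pp: np.ndarray, cfg: LnccConfig, mask: np.ndarray | None = None
) -> np.ndarray:
    """Gradient of :func:`lncc` with respect to each pixel of ``Pp``."""
    return lncc_and_gradient(P, Pp, cfg, mask)[1]
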