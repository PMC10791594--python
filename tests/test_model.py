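"""Correspondence model, subsets, the assembled gradient chain, animation."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cbctmoco import (
    ProjectionStack,
    SurrogateMatrix,
    Volume3D,
    forward_project,
    warp_image,
)
from cbctmoco.bspline import ControlPointGrid
from cbctmoco.geometry import fov_validity_mask
from cbctmoco.lncc import LnccConfig
from cbctmoco.model import (
    CorrespondenceModel,
    FitConfig,
    animate,
    loss_and_gradient,
    model_cpg_at_time,
    phase_binned_volumes,
    subset_indices,
)

from conftest import make_geometry


@pytest.fixture
def lattice(small_grid):
    return ControlPointGrid.covering(small_grid, spacing_voxels=4)


@pytest.fixture
def model(lattice, rng):
    comps = rng.uniform(-2, 2, (2,) + lattice.node_shape + (3,))
    return CorrespondenceModel(comps, lattice)


class TestCorrespondenceModel:
    def test_zero_components_give_zero_grid(self, lattice):
        model = CorrespondenceModel.zeros(lattice, 2)
        out = model_cpg_at_time(model, np.array([0.7, -1.3]))
        assert np.all(out.displacements == 0.0)

    def test_basis_vector_selects_component(self, model):
        out = model_cpg_at_time(model, np.array([1.0, 0.0]))
        np.testing.assert_array_equal(out.displacements, model.components[0])

    def test_bilinearity(self, model, rng):
        s1 = rng.standard_normal(2)
        s2 = rng.standard_normal(2)
        a, b = 1.7, -0.4
        combo = model_cpg_at_time(model, a * s1 + b * s2).displacements
        parts = (
            a * model_cpg_at_time(model, s1).displacements
            + b * model_cpg_at_time(model, s2).displacements
        )
        np.testing.assert_allclose(combo, parts, atol=1e-12)

    def test_row_length_checked(self, model):
        with pytest.raises(ValueError):
            model.cpg_at(np.array([1.0, 0.0, 0.0]))


class TestSubsetIndices:
    def test_published_sampling_pattern(self):
        idx = subset_indices(310, 1.0 / 10.0, 0)
        np.testing.assert_array_equal(idx, np.arange(0, 310, 10))
        assert idx.size == 31

    def test_full_fraction_returns_all(self):
        np.testing.assert_array_equal(subset_indices(17, 1.0, 0), np.arange(17))

    def test_offsets_partition_all_frames(self):
        parts = [subset_indices(310, 0.1, off) for off in range(10)]
        merged = np.sort(np.concatenate(parts))
        np.testing.assert_array_equal(merged, np.arange(310))
        assert sum(p.size for p in parts) == 310

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            subset_indices(10, 0.0, 0)
        with pytest.raises(ValueError):
            subset_indices(10, 1.5, 0)


def tiny_problem(rng, n=16, spacing=8.0, n_frames=3, cp_spacing=4):
    grid = Volume3D.centered((n, n, n), spacing)
    x, y, z = grid.world_coordinates()
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    envelope = np.exp(-((X / 40) ** 2 + (Y / 40) ** 2 + (Z / 40) ** 2))
    I0 = grid.like(
        0.02 * envelope * (1.0 + gaussian_filter(rng.standard_normal((n, n, n)), 2.0))
    )
    geom = make_geometry(
        n_det=n, px=409.6 / n, angles=np.arange(n_frames) * (360.0 / n_frames)
    )
    lattice = ControlPointGrid.covering(grid, cp_spacing)
    surr = SurrogateMatrix(rng.standard_normal((n_frames, 2)))
    true_model = CorrespondenceModel(
        rng.uniform(-3, 3, (2,) + lattice.node_shape + (3,)), lattice
    )
    frames = [
        forward_project(
            warp_image(I0, true_model.dvf_for_frame(t, surr, grid)), geom, t
        )
        for t in range(n_frames)
    ]
    projs = ProjectionStack(np.stack(frames), geom)
    masks = np.stack([fov_validity_mask(grid, geom, t) for t in range(n_frames)])
    return grid, I0, geom, lattice, surr, projs, masks


class TestLossAndGradient:
    def test_perfect_model_sits_at_the_optimum(self, rng):
        # static scan, exact reference, zero motion model: every LNCC is at
        # its maximum of 1, so the loss equals -len(subset) and the gradient
        # vanishes
        grid, I0, geom, lattice, surr, projs, masks = tiny_problem(rng)
        static = ProjectionStack(
            np.stack([forward_project(I0, geom, t) for t in range(3)]), geom
        )
        model = CorrespondenceModel.zeros(lattice, 2)
        loss, g = loss_and_gradient(
            model, I0, static, surr, np.arange(3), LnccConfig(sigma_px=2.0), masks
        )
        assert loss == pytest.approx(-3.0, abs=1e-6)
        assert np.abs(g).max() < 1e-5

    def test_gradient_matches_finite_differences(self, rng):
        grid, I0, geom, lattice, surr, projs, masks = tiny_problem(rng)
        cfg = LnccConfig(sigma_px=2.0)
        model = CorrespondenceModel(
            rng.uniform(-2, 2, (2,) + lattice.node_shape + (3,)), lattice
        )
        subset = np.arange(3)
        loss, g = loss_and_gradient(model, I0, projs, surr, subset, cfg, masks)
        gmax = np.abs(g).max()
        h = 1e-3
        sample = rng.integers(0, np.array(g.shape), size=(40, 5))
        for idx in map(tuple, sample):
            cp = model.components.copy()
            cm = model.components.copy()
            cp[idx] += h
            cm[idx] -= h
            lp, _ = loss_and_gradient(
                CorrespondenceModel(cp, lattice), I0, projs, surr, subset, cfg, masks
            )
            lm, _ = loss_and_gradient(
                CorrespondenceModel(cm, lattice), I0, projs, surr, subset, cfg, masks
            )
            fd = (lp - lm) / (2 * h)
            assert abs(fd - g[idx]) <= 1e-3 * gmax

    def test_surrogate_column_scaling_scales_gradient(self, rng):
        # at C = 0 the transport terms are fixed, so doubling one surrogate
        # column exactly doubles that component's gradient
        grid, I0, geom, lattice, surr, projs, masks = tiny_problem(rng)
        cfg = LnccConfig(sigma_px=2.0)
        model = CorrespondenceModel.zeros(lattice, 2)
        _, g1 = loss_and_gradient(model, I0, projs, surr, np.arange(3), cfg, masks)
        doubled = SurrogateMatrix(surr.values * np.array([2.0, 1.0]))
        _, g2 = loss_and_gradient(model, I0, projs, doubled, np.arange(3), cfg, masks)
        np.testing.assert_allclose(g2[0], 2.0 * g1[0], rtol=1e-10)
        np.testing.assert_allclose(g2[1], g1[1], rtol=1e-10)

    def test_empty_subset_rejected(self, rng):
        grid, I0, geom, lattice, surr, projs, masks = tiny_problem(rng)
        model = CorrespondenceModel.zeros(lattice, 2)
        with pytest.raises(ValueError):
            loss_and_gradient(
                model, I0, projs, surr, np.array([]), LnccConfig(sigma_px=2.0), masks
            )


class TestFitConfig:
    def test_levels_must_increase(self):
        with pytest.raises(ValueError):
            FitConfig(levels=(0.5, 0.25))

    def test_subset_fraction_bounds(self):
        with pytest.raises(ValueError):
            FitConfig(subset_fraction=0.0)


class TestAnimate:
    def test_zero_model_returns_reference_every_frame(self, rng, small_grid, lattice):
        I0 = small_grid.like(rng.random(small_grid.shape))
        model = CorrespondenceModel.zeros(lattice, 2)
        surr = SurrogateMatrix(rng.standard_normal((4, 2)))
        for _, vol in animate(I0, model, surr):
            np.testing.assert_array_equal(vol.data, I0.data)

    def test_equal_surrogate_rows_give_identical_volumes(self, rng, small_grid, lattice):
        I0 = small_grid.like(rng.random(small_grid.shape))
        comps = rng.uniform(-1, 1, (2,) + lattice.node_shape + (3,))
        model = CorrespondenceModel(comps, lattice)
        rows = np.array([[0.5, -0.2], [0.1, 0.9], [0.5, -0.2]])
        surr = SurrogateMatrix(rows)
        vols = dict(animate(I0, model, surr))
        np.testing.assert_array_equal(vols[0].data, vols[2].data)
        assert not np.array_equal(vols[0].data, vols[1].data)

    def test_phase_binning_produces_volumes(self, rng, small_grid, lattice):
        I0 = small_grid.like(rng.random(small_grid.shape))
        comps = rng.uniform(-1, 1, (2,) + lattice.node_shape + (3,))
        model = CorrespondenceModel(comps, lattice)
        s = np.sin(np.linspace(0, 6 * np.pi, 40))
        surr = SurrogateMatrix(np.stack([s, np.cos(np.linspace(0, 6 * np.pi, 40))], axis=1))
        vols = phase_binned_volumes(I0, model, surr, n_bins=4)
        assert 1 <= len(vols) <= 4
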