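"""FFD transform: basis evaluation, adjoints, warping, inversion, refinement."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cbctmoco import Volume3D
from cbctmoco.bspline import (
    ControlPointGrid,
    cubic_bspline_weights,
    dvf_adjoint_to_cpg,
    ffd_to_dvf,
    invert_dvf,
    refine_cpg,
    warp_image,
    warp_position_gradient,
    _sample_vector_field,
)


@pytest.fixture
def grid():
    return Volume3D.centered((20, 20, 20), 2.0)


@pytest.fixture
def cpg(grid):
    return ControlPointGrid.covering(grid, spacing_voxels=4)


class TestFfdToDvf:
    def test_zero_displacements_give_zero_dvf(self, grid, cpg):
        assert np.all(ffd_to_dvf(cpg, grid) == 0.0)

    def test_partition_of_unity(self, grid, cpg):
        v = np.array([1.7, -0.3, 2.5])
        cpg.displacements[...] = v
        dvf = ffd_to_dvf(cpg, grid)
        assert np.abs(dvf - v).max() < 1e-6

    def test_single_node_matches_tensor_product_basis(self, grid, cpg):
        cpg.displacements[4, 4, 4, 0] = 1.0
        dvf = ffd_to_dvf(cpg, grid)
        # direct per-point oracle from the 1-D basis
        for vox in [(3, 7, 11), (8, 8, 8), (14, 2, 5)]:
            u = [
                (grid.origin[a] + vox[a] * grid.spacing[a] - cpg.node_origin[a])
                / cpg.node_spacing[a]
                for a in range(3)
            ]
            expected = 1.0
            for a in range(3):
                base = int(np.floor(u[a]))
                w = cubic_bspline_weights(u[a] - base)
                offset = 4 - (base - 1)  # index of node 4 within the stencil
                expected *= w[offset] if 0 <= offset < 4 else 0.0
            assert dvf[vox + (0,)] == pytest.approx(expected, rel=1e-6, abs=1e-12)

    def test_linearity_in_node_displacements(self, grid, cpg, rng):
        a = rng.standard_normal(cpg.node_shape + (3,))
        b = rng.standard_normal(cpg.node_shape + (3,))
        ca = ControlPointGrid(a, cpg.node_spacing, cpg.node_origin)
        cb = ControlPointGrid(b, cpg.node_spacing, cpg.node_origin)
        cab = ControlPointGrid(2 * a - 3 * b, cpg.node_spacing, cpg.node_origin)
        np.testing.assert_allclose(
            ffd_to_dvf(cab, grid),
            2 * ffd_to_dvf(ca, grid) - 3 * ffd_to_dvf(cb, grid),
            atol=1e-12,
        )

    def test_insufficient_coverage_rejected(self, grid):
        small = ControlPointGrid(
            np.zeros((3, 3, 3, 3)), grid.spacing * 4, grid.origin.copy()
        )
        with pytest.raises(ValueError):
            ffd_to_dvf(small, grid)


class TestDvfAdjoint:
    def test_zero_field_gives_zero_gradient(self, grid, cpg):
        out = dvf_adjoint_to_cpg(np.zeros(grid.shape + (3,)), cpg, grid)
        assert np.all(out == 0.0)

    def test_adjoint_identity(self, grid, cpg, rng):
        M = rng.standard_normal(cpg.node_shape + (3,))
        g = rng.standard_normal(grid.shape + (3,))
        cm = ControlPointGrid(M, cpg.node_spacing, cpg.node_origin)
        lhs = np.sum(ffd_to_dvf(cm, grid) * g)
        rhs = np.sum(M * dvf_adjoint_to_cpg(g, cpg, grid))
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_constant_field_gives_equal_interior_node_gradients(self):
        big = Volume3D.centered((32, 32, 32), 2.0)
        lattice = ControlPointGrid.covering(big, spacing_voxels=4)
        g = np.ones(big.shape + (3,))
        out = dvf_adjoint_to_cpg(g, lattice, big)
        # nodes whose full cubic support lies inside the image
        interior = out[3:7, 3:7, 3:7, 0]
        assert interior.std() / interior.mean() < 1e-6


class TestWarpImage:
    def test_zero_dvf_is_identity(self, grid, rng):
        vol = grid.like(rng.standard_normal(grid.shape))
        out = warp_image(vol, np.zeros(grid.shape + (3,)))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_one_voxel_shift(self, grid, rng):
        vol = grid.like(rng.standard_normal(grid.shape))
        dvf = np.zeros(grid.shape + (3,))
        dvf[..., 0] = grid.spacing[0]
        out = warp_image(vol, dvf)
        np.testing.assert_allclose(out.data[:-1], vol.data[1:], atol=1e-12)

    def test_inverse_round_trip(self, grid, rng):
        img = gaussian_filter(rng.standard_normal(grid.shape), 3.0)
        vol = grid.like(img)
        x, y, z = np.meshgrid(*grid.world_coordinates(), indexing="ij")
        dvf = np.zeros(grid.shape + (3,))
        dvf[..., 0] = 6.0 * np.exp(-(x**2 + y**2 + z**2) / (2 * 10.0**2))
        inv = invert_dvf(dvf, grid.spacing)
        once = warp_image(vol, dvf)
        back = warp_image(once, inv)
        interior = (slice(4, -4),) * 3
        dyn = img.max() - img.min()
        assert np.abs(back.data[interior] - img[interior]).max() < 0.02 * dyn

    def test_grid_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            warp_image(grid, np.zeros((4, 4, 4, 3)))


class TestWarpPositionGradient:
    def test_constant_image_gives_zero(self, grid):
        vol = grid.like(np.full(grid.shape, 3.0))
        g = warp_position_gradient(vol, np.zeros(grid.shape + (3,)))
        assert np.abs(g[2:-2, 2:-2, 2:-2]).max() < 1e-12

    def test_linear_ramp_gradient_is_exact(self, grid, rng):
        x = grid.world_coordinates()[0]
        vol = grid.like(np.broadcast_to(x[:, None, None], grid.shape).copy())
        dvf = rng.uniform(-3, 3, grid.shape + (3,))
        g = warp_position_gradient(vol, dvf)
        interior = (slice(3, -3),) * 3
        np.testing.assert_allclose(g[interior + (0,)], 1.0, atol=1e-9)
        np.testing.assert_allclose(g[interior + (1,)], 0.0, atol=1e-9)

    def test_matches_finite_differences_of_warp(self, grid, rng):
        # the definitive consistency check: the returned field is the exact
        # derivative of warp_image with respect to the displacement
        vol = grid.like(gaussian_filter(rng.standard_normal(grid.shape), 1.5))
        dvf = rng.uniform(-3, 3, grid.shape + (3,))
        g = warp_position_gradient(vol, dvf)
        h = 1e-5
        for ax in range(3):
            dp, dm = dvf.copy(), dvf.copy()
            dp[..., ax] += h
            dm[..., ax] -= h
            fd = (warp_image(vol, dp).data - warp_image(vol, dm).data) / (2 * h)
            assert np.abs(fd - g[..., ax]).max() < 1e-7


class TestInvertDvf:
    def test_zero_field_inverts_to_zero(self, grid):
        inv = invert_dvf(np.zeros(grid.shape + (3,)), grid.spacing)
        assert np.all(inv == 0.0)

    def test_composition_is_identity(self, grid):
        x, y, z = np.meshgrid(*grid.world_coordinates(), indexing="ij")
        dvf = np.zeros(grid.shape + (3,))
        dvf[..., 2] = 4.0 * np.exp(-(x**2 + y**2 + z**2) / (2 * 12.0**2))
        inv = invert_dvf(dvf, grid.spacing)
        sampled = np.zeros_like(dvf)
        _sample_vector_field(dvf, grid.spacing, inv, sampled)
        residual = np.abs(inv + sampled)
        assert residual.mean() < 0.05  # mm


class TestRefinement:
    def test_refined_lattice_preserves_deformation(self, rng):
        coarse_grid = Volume3D.centered((16, 16, 16), 4.0)
        fine_grid = Volume3D(
            np.zeros((32, 32, 32)), coarse_grid.spacing / 2, coarse_grid.origin.copy()
        )
        cpg = ControlPointGrid.covering(coarse_grid, 8)
        cpg.displacements[:] = gaussian_filter(
            rng.standard_normal(cpg.node_shape + (3,)), (1, 1, 1, 0)
        )
        fine = refine_cpg(cpg, fine_grid, 8)
        probe = Volume3D.centered((10, 10, 10), 4.0)  # interior region
        d_coarse = ffd_to_dvf(cpg, probe)
        d_fine = ffd_to_dvf(fine, probe)
        scale = np.abs(d_coarse).max()
        assert np.abs(d_fine - d_coarse).max() < 0.02 * scale
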