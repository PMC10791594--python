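"""Phantom generator: anatomy, breathing traces, ground-truth motion, scans."""

import numpy as np
import pytest

from cbctmoco import (
    PhantomSpec,
    forward_project,
    make_breathing_traces,
    make_gt_motion,
    make_reference_phantom,
    simulate_scan,
    warp_image,
)
from cbctmoco.phantom import (
    FULL_RES_SHAPE,
    _si_envelope,
    default_geometry,
    min_jacobian_det,
    simulate_study,
)


@pytest.fixture(scope="module")
def spec():
    return PhantomSpec(shape=(64, 64, 64), spacing=4.0)


@pytest.fixture(scope="module")
def phantom(spec):
    return make_reference_phantom(spec)


class TestReferencePhantom:
    def test_tumor_mask_volume_matches_sphere(self, spec, phantom):
        _, mask = phantom
        count = mask.data.sum()
        expected = 4.0 / 3.0 * np.pi * spec.tumor_radius**3 / np.prod(spec.spacing**3 * np.ones(1))
        vox_vol = float(np.prod(np.full(3, spec.spacing)))
        expected = 4.0 / 3.0 * np.pi * spec.tumor_radius**3 / vox_vol
        assert abs(count - expected) / expected < 0.05

    def test_attenuation_bounds(self, phantom):
        vol, _ = phantom
        assert vol.data.min() >= 0.0
        assert vol.data.max() <= 0.05

    def test_full_resolution_grid_shape(self):
        full = PhantomSpec(shape=FULL_RES_SHAPE, spacing=1.0)
        assert full.grid().shape == (375, 375, 343)

    def test_tumor_outside_lung_rejected(self):
        bad = PhantomSpec(tumor_center=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            make_reference_phantom(bad)


class TestBreathingTraces:
    def test_regular_traces_are_in_phase(self):
        tr = make_breathing_traces("regular", 310, 5.4, seed=0)
        r = np.corrcoef(tr.s_diaphragm, tr.s_chest)[0, 1]
        assert r > 0.99

    def test_quadrature_offset_decorrelates_traces(self):
        tr = make_breathing_traces("irregular", 310, 5.4, seed=0, phase_offset_deg=90.0)
        # restrict to whole cycles (period 4 s)
        n = int(np.floor(tr.times[-1] / 4.0) * 4.0 * 5.4)
        r = np.corrcoef(tr.s_diaphragm[:n], tr.s_chest[:n])[0, 1]
        assert abs(r) < 0.3

    def test_irregular_traces_lag_and_vary(self):
        tr = make_breathing_traces("irregular", 310, 5.4, seed=0)
        assert tr.phase_offset_deg > 0.0
        assert tr.cycle_variability > 0.0
        # hysteresis: correlated but clearly less than the regular regime
        r = np.corrcoef(tr.s_diaphragm, tr.s_chest)[0, 1]
        assert r < 0.95

    def test_default_duration_near_one_minute(self):
        tr = make_breathing_traces("regular")
        assert tr.times[-1] == pytest.approx(309 / 5.4)
        assert 56.0 < tr.times[-1] < 58.0

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            make_breathing_traces("chaotic", 10, 5.4)

    def test_irregular_is_seeded(self):
        a = make_breathing_traces("irregular", 100, 5.4, seed=7)
        b = make_breathing_traces("irregular", 100, 5.4, seed=7)
        c = make_breathing_traces("irregular", 100, 5.4, seed=8)
        np.testing.assert_array_equal(a.s_diaphragm, b.s_diaphragm)
        assert not np.array_equal(a.s_diaphragm, c.s_diaphragm)


@pytest.fixture(scope="module")
def motion(spec):
    traces = make_breathing_traces("irregular", 40, 5.4, seed=3)
    return make_gt_motion(traces, spec)


class TestGroundTruthMotion:

    def test_zero_signal_frame_has_zero_dvf(self, spec):
        traces = make_breathing_traces("regular", 40, 5.4, seed=0)
        traces.s_diaphragm[5] = 0.0
        traces.s_chest[5] = 0.0
        motion = make_gt_motion(traces, spec)
        assert np.all(motion.dvf(5, spec.grid()) == 0.0)

    def test_jacobian_stays_positive(self, spec, motion):
        grid = spec.grid()
        worst = min(
            min_jacobian_det(motion.dvf(t, grid), grid.spacing)
            for t in range(0, motion.n_frames, 8)
        )
        assert worst > 0.2

    def test_tumor_center_tracks_diaphragm_signal(self, spec, motion):
        grid = spec.grid()
        tc = np.asarray(spec.tumor_center)
        w = _si_envelope(*tc)
        for t in (3, 17, 31):
            d = motion.dvf(t, grid)
            idx = tuple(np.round((tc - grid.origin) / grid.spacing).astype(int))
            expected = motion.traces.s_diaphragm[t] * w
            # the coarse node lattice smooths the envelope, so agreement is
            # at the B-spline approximation level
            assert d[idx + (2,)] == pytest.approx(expected, abs=0.35 * abs(expected) + 0.1)

    def test_analytic_mechanism_matches_envelopes(self, spec):
        traces = make_breathing_traces("regular", 20, 5.4)
        motion = make_gt_motion(traces, spec, mechanism="analytic")
        grid = spec.grid()
        d = motion.dvf(7, grid)
        idx = (32, 32, 16)
        pos = grid.origin + np.array(idx) * grid.spacing
        assert d[idx + (2,)] == pytest.approx(
            traces.s_diaphragm[7] * _si_envelope(*pos), rel=1e-9
        )


class TestSimulateScan:
    def test_zero_motion_matches_static_projection(self, spec, phantom):
        vol, _ = phantom
        traces = make_breathing_traces("regular", 8, 5.4)
        traces.s_diaphragm[:] = 0.0
        traces.s_chest[:] = 0.0
        motion = make_gt_motion(traces, spec)
        geom = default_geometry(64, 8)
        projs = simulate_scan(vol, motion, geom)
        for t in (0, 5):
            np.testing.assert_array_equal(projs.frame(t), forward_project(vol, geom, t))

    def test_frames_compose_warp_then_project(self, spec, phantom):
        vol, _ = phantom
        traces = make_breathing_traces("regular", 6, 5.4)
        motion = make_gt_motion(traces, spec)
        geom = default_geometry(64, 6)
        projs = simulate_scan(vol, motion, geom)
        t = 2
        expected = forward_project(warp_image(vol, motion.dvf(t, vol)), geom, t)
        np.testing.assert_array_equal(projs.frame(t), expected)

    def test_default_geometry_is_elekta_like(self):
        geom = default_geometry(64)
        assert geom.sid == 1000.0
        assert geom.sdd == 1536.0
        assert geom.n_frames == 310
        assert geom.detector_spacing[0] * geom.detector_rows == pytest.approx(409.6)

    def test_frame_count_mismatch_rejected(self, spec, phantom):
        vol, _ = phantom
        traces = make_breathing_traces("regular", 6, 5.4)
        motion = make_gt_motion(traces, spec)
        with pytest.raises(ValueError):
            simulate_scan(vol, motion, default_geometry(64, 10))


class TestTumorMaskTracking:
    def test_warped_mask_tracks_warped_intensity(self):
        # texture-free phantom: inside the lung only the tumor exceeds the
        # threshold, so an intensity segmentation of the warped image is an
        # independent oracle for the warped mask
        spec = PhantomSpec(
            shape=(64, 64, 64), spacing=4.0, texture_amplitude=0.0,
            edge_smoothing_voxels=0.0,
        )
        sim = simulate_study(spec, regime="regular", n_frames=6, seed=2)
        grid = sim.reference
        coords = grid.world_coordinates()
        ox, oy, oz = spec.lung_offset
        lung = _ellipsoid_indicator(coords, (-ox, oy, oz), spec.lung_axes)
        dvf = sim.motion.dvf(1, grid)  # frame with clear displacement
        gt_mask = sim.motion.tumor_mask(1, sim.tumor_mask).data > 0.5
        warped_img = warp_image(grid, dvf)
        warped_lung = warp_image(grid.like(lung.astype(float)), dvf).data > 0.5
        thresh = (warped_img.data > 0.012) & warped_lung
        inter = np.logical_and(thresh, gt_mask).sum()
        dsc = 2 * inter / (thresh.sum() + gt_mask.sum())
        assert dsc > 0.9


def _ellipsoid_indicator(coords, center, axes):
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = axes
    return (
        ((x[:, None, None] - cx) / ax) ** 2
        + ((y[None, :, None] - cy) / ay) ** 2
        + ((z[None, None, :] - cz) / az) ** 2
    ) <= 1.0
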