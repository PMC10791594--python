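import numpy as np
import pytest

from cbctmoco import ScanGeometry, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """16^3 grid at 8 mm spacing centered on the isocenter."""
    return Volume3D.centered((16, 16, 16), 8.0)


def make_geometry(n_det=24, px=8.0, angles=(0.0,), fps=5.4, sid=1000.0, sdd=1536.0):
    angles = np.asarray(angles, dtype=float)
    return ScanGeometry(
        sid=sid,
        sdd=sdd,
        detector_rows=n_det,
        detector_cols=n_det,
        detector_spacing=(px, px),
        angles=angles,
        times=np.arange(angles.size) / fps,
    )


@pytest.fixture
def single_frame_geometry():
    return make_geometry()
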