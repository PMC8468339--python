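import numpy as np
import pytest

import mrisim as m


@pytest.fixture(scope="session")
def head_model():
    """Small head-like phantom shared by read-only tests."""
    return m.default_head_phantom(32, 6.0, seed=0)


@pytest.fixture()
def nested_ellipsoids():
    """Two nested homogeneous ellipsoids on a 64-voxel grid."""
    tissues = [
        m.TissueSpec("outer", 0.7, 900.0, 90.0,
                     {"type": "ellipsoid", "center": [0, 0, 0], "semi_axes": [80.0, 70.0, 60.0]}),
        m.TissueSpec("inner", 1.0, 4000.0, 2000.0,
                     {"type": "ellipsoid", "center": [0, 0, 0], "semi_axes": [35.0, 30.0, 25.0]}),
    ]
    return m.build_phantom(tissues, (64, 64, 64), (3.0, 3.0, 3.0), seed=1)


@pytest.fixture()
def unit_geometry():
    """Axial 128x128 single-slice plan with identity axes, 256 mm FOV."""
    return m.PlanGeometry(
        freq_axis=np.array([1.0, 0.0, 0.0]),
        phase_axis=np.array([0.0, 1.0, 0.0]),
        slice_axis=np.array([0.0, 0.0, 1.0]),
        fov_freq=256.0,
        fov_phase=256.0,
        matrix_freq=128,
        matrix_phase=128,
        slice_thickness=5.0,
        slice_separation=5.0,
        n_slices=1,
    )
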