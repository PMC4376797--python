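import numpy as np
import pytest

from lovofit import FrameCoordinates


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_frame(rng, n_atoms, scale=5.0):
    """Random non-degenerate frame with integer atom ids."""
    coords = rng.normal(size=(n_atoms, 3)) * scale
    return FrameCoordinates(coords, tuple(range(n_atoms)))


def random_rotation(rng):
    """Uniform random proper rotation (normalized Gaussian quaternion)."""
    q = rng.normal(size=4)
    q0, q1, q2, q3 = q / np.linalg.norm(q)
    return np.array(
        [
            [
                q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                2 * (q1 * q2 - q0 * q3),
                2 * (q1 * q3 + q0 * q2),
            ],
            [
                2 * (q1 * q2 + q0 * q3),
                q0 * q0 + q2 * q2 - q1 * q1 - q3 * q3,
                2 * (q2 * q3 - q0 * q1),
            ],
            [
                2 * (q1 * q3 - q0 * q2),
                2 * (q2 * q3 + q0 * q1),
                q0 * q0 + q3 * q3 - q1 * q1 - q2 * q2,
            ],
        ]
    )


def random_rigid_motion(rng, translation_scale=10.0):
    from lovofit import RigidTransform

    return RigidTransform(random_rotation(rng), rng.uniform(-1, 1, 3) * translation_scale)
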