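import numpy as np
import pytest

from taijikit.layout import JOINT_NAMES_32, skeleton_edges
from taijikit.skeleton import SkeletonSequence
from taijikit.synth import MotionSpec, generate_motion, random_unit_spec


def make_sequence(positions: np.ndarray, fps: float = 30.0) -> SkeletonSequence:
    """Wrap a raw (T, J, 3) array in a SkeletonSequence with generic names."""
    T, J = positions.shape[:2]
    names = (
        JOINT_NAMES_32 if J == 32 else tuple(f"j{i}" for i in range(J))
    )
    edges = tuple(skeleton_edges()) if J == 32 else ()
    return SkeletonSequence(
        positions=positions,
        confidence=np.ones((T, J)),
        fps=fps,
        joint_names=names,
        edges=edges,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_motion():
    """A 150-frame seeded movement unit used as a clean reference."""
    r = np.random.default_rng(5)
    spec = MotionSpec((random_unit_spec(r, 150, unit_id="u"),), seed=6)
    seq, _ = generate_motion(spec)
    return seq


@pytest.fixture(scope="session")
def camera_rig():
    from taijikit.synth import camera_ring

    return camera_ring()
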