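import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from porephys.gating_sim import SCHEMES, simulate_dwells
from porephys.synthetic_structures import IdealPoreSpec, build_ideal_pore

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ideal_pore():
    """Untilted pentameric Cα pore with the closed-state 9' ring radius."""
    return build_ideal_pore(IdealPoreSpec(ring_radius=6.84, helix_tilt=0.0))


@pytest.fixture(scope="session")
def tilted_pore():
    return build_ideal_pore(IdealPoreSpec(ring_radius=6.84, helix_tilt=5.0))


@pytest.fixture(scope="session")
def a1b3_events():
    """~10^4 open dwells from the low-Po scheme (ground truth)."""
    return simulate_dwells(SCHEMES["a1b3-like"], 170.0, seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=20.0, size=3)
    return R, t
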