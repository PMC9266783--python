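import numpy as np
import pytest

from confswitch import topology
from confswitch.synthetic import BundleSpec, MsaSpec, make_bundle, make_msa

FIXTURE_SEED = 7
STATE_NAMES = {
    "inward": "inward-open",
    "outward": "outward-open",
    "occluded": "occluded",
}


@pytest.fixture(scope="session")
def bundles():
    """Inward/outward/occluded bundles built from one seed (one protein)."""
    return {
        state: make_bundle(BundleSpec(state=state, seed=FIXTURE_SEED))
        for state in ("inward", "outward", "occluded")
    }


@pytest.fixture(scope="session")
def outward_topo(bundles):
    """Automatic annotation of the outward fixture."""
    return topology.annotate(bundles["outward"].structure)


@pytest.fixture(scope="session")
def default_msa():
    """The default planted-coupling alignment (500 rows, L=120, 5 pairs)."""
    return make_msa(MsaSpec(seed=FIXTURE_SEED))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.1, np.pi)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
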