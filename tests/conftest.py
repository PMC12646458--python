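import numpy as np
import pytest

from mechanokit import synth


@pytest.fixture(scope="session")
def planted_complex():
    """20+20-residue two-chain model with 10 planted contacts, no clashes."""
    s, manifest = synth.gen_complex(20, 20, 10, 90.0, 60.0, 0, seed=11)
    return s, manifest


@pytest.fixture(scope="session")
def clashed_complex():
    """100-heavy-atom model with exactly one planted non-bonded overlap."""
    s, manifest = synth.gen_complex(10, 10, 0, 90.0, 60.0, 1, seed=12)
    return s, manifest


@pytest.fixture(scope="session")
def membrane_traj():
    s, manifest = synth.gen_membrane_trajectory(n_frames=60, seed=13)
    return s, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
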