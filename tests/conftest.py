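import numpy as np
import pytest

import kinmap as km
from oracles import LUMP_MAP, T3, T_HIDDEN


@pytest.fixture(scope="session")
def chain3_labels():
    """300k-frame sample of the 3-state reference chain."""
    spec = km.ChainSpec(3, T3, np.ones(3) / 3, 300_000, seed=5)
    return km.sample_chain(spec)


@pytest.fixture(scope="session")
def lumped_labels():
    """Observed sequence of the lumped 4-state hidden chain (strong memory)."""
    hidden = km.ChainSpec(4, T_HIDDEN, np.array([1.0, 0, 0, 0]), 500_000, seed=7)
    return km.sample_lumped_chain(km.LumpingSpec(hidden, LUMP_MAP))


@pytest.fixture(scope="session")
def brownian_threewell():
    """30k-frame Brownian run on the three-well landscape, with core labels."""
    spec = km.LandscapeSpec.three_well(n_frames=30_000, seed=11)
    traj = km.simulate_brownian_2d(spec)
    labels = km.assign_states(traj, km.StateDefinition.folding_three_state())
    return spec, traj, labels


@pytest.fixture(scope="session")
def circle200():
    return km.sample_circle(200).data
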