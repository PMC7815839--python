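import numpy as np
import pytest

from nqekit.data import PermutationGroup
from nqekit.forcefield import GDML
from nqekit.potentials import MorseDimerPES, sample_training_set


@pytest.fixture(scope="session")
def morse_pes():
    return MorseDimerPES()


@pytest.fixture(scope="session")
def morse_dataset(morse_pes):
    """120 Boltzmann-sampled dimer configurations at 300 K (fixed seed)."""
    x0 = np.array([0.0, 0.0, 0.0, morse_pes.re, 0.0, 0.0])
    return sample_training_set(morse_pes, 300.0, 120, seed=5, x0=x0)


@pytest.fixture(scope="session")
def morse_model(morse_dataset):
    """Force field trained on the first 80 dimer configurations."""
    group = PermutationGroup([[1, 0]], 2)
    return GDML(morse_dataset[:80], sigma=1.0, lam=1e-10,
                permutations=group).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
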