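import numpy as np
import pytest

from padmine.model import Dataset, MoleculeRecord
from padmine.synth import generate, sibling_family_plants


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """20 molecules, no plants: pure noise feature graphs."""
    return generate(20, [], seed=11, noise_features=(3, 6))


@pytest.fixture(scope="session")
def planted_dataset() -> Dataset:
    """200 molecules with the outlier-among-null-siblings plant family."""
    return generate(200, sibling_family_plants(), seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def two_fragment_molecule() -> MoleculeRecord:
    """A on one fragment, R on another: the pair is unreachable."""
    return MoleculeRecord(
        "frag",
        features=(("A", 0), ("R", 5), ("D", 1)),
        dist=((0, None, 1), (None, 0, None), (1, None, 0)),
    )
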