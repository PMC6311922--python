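import numpy as np
import pytest

from fmsm import synthetic
from fmsm.datasets import AssociationDataset
from fmsm.evaluation import SimilarityInputs


@pytest.fixture(scope="session")
def planted():
    """Default planted benchmark: 30 diseases x 60 miRNAs, two blocks."""
    return synthetic.generate(synthetic.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def planted_sims(planted):
    return SimilarityInputs.from_data(
        planted.dataset, planted.expression, planted.mesh
    )


@pytest.fixture(scope="session")
def tiny():
    """Small planted benchmark for fast cross-validation tests."""
    return synthetic.generate(
        synthetic.SyntheticConfig(
            nd=12, nm=18, n_tissues=12, n_blocks=2, density=0.1, seed=11
        )
    )


@pytest.fixture(scope="session")
def tiny_sims(tiny):
    return SimilarityInputs.from_data(tiny.dataset, tiny.expression, tiny.mesh)


def make_dataset(U, prefix=("d", "m")):
    """Build an AssociationDataset from a binary array with generic names."""
    U = np.asarray(U)
    return AssociationDataset(
        [f"{prefix[0]}{i + 1}" for i in range(U.shape[0])],
        [f"{prefix[1]}{j + 1}" for j in range(U.shape[1])],
        U,
    )
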