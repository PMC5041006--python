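import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gfex.datasets import load_fictional_example, mycoplasma_profiles
from gfex.matrix import GeneFamilyMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fictional():
    """The packaged 3-genome x 5-COG worked example and its metadata."""
    return load_fictional_example()


@pytest.fixture(scope="session")
def fictional_matrix(fictional):
    return fictional[0]


@pytest.fixture(scope="session")
def mycoplasma():
    return mycoplasma_profiles()


def random_matrix(seed: int, n_genomes: int = 6, n_cogs: int = 8) -> GeneFamilyMatrix:
    """Small random count matrix with no all-zero rows (helper, not a fixture)."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 5, size=(n_genomes, n_cogs))
    empty = counts.sum(axis=1) == 0
    counts[empty, 0] = 1
    return GeneFamilyMatrix(
        [f"g{i}" for i in range(n_genomes)],
        [f"c{j}" for j in range(n_cogs)],
        counts,
    )
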