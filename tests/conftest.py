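import numpy as np
import pytest

from barcodeval import DistanceMatrix, distance_matrix, worked_fixture


@pytest.fixture(scope="session")
def fixture_aln():
    return worked_fixture()


@pytest.fixture(scope="session")
def fixture_dm(fixture_aln):
    return distance_matrix(fixture_aln)


def make_random_dm(rng: np.random.Generator, n_species: int = 3,
                   per_species: int = 3, scale: float = 0.1) -> DistanceMatrix:
    """Random symmetric, fully defined distance matrix with species labels.

    Not metric — identification methods only rank distances, so arbitrary
    symmetric positives exercise them fully.
    """
    n = n_species * per_species
    vals = rng.uniform(0.0, scale, size=(n, n))
    vals = np.triu(vals, k=1)
    vals = vals + vals.T
    ids = [f"s{k}_i{j}" for k in range(n_species) for j in range(per_species)]
    species = [f"Species_{k}" for k in range(n_species) for _ in range(per_species)]
    return DistanceMatrix(ids, species, vals, np.ones((n, n), dtype=bool))


@pytest.fixture
def random_dm_factory():
    return make_random_dm
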