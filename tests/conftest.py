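import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from gpsel import (
    Dataset,
    GenotypeMatrix,
    mixed_design,
    simulate_founders,
    simulate_trait,
    unbalanced_design,
)


@pytest.fixture(scope="session")
def toy_genotypes() -> GenotypeMatrix:
    """4 samples x 4 markers covering the hand-countable cases."""
    d = np.array(
        [
            [0, 0, 2, 1],
            [1, 0, 2, 1],
            [2, 0, 1, 1],
            [1, 0, 1, 1],
        ]
    )
    return GenotypeMatrix(["a", "b", "c", "d"], ["m1", "m2", "m3", "m4"], d)


@pytest.fixture(scope="session")
def hwe_population():
    """Binomial Hardy-Weinberg genotypes: 500 samples x 1000 markers."""
    rng = np.random.default_rng(12)
    p = rng.uniform(0.1, 0.9, 1000)
    X = rng.binomial(2, p, size=(500, 1000))
    return GenotypeMatrix(
        [f"s{i}" for i in range(500)], [f"m{j}" for j in range(1000)], X
    )


@pytest.fixture(scope="session")
def small_populations():
    """Both crossing designs with an additive h2=0.5 trait, desk scale."""
    founders = simulate_founders(50, 5, 40, seed=3)
    mixed = simulate_trait(mixed_design(founders, 40, 160, seed=4), 50, 0.5, seed=5)
    unbal = simulate_trait(
        unbalanced_design(founders, [60, 40, 25, 20, 15], seed=6), 50, 0.5, seed=7
    )
    return {"mixed": mixed, "unbalanced": unbal}


@pytest.fixture(scope="session")
def mixed_dataset(small_populations) -> Dataset:
    pop = small_populations["mixed"]
    return Dataset(pop.genotypes(), pop.y)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
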