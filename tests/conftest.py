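import numpy as np
import pytest

from tumorgeo import (
    CloneComposition,
    ExpressionMatrix,
    GrowthConfig,
    MutationMatrix,
    SectorMap,
    simulate_patient,
)


@pytest.fixture
def square_map() -> SectorMap:
    """Four sectors on the corners of a 10 mm square."""
    coords = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
    return SectorMap("demo", ("A", "B", "C", "D"), coords)


@pytest.fixture
def paired_mutations() -> MutationMatrix:
    """A/B share m1, C/D share m2; one private variant each."""
    presence = np.array(
        [
            [1, 0, 1, 0, 0, 0],
            [1, 0, 0, 1, 0, 0],
            [0, 1, 0, 0, 1, 0],
            [0, 1, 0, 0, 0, 1],
        ]
    )
    return MutationMatrix(
        ("A", "B", "C", "D"),
        ("m1", "m2", "pA", "pB", "pC", "pD"),
        presence,
    )


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = rng.lognormal(1.0, 0.5, size=(30, 4))
    genes = tuple(f"g{i}" for i in range(30))
    return ExpressionMatrix(genes, ("A", "B", "C", "D"), values)


@pytest.fixture
def two_clone_composition() -> CloneComposition:
    props = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5], [0.8, 0.2]])
    return CloneComposition(("A", "B", "C", "D"), ("c1", "c2"), props)


@pytest.fixture(scope="session")
def neutral_patient():
    """One neutral boundary-growth patient, shared across tests."""
    return simulate_patient(GrowthConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_growth_config() -> GrowthConfig:
    """A fast-growing small tumor for tests that resimulate."""
    return GrowthConfig(lattice_size=48, rng_seed=5)
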