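import pytest

from effectpaths.effect_paths import infer_deps, infer_heps
from effectpaths.synthetic_data import generate_worked_example, generate_world


@pytest.fixture(scope="session")
def example_world():
    return generate_worked_example()


@pytest.fixture(scope="session")
def example_dep(example_world):
    return infer_deps(
        example_world.network, {"T1", "T2"}, {"S1", "S2"}, drug="DRUG1", disease="DIS1"
    )


@pytest.fixture(scope="session")
def example_hep(example_world, example_dep):
    return infer_heps(example_world.network, {"R1", "R2"}, example_dep, hormone="HORM1")


@pytest.fixture(scope="session")
def planted_world():
    """Noiseless random world with total gold/background separation."""
    return generate_world(seed=1)
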