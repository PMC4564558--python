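import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from genesect import FunctionalGeneSet, GeneUniverse, DiseaseGeneSample


@pytest.fixture
def small_universe() -> GeneUniverse:
    return GeneUniverse.from_symbols([f"G{i:03d}" for i in range(100)], label="toy")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_set(label: str, indices) -> FunctionalGeneSet:
    return FunctionalGeneSet.from_symbols(label, [f"G{i:03d}" for i in indices])


def make_sample(label: str, indices) -> DiseaseGeneSample:
    return DiseaseGeneSample.from_symbols(label, [f"G{i:03d}" for i in indices])
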