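import numpy as np
import pytest

from benchlink.matcher import SynonymTable
from benchlink.models import manifest_for_conditions
from benchlink.synthetic import generate_point_benchmark


@pytest.fixture(scope="session")
def table():
    return SynonymTable.default()


@pytest.fixture(scope="session")
def small_benchmark():
    """50 sequences, 3 conditions, noiseless; with its ground-truth model."""
    return generate_point_benchmark(n=50, length=80, seed=11)


@pytest.fixture(scope="session")
def oracle_manifest():
    return manifest_for_conditions(["K562", "HepG2", "GM12878"], name="oracle")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
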