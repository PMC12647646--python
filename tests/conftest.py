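import numpy as np
import pytest

from clamrfo.benchmarks import make_function
from clamrfo.initialization import Bounds
from clamrfo.synth import SynthSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere2():
    return make_function("sphere", 2, seed=7)


@pytest.fixture(scope="session")
def cigar10():
    return make_function("bent_cigar", 10, seed=42)


@pytest.fixture
def unit_bounds():
    return Bounds.cube(0.0, 1.0, 5)


@pytest.fixture(scope="session")
def synth_problem():
    """Default two-class design (72 samples, 47/25, 100 genes, 5 informative)."""
    return make_dataset(SynthSpec(seed=11))
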