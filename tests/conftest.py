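import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from hgtscan.composition import GeneticCode
from hgtscan.synthetic import make_profile, simulate_genome


@pytest.fixture(scope="session")
def code():
    return GeneticCode.from_table_id(11)


@pytest.fixture(scope="session")
def small_genome():
    """60 background + 6 alien genes, GC3-rich vs AT3-rich profiles."""
    bg = make_profile(0.85, label="bg")
    alien = make_profile(0.25, label="alien")
    return simulate_genome(60, 6, (150, 300), bg, alien, seed=11)


@pytest.fixture(scope="session")
def sense_codons(code):
    return sorted(code.forward)


@pytest.fixture(scope="session")
def random_cds(sense_codons):
    """Factory for random in-frame sequences of sense codons."""

    def _make(rng: np.random.Generator, n_codons: int) -> str:
        idx = rng.integers(0, len(sense_codons), size=n_codons)
        return "".join(sense_codons[i] for i in idx)

    return _make
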