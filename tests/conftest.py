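import pytest

from plastcomp.alignment import Alignment
from plastcomp.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_default():
    """One default 30 kb, two-species x four-individual simulation."""
    ancestor, individuals, aln, truth = simulate(SimConfig(seed=1))
    return ancestor, individuals, aln, truth


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


def make_alignment(*rows: str, labels=None) -> Alignment:
    labels = labels or [f"r{i}" for i in range(len(rows))]
    return Alignment(labels, list(rows))
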