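import numpy as np
import pytest

from xdeg import SequenceRecord, SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_record(id="r1", species="A", sequence="ACGT", read_count=2):
    return SequenceRecord(id, species, sequence, read_count)


@pytest.fixture(scope="session")
def small_dataset():
    """One small two-species dataset with truth, shared across tests."""
    cfg = SimulationConfig(
        n_ortholog_pairs=300, n_specific_a=50, n_specific_b=50, seed=11
    )
    records_a, records_b, truth = generate_dataset(cfg)
    return cfg, records_a, records_b, truth


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
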