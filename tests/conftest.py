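import numpy as np
import pytest

from trxmine.family_mining import SequenceRecord
from trxmine.simulate import FamilySimConfig, simulate_family


@pytest.fixture(scope="session")
def sim_dataset():
    """A seeded three-family dataset shared by mining/clustering tests."""
    return simulate_family(FamilySimConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(seq_id: str, residues: str, **kwargs) -> SequenceRecord:
    return SequenceRecord(id=seq_id, residues=residues, **kwargs)
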