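import numpy as np
import pytest

from acetknn.dataio import Corpus, ProteinRecord
from acetknn.synthetic_data import SimParams, simulate_corpus


def make_record(rid, sequence="ACDEFGHIKLMNPQRSTVWYACDEFGHIKL", label=None,
                annotations=None, pssm=None):
    return ProteinRecord(
        id=rid, sequence=sequence, label=label,
        annotations=annotations or {}, pssm=pssm,
    )


@pytest.fixture
def toy_corpus():
    """Ten labeled records with GO sets that separate the classes."""
    rng = np.random.default_rng(7)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records = []
    for i in range(10):
        label = 1 if i < 5 else 0
        pool = "enr" if label else "bg"
        seq = "".join(rng.choice(aa, size=40))
        records.append(
            make_record(
                f"r{i:02d}", sequence=seq, label=label,
                annotations={"GO": frozenset({f"{pool}{i % 3}", f"{pool}{(i + 1) % 3}"})},
            )
        )
    return Corpus(records)


@pytest.fixture(scope="session")
def small_strong_corpus():
    """A 30+30 strong-signal synthetic corpus shared across tests."""
    return simulate_corpus(
        SimParams(n_pos=30, n_neg=30, seq_len=(30, 80), seed=11)
    )
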