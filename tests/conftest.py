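import numpy as np
import pytest

from otunet.io_seq import SequenceRecord, SequenceTypeTable
from otunet.network_aic import BipartiteNetwork


@pytest.fixture
def toy_records():
    return [
        SequenceRecord("r1", "P1", "ACGT"),
        SequenceRecord("r2", "P1", "ACGT"),
        SequenceRecord("r3", "P2", "ACGT"),
        SequenceRecord("r4", "P1", "ACGA"),
        SequenceRecord("r5", "P2", "TTTT"),
        SequenceRecord("r6", "P2", "TTTT"),
    ]


@pytest.fixture
def toy_table():
    return SequenceTypeTable(
        sequences=["ACGT", "TTTT", "ACGA"],
        plots=["P1", "P2"],
        abundance=np.array([[2, 1], [0, 2], [1, 0]]),
    )


def make_network(member_rows):
    """Build a BipartiteNetwork directly from per-OTU member abundance rows."""
    members = [np.asarray(rows, dtype=np.int64) for rows in member_rows]
    r = members[0].shape[1]
    S_i = np.array([m.shape[0] for m in members])
    return BipartiteNetwork(
        k=len(members),
        r=r,
        S=int(S_i.sum()),
        S_i=S_i,
        L_iq=np.stack([(m > 0).sum(axis=0) for m in members]),
        a_dot_iq=np.stack([m.sum(axis=0) for m in members]),
        members=members,
    )


def random_member_rows(rng, k_max=10, r_max=8, S_max=40, a_max=20):
    """Random per-OTU member abundance rows within the tested size envelope."""
    k = int(rng.integers(1, k_max + 1))
    r = int(rng.integers(1, r_max + 1))
    sizes = rng.multinomial(int(rng.integers(k, S_max + 1)) - k, np.ones(k) / k) + 1
    return [
        rng.integers(0, a_max + 1, size=(int(s), r)).tolist() for s in sizes
    ]
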