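import numpy as np
import pytest

from evtrf import ReferenceRecord, ReferenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240216)


@pytest.fixture
def small_trna_set():
    """Three hand-written tRNA references (76 nt, CCA-terminated)."""
    body = (
        "GCATTGGTGGTTCAGTGGTAGAATTCTCGCCTGCCACGCGGGAG"
        "GCCCGGGTTCGATTCCCGGCCAATGCA"
    )
    assert len(body) == 71
    seqs = {
        "tRNA-Gly-GCC-1-1": body + "TCCCA",
        "tRNA-Glu-CTC-1-1": "AGT" + body[3:] + "GACCA",
        "tRNA-Lys-TTT-2-1": body[::-1] + "GGCCA",
    }
    refset = ReferenceSet("tRNA")
    for rid, seq in seqs.items():
        refset.add(ReferenceRecord(rid, "tRNA", seq))
    return refset
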