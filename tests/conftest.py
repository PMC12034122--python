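import numpy as np
import pytest

from pirnascope.io_core import CountMatrix, GenomicLocus, PiRNARecord, SampleMeta


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        np.array([[3, 5], [1, 2]]), pirna_ids=["pU", "pC"], sample_ids=["s1", "s2"]
    )


@pytest.fixture
def tiny_records() -> list[PiRNARecord]:
    # pU starts with U, pC with C; both cover position 10
    return [
        PiRNARecord("pU", "UGGAAUCGAUACGUAGCUAGCUAGGCAUGC"),
        PiRNARecord("pC", "CGGAAUCGAUACGUAGCUAGCUAGGCAUG"),
    ]


@pytest.fixture
def two_group_meta():
    def make(n_case: int, n_control: int) -> list[SampleMeta]:
        meta = [SampleMeta(f"c{i}", "case", "favorable") for i in range(n_case)]
        meta += [SampleMeta(f"h{i}", "control") for i in range(n_control)]
        return meta

    return make


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGU")), size=length))


@pytest.fixture
def rna_factory():
    return random_rna
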