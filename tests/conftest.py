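from __future__ import annotations

import random

import pytest

from fadevo.codes import genetic_code
from fadevo.seqio import CodingSequence


@pytest.fixture(scope="session")
def code1():
    return genetic_code(1)


@pytest.fixture(scope="session")
def code6():
    return genetic_code(6)


def make_cds(nucleotides: str, code, seq_id: str = "g") -> CodingSequence:
    """Construct a CodingSequence directly (inputs are known-valid in tests)."""
    return CodingSequence(id=seq_id, nucleotides=nucleotides, code=code)


def random_codons(rng: random.Random, code, n: int) -> list[str]:
    return [rng.choice(code.sense_codons) for _ in range(n)]
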