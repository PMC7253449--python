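from __future__ import annotations

import numpy as np
import pytest

from uorfkit.transcripts import TranscriptRecord

BASES = "ACGT"


def random_transcript(rng: np.random.Generator, min_len=10, max_len=300,
                      tag: str = "T") -> TranscriptRecord:
    L = int(rng.integers(min_len, max_len + 1))
    utr = "".join(rng.choice(list(BASES), size=L))
    cds = "ATG" + "".join(rng.choice(list(BASES), size=9))
    return TranscriptRecord(f"G_{tag}", f"T_{tag}", utr, cds)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_transcripts(rng):
    return [random_transcript(rng, tag=str(i)) for i in range(50)]


@pytest.fixture
def simple_transcript():
    return TranscriptRecord("G1", "T1", "ACGTTTG", "ATGGCT")


@pytest.fixture
def two_uorf_transcript():
    # one uORF (start 0, TGA stop at 6) and one existing in-frame oORF (start 5)
    return TranscriptRecord("G2", "T2", "ATGAAATGACC", "ATGGCT")


@pytest.fixture
def strong_kozak_transcript():
    # strong-Kozak uORF: start 4, TAG stop at 10
    return TranscriptRecord("G3", "T3", "AAGGATGGACTAGCCC", "ATGGCT")
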