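"""Shared fixtures: small transcript sets written to disk at test time."""

from __future__ import annotations

import numpy as np
import pytest

from apsscan import Transcript
from apsscan.sequence_model import write_transcripts


def random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(len(alphabet), size=n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20190410)


@pytest.fixture
def tiny_transcript() -> Transcript:
    # 2-nt UTR5, 9-nt CDS, 2-nt UTR3 (the U->T normalized record)
    return Transcript("x", "X", "human", "AAATGGGCTAAAA", 3, 11)


@pytest.fixture
def transcript_files(tmp_path, rng):
    """Three random transcripts written as FASTA + CDS table; returns paths."""
    transcripts = []
    for i in range(3):
        utr5 = random_seq(rng, 50)
        cds = "ATG" + random_seq(rng, 294) + "TAA"
        utr3 = random_seq(rng, 350)
        seq = utr5 + cds + utr3
        transcripts.append(Transcript(f"t{i}", f"G{i}", "human", seq, 51, 350))
    fasta = tmp_path / "transcripts.fasta"
    table = tmp_path / "cds.tsv"
    write_transcripts(transcripts, fasta, table)
    return fasta, table, transcripts
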