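"""Shared fixtures: tiny genomes, random-sequence helpers, the published
up-regulated candidate table (p values printed as "<10-4" are transcribed
as 1e-4), and brute-force oracle helpers that stay independent of the
implementation paths they check."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

DATA_DIR = Path(__file__).parent / "data"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_oracle(seq: str) -> str:
    """String-level reverse complement, written independently of the package."""
    return "".join(_COMP[c] for c in reversed(seq))


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def tiny_genome():
    from mircircuit import GenomeSequence

    return {
        "chr1": GenomeSequence("chr1", "ACGTACGTAC"),
        "chr2": GenomeSequence("chr2", "NNNNACGT"),
    }


@pytest.fixture(scope="session")
def up_candidates_table():
    return pd.read_csv(DATA_DIR / "up_candidates_c2c12.tsv", sep="\t")
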