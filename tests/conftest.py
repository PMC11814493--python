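"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use the dumbest correct algorithms
(enumeration, quadratic scans) so they stay independent of the code paths
they check.
"""

from __future__ import annotations

import random
from typing import Dict, List, Tuple

import pytest

from telokit.seqio import SequenceRecord, write_fasta

# ---------------------------------------------------------------------------
# brute-force oracles

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(u: str) -> str:
    return "".join(_COMP[c] for c in reversed(u))


def oracle_rotations(u: str) -> List[str]:
    return [u[i:] + u[:i] for i in range(len(u))]


def oracle_canonical(u: str) -> str:
    """Minimum over all 2k rotation/strand candidates, by enumeration."""
    return min(oracle_rotations(u) + oracle_rotations(oracle_revcomp(u)))


def oracle_runs(seq: str, k: int) -> List[Tuple[str, int, int]]:
    """Naive tandem-run detection: chunk, then group consecutive equals."""
    chunks = [seq[i : i + k] for i in range(0, len(seq) - k + 1, k)]
    runs = []
    i = 0
    while i < len(chunks):
        j = i
        while (
            j + 1 < len(chunks)
            and chunks[j + 1] == chunks[i]
            and set(chunks[i]) <= set("ACGT")
        ):
            j += 1
        if j > i:
            runs.append((chunks[i], i * k, j - i + 1))
        i = j + 1
    return runs


def oracle_explore_record(seq: str, k: int, threshold: int) -> Dict[str, int]:
    tally: Dict[str, int] = {}
    for unit, _start, count in oracle_runs(seq, k):
        if count >= threshold:
            c = oracle_canonical(unit)
            tally[c] = tally.get(c, 0) + count
    return tally


def oracle_occurrences(seq: str, motif: str) -> List[int]:
    """Quadratic all-positions scan."""
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


def random_unit(rng: random.Random, k_max: int = 20, k_min: int = 1) -> str:
    k = rng.randint(k_min, k_max)
    return "".join(rng.choice("ACGT") for _ in range(k))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260920)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing records to a temporary FASTA file."""

    def _write(records, name="input.fasta"):
        path = tmp_path / name
        write_fasta(records, path)
        return path

    return _write


@pytest.fixture
def telomere_record() -> SequenceRecord:
    return SequenceRecord(id="telo", seq="TTAGGG" * 100)
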