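"""De-novo discovery of candidate telomeric repeat units.

The scan walks each sequence once in non-overlapping chunks of size k
(frame fixed at offset 0; the trailing remainder shorter than k is
ignored).  Maximal groups of two or more identical consecutive chunks are
collapsed into tandem runs.  Runs whose chunk count reaches a threshold are
tallied — the tallied quantity is the number of repeat units in the run, so
long telomeric arrays weigh more than short interstitial repeats — and the
tallies are merged under canonical rotation/reverse-complement equivalence.

Chunk-level aggregation makes the scan O(n) per k.  Frame shifts between
arrays (e.g. an indel inside a telomere) simply split one run into two runs
of rotated units, which the canonical merge re-unites.  A chunk containing
any non-ACGT character never joins a run.

The threshold is expressed in repeat units, not nucleotides: threshold 100
at k=6 demands a 600 nt perfect array.  Lower it if nothing is reported.
Recommended k for telomeric repeat discovery is 4-15; nearly all known
telomeric units are shorter than 15 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from telokit.canonical import merge_counts
from telokit.seqio import SequenceRecord

DEFAULT_THRESHOLD = 100

# TSV column names for the explore output table
EXPLORE_COLUMNS = ["canonical_repeat_unit", "kmer_length", "count"]

_ACGT_TABLE = np.zeros(256, dtype=bool)
_ACGT_TABLE[[ord(b) for b in "ACGT"]] = True


@dataclass(frozen=True)
class TandemRun:
    """A maximal run of >= 2 identical consecutive k-chunks.

    ``start`` is a 0-based nucleotide offset (always a multiple of k) and
    ``count`` the number of consecutive identical chunks, so the slice
    ``seq[start : start + count * len(unit)]`` is ``unit * count``.
    """

    unit: str
    start: int
    count: int

    @property
    def span(self) -> int:
        return self.count * len(self.unit)


@dataclass(frozen=True)
class ExploreConfig:
    """Parameters of the discovery scan: k range and run-count threshold."""

    k_min: int
    k_max: int
    threshold: int = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValueError(f"k_min must be >= 2, got {self.k_min}")
        if self.k_max < self.k_min:
            raise ValueError(f"k_max ({self.k_max}) must be >= k_min ({self.k_min})")
        if self.threshold < 2:
            raise ValueError(f"threshold must be >= 2, got {self.threshold}")


class _ComparisonCounter:
    """Mutable counter used to audit the single-pass contract."""

    def __init__(self) -> None:
        self.comparisons = 0


def detect_runs(
    seq: str, k: int, _counter: Optional[_ComparisonCounter] = None
) -> List[TandemRun]:
    """Single-pass scan: collapse identical consecutive k-chunks into runs.

    Each chunk is compared once to its predecessor (at most floor(n/k) - 1
    comparisons per sequence; pass ``_counter`` to audit this).  Chunks
    containing non-ACGT characters terminate runs and never join one.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n_chunks = len(seq) // k
    runs: List[TandemRun] = []
    prev: Optional[str] = None
    run_start = 0
    run_count = 0

    def flush() -> None:
        if run_count >= 2:
            runs.append(TandemRun(unit=prev, start=run_start, count=run_count))

    for i in range(n_chunks):
        chunk = seq[i * k : (i + 1) * k]
        if _counter is not None:
            _counter.comparisons += 1
        if prev is not None and chunk == prev and _VALID_CACHE(chunk):
            run_count += 1
        else:
            flush()
            prev = chunk
            run_start = i * k
            run_count = 1
    flush()
    return runs


_VALID_SET = frozenset("ACGT")


def _VALID_CACHE(chunk: str) -> bool:
    return _VALID_SET.issuperset(chunk)


def _detect_runs_vectorized(codes: np.ndarray, k: int) -> List[tuple[int, int]]:
    """Fast path over a uint8 view of the sequence.

    Returns (start_chunk_index, chunk_count) pairs for maximal runs of >= 2
    identical consecutive valid chunks; unit extraction is left to the
    caller.  Bit-identical in outcome to :func:`detect_runs`.
    """
    n_chunks = codes.size // k
    if n_chunks < 2:
        return []
    m = codes[: n_chunks * k].reshape(n_chunks, k)
    valid = _ACGT_TABLE[m].all(axis=1)
    adj = (m[1:] == m[:-1]).all(axis=1) & valid[1:] & valid[:-1]
    if not adj.any():
        return []
    # maximal stretches of True in adj: a stretch of t adjacencies = t+1 chunks
    padded = np.concatenate(([False], adj, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s + 1)) for s, e in zip(starts, ends)]


def _record_tally(seq: str, k: int, threshold: int) -> Dict[str, int]:
    """Raw (non-canonical) unit tally of qualifying runs for one sequence."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    tally: Dict[str, int] = {}
    for start_chunk, count in _detect_runs_vectorized(codes, k):
        if count >= threshold:
            unit = seq[start_chunk * k : (start_chunk + 1) * k]
            tally[unit] = tally.get(unit, 0) + count
    return tally


def explore_record(seq: str, k: int, threshold: int) -> Dict[str, int]:
    """Tally qualifying tandem runs of one sequence under canonical forms.

    Every run of at least ``threshold`` identical consecutive chunks
    contributes its unit count; tallies are then merged over rotations and
    reverse complements.  Returns an empty map when no run qualifies.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if threshold < 2:
        raise ValueError(f"threshold must be >= 2, got {threshold}")
    return merge_counts(_record_tally(seq, k, threshold))


def explore(records: Iterable[SequenceRecord], cfg: ExploreConfig) -> pd.DataFrame:
    """Run the discovery scan over all records for every k in the range.

    Returns a table with columns ``canonical_repeat_unit``, ``kmer_length``
    and ``count``, sorted by k ascending, count descending, then unit.  The
    result is a pure aggregation: independent of record order.
    """
    records = list(records)
    rows: List[tuple[str, int, int]] = []
    for k in range(cfg.k_min, cfg.k_max + 1):
        raw: Dict[str, int] = {}
        for rec in records:
            for unit, n in _record_tally(rec.seq, k, cfg.threshold).items():
                raw[unit] = raw.get(unit, 0) + n
        for unit, n in sorted(merge_counts(raw).items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append((unit, k, n))
    return pd.DataFrame(rows, columns=EXPLORE_COLUMNS)
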