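"""FASTA input and the toolkit's TSV dialect.

FASTA parsing is delegated to Biopython; this module adds transparent
gzip handling (detected by magic bytes, not file extension), uppercase
folding, and strict validation of the two failure modes that matter for a
command-line tool: input that is not FASTA at all, and records with an
empty sequence body.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO

GZIP_MAGIC = b"\x1f\x8b"


class FastaFormatError(ValueError):
    """The input file is not valid FASTA."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record.

    ``id`` is the first whitespace-delimited token of the header line;
    the full header is kept in ``description``.  ``seq`` is folded to
    uppercase at load time and may contain IUPAC ambiguity codes.
    """

    id: str
    seq: str
    description: str = field(default="", compare=False)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    """Open a text handle, transparently decompressing gzip input."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file (plain or gzip-compressed).

    Records are yielded in file order with sequences folded to uppercase.
    Memory scales with the largest single record, not with file size.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FastaFormatError
        If the first non-blank character is not '>' or a record has an
        empty sequence body.
    """
    handle = _open_maybe_gzip(path)
    try:
        # Biopython silently skips leading junk before the first '>';
        # reject it up front so a non-FASTA file is a loud error.
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: not FASTA (first non-blank character is "
                        f"{line.lstrip()[0]!r}, expected '>')"
                    )
                break
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
            yield SequenceRecord(id=rec.id, seq=seq, description=rec.description)
    finally:
        handle.close()


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as plain FASTA (helper for fixtures and round-trips)."""
    with open(path, "wt", encoding="utf-8") as out:
        for rec in records:
            header = rec.description if rec.description else rec.id
            out.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


def write_tsv(rows: Iterable[Sequence], header: Sequence[str], path: str | Path) -> None:
    """Write a tab-separated table: one header line, LF endings, UTF-8.

    Every row must have the same arity as ``header``.
    """
    header = list(header)
    with open(path, "wt", encoding="utf-8", newline="") as out:
        out.write("\t".join(str(h) for h in header) + "\n")
        for i, row in enumerate(rows):
            if len(row) != len(header):
                raise ValueError(
                    f"row {i} has {len(row)} fields, expected {len(header)}"
                )
            out.write("\t".join(str(v) for v in row) + "\n")


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a table written by :func:`write_tsv`; returns (header, rows)."""
    with open(path, "rt", encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty TSV")
    header = lines[0].split("\t")
    rows = [line.split("\t") for line in lines[1:]]
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise ValueError(f"{path}: line {i + 2} has {len(row)} fields, expected {len(header)}")
    return header, rows
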