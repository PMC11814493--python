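"""Clade → canonical telomeric repeat lookup database.

A small table of canonical telomeric repeat units per clade, seeded from
the Darwin Tree of Life survey of chromosomally complete assemblies, ships
with the package.  ``build`` installs it into a per-user data directory
(or installs a user-supplied table); ``find`` looks a clade up and then
delegates to the windowed search with each of the clade's repeats.

A clade may carry several repeats (the bumblebee genus Bombus has a
compound telomeric landscape of AACCCG, AACCT and AACCCT pasted together),
so lookups return a list.  Every repeat in the database must already be in
canonical form; loading validates this.
"""

from __future__ import annotations

import importlib.resources
import os
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

from telokit.canonical import canonical
from telokit.seqio import read_tsv

DB_COLUMNS = ["clade", "repeat", "n_species", "note"]
DB_FILENAME = "clade_db.tsv"


class CladeNotFoundError(KeyError):
    """No database record matches the requested clade."""


@dataclass(frozen=True)
class CladeRecord:
    clade: str
    repeat: str
    n_species: Optional[int] = None
    note: str = ""


def bundled_database_path() -> Path:
    """Path of the clade table shipped inside the package."""
    return Path(importlib.resources.files("telokit") / "data" / DB_FILENAME)


def default_data_dir() -> Path:
    """Per-user data directory (override with TELOKIT_DATA_DIR)."""
    env = os.environ.get("TELOKIT_DATA_DIR")
    if env:
        return Path(env)
    return Path.home() / ".local" / "share" / "telokit"


def load_database(path: str | Path | None = None) -> List[CladeRecord]:
    """Load and validate a clade database TSV.

    Defaults to the installed copy if present, else the bundled fixture.
    Every repeat must equal its own canonical form, and (clade, repeat)
    pairs must be unique case-insensitively.
    """
    if path is None:
        installed = default_data_dir() / DB_FILENAME
        path = installed if installed.exists() else bundled_database_path()
    header, rows = read_tsv(path)
    if header != DB_COLUMNS:
        raise ValueError(f"{path}: expected columns {DB_COLUMNS}, found {header}")
    records: List[CladeRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, (clade, repeat, n_species, note) in enumerate(rows, start=2):
        if canonical(repeat) != repeat:
            raise ValueError(
                f"{path}: line {i}: repeat {repeat!r} is not canonical "
                f"(canonical form is {canonical(repeat)!r})"
            )
        key = (clade.lower(), repeat)
        if key in seen:
            raise ValueError(f"{path}: line {i}: duplicate entry for {clade!r} / {repeat!r}")
        seen.add(key)
        records.append(
            CladeRecord(
                clade=clade,
                repeat=repeat,
                n_species=int(n_species) if n_species else None,
                note=note,
            )
        )
    return records


def _edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (small strings; used only for suggestions)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def lookup(clade: str, db: List[CladeRecord]) -> List[CladeRecord]:
    """All records whose clade name matches ``clade`` case-insensitively.

    Raises :class:`CladeNotFoundError` when nothing matches, listing names
    within edit distance 2 as suggestions.
    """
    wanted = clade.lower()
    hits = [rec for rec in db if rec.clade.lower() == wanted]
    if hits:
        return hits
    names = sorted({rec.clade for rec in db})
    near = [n for n in names if _edit_distance(n.lower(), wanted) <= 2]
    msg = f"clade {clade!r} not in database"
    if near:
        msg += f"; did you mean: {', '.join(near)}?"
    raise CladeNotFoundError(msg)


def install_database(
    from_file: str | Path | None = None, data_dir: str | Path | None = None
) -> Path:
    """Copy the bundled (or a user-supplied) clade table into the data dir.

    The source table is validated before installation; returns the
    installed path.
    """
    src = Path(from_file) if from_file is not None else bundled_database_path()
    load_database(src)  # validate before installing
    dest_dir = Path(data_dir) if data_dir is not None else default_data_dir()
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / DB_FILENAME
    shutil.copyfile(src, dest)
    return dest
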