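"""Canonical representation of tandem repeat units.

A telomeric repeat array can be read in either phase (any rotation of the
unit tiles the same array) and on either strand.  Two units therefore
describe the same repeat whenever one is a rotation of the other or of its
reverse complement.  The canonical form of a unit is the lexicographically
smallest string (plain byte order, A < C < G < T) over all rotations of the
unit and all rotations of its reverse complement; it is the class
representative under this equivalence.  For the vertebrate repeat the
canonical form of TTAGGG is AACCCT.

A unit that is a whole multiple of a shorter unit (AACCCTAACCCT) is kept as
is — it is a distinct unit at its own length k, never reduced to its
primitive root.
"""

from __future__ import annotations

from typing import Dict

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def _check_unit(unit: str) -> None:
    if not unit:
        raise ValueError("repeat unit must be non-empty")
    if not _VALID.issuperset(unit):
        bad = sorted(set(unit) - _VALID)
        raise ValueError(f"repeat unit contains non-ACGT characters: {bad}")


def reverse_complement(unit: str) -> str:
    """Reverse complement of a strictly-ACGT unit (an involution)."""
    _check_unit(unit)
    return unit.translate(_COMPLEMENT)[::-1]


def least_rotation(unit: str) -> str:
    """Lexicographically smallest rotation of ``unit`` (Booth's algorithm).

    Runs in O(k) time; equivalent to taking the minimum over all k
    rotations under plain byte order.
    """
    _check_unit(unit)
    s = unit + unit
    n = len(s)
    f = [-1] * n  # failure function over the doubled string
    start = 0  # least rotation of the prefix considered so far
    for j in range(1, n):
        c = s[j]
        i = f[j - start - 1]
        while i != -1 and c != s[start + i + 1]:
            if c < s[start + i + 1]:
                start = j - i - 1
            i = f[i]
        if c != s[start + i + 1]:
            if c < s[start + i + 1]:  # i == -1 here
                start = j
            f[j - start] = -1
        else:
            f[j - start] = i + 1
    return s[start : start + len(unit)]


def canonical(unit: str) -> str:
    """Canonical form: min over all rotations of the unit and of its
    reverse complement.  Idempotent, rotation- and strand-invariant.

    >>> canonical("TTAGGG")
    'AACCCT'
    """
    fwd = least_rotation(unit)
    rev = least_rotation(reverse_complement(unit))
    return min(fwd, rev)


def merge_counts(counts: Dict[str, int]) -> Dict[str, int]:
    """Aggregate a unit→count map under canonical equivalence.

    All keys must be valid ACGT units of one common length.  The total of
    the counts is conserved exactly; keys of the result are canonical.
    """
    if not counts:
        return {}
    lengths = {len(u) for u in counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed unit lengths in count map: {sorted(lengths)}")
    merged: Dict[str, int] = {}
    for unit, n in counts.items():
        c = canonical(unit)
        merged[c] = merged.get(c, 0) + n
    return merged
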