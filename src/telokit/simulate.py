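"""Error-bearing telomeric array simulation and the discovery benchmark grid.

The generator emulates a telomeric array as a unit (default TTAGGG) tiled
to a target length, then corrupted by independent per-base errors: with
probability ``rate`` a position receives exactly one event — a substitution
to a uniformly chosen different base, an insertion of a uniform base after
the position, or a deletion of the position — with the event type drawn
from a (sub, ins, del) mix.  The benchmark grid crosses array lengths
600 / 12,000 / 30,000 nt with per-base error rates 0%, 0.1%, 1%, 1.5%, 2%,
5% and 10% (21 conditions), simulates many replicate arrays per condition,
pools each condition's replicates through the discovery scan, and records
whether the most abundant canonical unit matches the simulated repeat and
whether the true canonical unit is recovered at all.

Everything is reproducible: a single integer seed determines every
replicate of every condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from telokit.canonical import canonical, merge_counts, reverse_complement
from telokit.explore import EXPLORE_COLUMNS, ExploreConfig, _record_tally
from telokit.seqio import SequenceRecord

DEFAULT_LENGTHS: Tuple[int, ...] = (600, 12_000, 30_000)
DEFAULT_RATES: Tuple[float, ...] = (0.0, 0.001, 0.01, 0.015, 0.02, 0.05, 0.10)
DEFAULT_REPLICATES = 1000
DEFAULT_UNIT = "TTAGGG"

GRID_COLUMNS = ["length", "rate", "n_replicates", "top_repeat", "top_count", "true_repeat_found"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# for each base code, the three alternative bases (substitution targets)
_ALT = np.zeros((256, 3), dtype=np.uint8)
for _b in _BASES:
    _ALT[_b] = np.array([x for x in _BASES if x != _b], dtype=np.uint8)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error process: total rate plus the event-type mix."""

    rate: float
    sub_frac: float = 1.0 / 3.0
    ins_frac: float = 1.0 / 3.0
    del_frac: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"error rate must be in [0, 1], got {self.rate}")
        total = self.sub_frac + self.ins_frac + self.del_frac
        if any(f < 0 for f in (self.sub_frac, self.ins_frac, self.del_frac)):
            raise ValueError("event fractions must be non-negative")
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"event fractions must sum to 1, got {total}")


def simulate_telomere(
    unit: str,
    length: int,
    model: ErrorModel,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """One simulated telomeric array of ``length`` nt before errors.

    The unit is tiled to exactly ``length`` nt (the final copy truncated if
    needed); each position independently receives at most one error event.
    Deterministic given the model's seed (or an explicit ``rng``); the
    output length differs from ``length`` only through indels.
    """
    if length < len(unit):
        raise ValueError(f"length ({length}) must be at least the unit length ({len(unit)})")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    clean = (unit * (length // len(unit) + 1))[:length]
    arr = np.frombuffer(clean.encode("ascii"), dtype=np.uint8).copy()
    if model.rate == 0.0:
        return clean
    err_idx = np.flatnonzero(rng.random(length) < model.rate)
    if err_idx.size == 0:
        return clean
    ev = rng.random(err_idx.size)
    sub_idx = err_idx[ev < model.sub_frac]
    ins_idx = err_idx[(ev >= model.sub_frac) & (ev < model.sub_frac + model.ins_frac)]
    del_idx = err_idx[ev >= model.sub_frac + model.ins_frac]
    if sub_idx.size:
        arr[sub_idx] = _ALT[arr[sub_idx], rng.integers(0, 3, size=sub_idx.size)]
    counts = np.ones(length, dtype=np.intp)
    counts[del_idx] = 0
    counts[ins_idx] = 2
    out = np.repeat(arr, counts)
    if ins_idx.size:
        # np.repeat duplicates the original base; overwrite the second copy
        # (the position just after the original) with a uniform base
        pos = np.cumsum(counts)[ins_idx] - 1
        out[pos] = _BASES[rng.integers(0, 4, size=ins_idx.size)]
    return out.tobytes().decode("ascii")


@dataclass
class ConditionResult:
    """Outcome of one (length, error-rate) benchmark condition."""

    length: int
    rate: float
    n_replicates: int
    top_repeat: Optional[str]
    top_count: int
    true_repeat_found: bool
    n_replicates_with_runs: int
    table: pd.DataFrame = field(repr=False, default=None)


def _table_from_raw(per_k_raw: Dict[int, Dict[str, int]]) -> pd.DataFrame:
    rows = []
    for k in sorted(per_k_raw):
        merged = merge_counts(per_k_raw[k])
        for unit, n in sorted(merged.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append((unit, k, n))
    return pd.DataFrame(rows, columns=EXPLORE_COLUMNS)


def _top_row(table: pd.DataFrame) -> Tuple[Optional[str], int]:
    """Most abundant canonical unit across all k; ties break to the
    lexicographically smallest unit."""
    if len(table) == 0:
        return None, 0
    best = table.loc[
        table.sort_values(
            ["count", "canonical_repeat_unit"], ascending=[False, True]
        ).index[0]
    ]
    return str(best["canonical_repeat_unit"]), int(best["count"])


def run_condition(
    unit: str,
    length: int,
    model: ErrorModel,
    n_replicates: int,
    cfg: ExploreConfig,
) -> ConditionResult:
    """Simulate one condition and pool its replicates through the scan.

    All replicates are analysed as one multi-record input (counts are
    summed per canonical unit per k, exactly as :func:`telokit.explore`
    does for a multi-record FASTA).  ``top_repeat`` is the unit with the
    largest count across all k.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    child_seeds = np.random.SeedSequence(model.seed).spawn(n_replicates)
    ks = range(cfg.k_min, cfg.k_max + 1)
    per_k_raw: Dict[int, Dict[str, int]] = {k: {} for k in ks}
    n_with_runs = 0
    for child in child_seeds:
        seq = simulate_telomere(unit, length, model, rng=np.random.default_rng(child))
        contributed = False
        for k in ks:
            tally = _record_tally(seq, k, cfg.threshold)
            if tally:
                contributed = True
                agg = per_k_raw[k]
                for u, n in tally.items():
                    agg[u] = agg.get(u, 0) + n
        n_with_runs += contributed
    table = _table_from_raw(per_k_raw)
    top_repeat, top_count = _top_row(table)
    true_unit = canonical(unit)
    return ConditionResult(
        length=length,
        rate=model.rate,
        n_replicates=n_replicates,
        top_repeat=top_repeat,
        top_count=top_count,
        true_repeat_found=bool((table["canonical_repeat_unit"] == true_unit).any()),
        n_replicates_with_runs=n_with_runs,
        table=table,
    )


@dataclass
class GridSummary:
    """Aggregate view of a full benchmark grid."""

    results: List[ConditionResult]
    n_conditions: int
    n_top_match: int  # conditions whose most abundant unit is the true repeat
    n_true_absent: int  # conditions where the true repeat never appears
    absent_rates: List[float]  # error rates of the absent conditions
    substring_top_fraction: float  # of mismatching tops, fraction that are
    # substrings/near-variants of the true repeat (reported, not asserted)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                r.length,
                r.rate,
                r.n_replicates,
                r.top_repeat if r.top_repeat is not None else "",
                r.top_count,
                str(r.true_repeat_found).lower(),
            )
            for r in self.results
        ]
        return pd.DataFrame(rows, columns=GRID_COLUMNS)


def _is_substring_variant(top: str, true_unit: str) -> bool:
    """Is ``top`` a rotation-aware proper substring or 1-edit variant of
    the true unit (or of its dimer)?"""
    doubled = true_unit * 2
    rc_doubled = reverse_complement(true_unit) * 2
    if len(top) < 2 * len(true_unit) and (top in doubled or top in rc_doubled):
        return True
    # one-edit near-variants of any rotation
    for ref in (doubled, rc_doubled):
        for i in range(len(true_unit)):
            rot = ref[i : i + len(true_unit)]
            if _edit1(top, rot):
                return True
    return False


def _edit1(a: str, b: str) -> bool:
    if abs(len(a) - len(b)) > 1:
        return False
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b)) <= 1
    if len(a) > len(b):
        a, b = b, a
    for i in range(len(b)):
        if a == b[:i] + b[i + 1 :]:
            return True
    return False


def run_grid(
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    rates: Sequence[float] = DEFAULT_RATES,
    n_replicates: int = DEFAULT_REPLICATES,
    cfg: ExploreConfig = ExploreConfig(4, 12, 50),
    seed: int = 0,
    unit: str = DEFAULT_UNIT,
    sub_frac: float = 1.0 / 3.0,
    ins_frac: float = 1.0 / 3.0,
    del_frac: float = 1.0 / 3.0,
) -> GridSummary:
    """Run the full lengths x rates benchmark grid.

    One :class:`ConditionResult` per (length, rate), plus the two headline
    statistics: in how many conditions the most abundant canonical unit is
    the true repeat, and in how many the true repeat is entirely absent
    from the output.  Bit-reproducible given ``seed``.
    """
    master = np.random.default_rng(seed)
    cond_seeds = master.integers(0, 2**31 - 1, size=len(lengths) * len(rates))
    true_unit = canonical(unit)
    results: List[ConditionResult] = []
    i = 0
    for length in lengths:
        for rate in rates:
            model = ErrorModel(
                rate=rate,
                sub_frac=sub_frac,
                ins_frac=ins_frac,
                del_frac=del_frac,
                seed=int(cond_seeds[i]),
            )
            results.append(run_condition(unit, length, model, n_replicates, cfg))
            i += 1
    n_top = sum(r.top_repeat == true_unit for r in results)
    absent = [r for r in results if not r.true_repeat_found]
    mism = [r for r in results if r.top_repeat is not None and r.top_repeat != true_unit]
    frac = (
        sum(_is_substring_variant(r.top_repeat, true_unit) for r in mism) / len(mism)
        if mism
        else float("nan")
    )
    return GridSummary(
        results=results,
        n_conditions=len(results),
        n_top_match=n_top,
        n_true_absent=len(absent),
        absent_rates=[r.rate for r in absent],
        substring_top_fraction=frac,
    )


def mix_sensitivity(
    mixes: Dict[str, Tuple[float, float, float]] | None = None,
    **grid_kwargs,
) -> pd.DataFrame:
    """Re-run the grid under several error-event mixes (sensitivity table).

    Default mixes: the uniform reference, substitution-only, indel-only and
    a substitution-heavy profile.  Returns one row per mix with the two
    headline grid statistics.
    """
    if mixes is None:
        mixes = {
            "uniform": (1 / 3, 1 / 3, 1 / 3),
            "sub_only": (1.0, 0.0, 0.0),
            "indel_only": (0.0, 0.5, 0.5),
            "sub_heavy": (0.8, 0.1, 0.1),
        }
    rows = []
    for name, (s, ins, d) in mixes.items():
        summary = run_grid(sub_frac=s, ins_frac=ins, del_frac=d, **grid_kwargs)
        rows.append((name, s, ins, d, summary.n_top_match, summary.n_true_absent))
    return pd.DataFrame(
        rows,
        columns=["mix", "sub_frac", "ins_frac", "del_frac", "n_top_match", "n_true_absent"],
    )


# ---------------------------------------------------------------------------
# synthetic fixtures


def alternating_array(unit_a: str, unit_b: str, n_pairs: int) -> str:
    """A higher-order-repeat-like array alternating two units n_pairs times."""
    return (unit_a + unit_b) * n_pairs


def synthetic_assembly(
    n_records: int = 10,
    n_both_ends: int = 8,
    record_length: int = 20_000,
    telomere_length: int = 2_000,
    unit: str = DEFAULT_UNIT,
    seed: int = 0,
) -> List[SequenceRecord]:
    """A toy assembly with telomeric arrays stitched onto chromosome ends.

    ``n_both_ends`` records carry an array at both ends (complete
    pseudomolecules); the remainder carry one only at the 5' end
    (assemblies locally incomplete at the other telomere).  The 5' array is
    the C-rich strand (reverse complement of ``unit``), the 3' array the
    G-rich strand, as on a real chromosome.  Record lengths are staggered
    so length ordering is unambiguous.
    """
    if not 0 <= n_both_ends <= n_records:
        raise ValueError("n_both_ends must be between 0 and n_records")
    rng = np.random.default_rng(seed)
    five_prime = (reverse_complement(unit) * (telomere_length // len(unit) + 1))[:telomere_length]
    three_prime = (unit * (telomere_length // len(unit) + 1))[:telomere_length]
    records = []
    for i in range(n_records):
        length = record_length + (n_records - i) * 997  # staggered, distinct
        body_len = length - telomere_length * 2
        body = _BASES[rng.integers(0, 4, size=body_len)].tobytes().decode("ascii")
        if i < n_both_ends:
            seq = five_prime + body + three_prime
        else:
            seq = five_prime + body + _BASES[
                rng.integers(0, 4, size=telomere_length)
            ].tobytes().decode("ascii")
        records.append(SequenceRecord(id=f"chr_{i + 1}", seq=seq))
    return records
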