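# Methods

## Repeat model and canonicalisation

A telomeric repeat array is modelled as tandem copies of a short unit over
{A,C,G,T}. Because an array can be entered in any phase and assembled on
either strand, a unit is identified only up to rotation and reverse
complement. The canonical representative is the lexicographically smallest
string (plain byte order on uppercase ASCII, so A < C < G < T) among the
2k candidates formed by the k rotations of the unit and the k rotations of
its reverse complement. The minimal rotation is computed with Booth's
O(k) algorithm and the package verifies it against exhaustive enumeration
in the test suite. Canonicalisation is undefined for units containing
non-ACGT characters; callers must exclude them (the discovery scan does).

A unit that is an exact multiple of a shorter unit (AACCCTAACCCT) is a
legitimate unit at its own length and is never reduced to its primitive
root: when a k range includes both 6 and 12, a pure 6-periodic array
reports both the 6-mer and its dimer, the dimer at half the unit count.
Collapsing multiples is left to the reader of the table, who can recognise
dimers by inspection.

## Discovery scan

For each k in the configured range, each sequence is cut into
non-overlapping chunks `seq[0:k], seq[k:2k], …` (trailing remainder
ignored; the chunking frame is fixed at offset 0 and no phase-shifted
rescans are made — a frame shift between two arrays splits them into runs
of rotated units, which the canonical merge re-unites, so rescans would
only double-count). Identical consecutive chunks are collapsed into
maximal tandem runs; a chunk containing any non-ACGT character terminates
the current run and never joins one. Each chunk is compared once to its
predecessor, so the scan performs at most ⌊n/k⌋ comparisons per sequence.
A vectorised (numpy) path is used internally for long sequences; the test
suite asserts it is result-identical to the scalar single-pass reference.

Runs with at least `threshold` units contribute their **unit count** to
the tally of their unit ("how many repeat copies sit in qualifying runs"),
not a run count of 1 — the unit count is what makes the output a relative
abundance that weights long telomeres appropriately. Tallies are merged
under canonical equivalence per k, summed over records (the result is
invariant to record order), and emitted sorted by k ascending, count
descending, then unit.

Parameters:

| parameter | default | meaning |
|---|---|---|
| `k_min`, `k_max` | required (CLI recommends 4–15) | unit lengths scanned; nearly all known telomeric units are < 15 bp |
| `threshold` | 100 (CLI); 50 in the benchmark | minimum run length in units; at k=6, 100 units = 600 nt of perfect array. A conservative threshold also suppresses the O(m²) canonical-merge cost over m distinct keys. Lower it if nothing is reported |

## Windowed motif search

All exact occurrences (overlapping included) of the motif and of its
reverse complement are located and binned by start offset into windows of
`window` nt (default 10,000 — a package convention, stated as such in the
CLI help) tiling the sequence from 0; the final partial window is emitted
when non-empty. Matches spanning a boundary are not split, so window
counts partition the occurrence list exactly — an invariant the tests
assert. Coordinates are 0-based half-open; `window_end` is the exclusive
end, numerically equal to the 1-based inclusive end used by genome
browsers. Python's built-in substring search (the two-way algorithm,
linear time for these short motifs) locates occurrences; any
all-occurrences matcher is observationally equivalent.

## Clade database

A small TSV (`clade`, `repeat`, `n_species`, `note`) of canonical repeats
per clade, seeded from the Darwin Tree of Life survey of chromosomally
complete assemblies, ships inside the package; `build` copies it (or a
user-supplied, validated table) to `~/.local/share/telokit` (override with
`TELOKIT_DATA_DIR`). Loading validates that every repeat equals its own
canonical form and that (clade, repeat) pairs are unique
case-insensitively — a clade may legitimately carry several repeats
(Bombus: AACCCG, AACCT, AACCCT), so uniqueness is on the pair, and `find`
emits one output table per repeat. Failed lookups suggest names within
edit distance 2.

## Plots

Pure SVG 1.1 with inline styling, no timestamps and no generated ids:
identical input yields byte-identical output. One track per sequence,
ordered by descending sequence length (length = end of the last window)
with ties broken by id, capped at `max_tracks` (default 25). Each track
draws one polyline of forward + reverse counts per window (vertex at the
window midpoint), scaled linearly to the track's own maximum (minimum 1,
so an all-zero track draws a flat baseline). Colours and margins are
cosmetic, not part of any contract.

## Error simulation and the benchmark grid

`simulate_telomere` tiles a unit to exactly the requested length
(truncating the last copy), then visits each position independently: with
probability `rate` the position receives exactly one event, chosen by the
(sub, ins, del) mix — substitution to a uniformly random *different* base,
insertion of a uniformly random base after the position, or deletion.
Defaults: uniform mix (1/3 each), since no platform-specific profile is
assumed. All randomness flows from numpy `SeedSequence` spawning, so a
single integer seed makes every replicate of every condition reproducible.

The generator emulates the one property of real telomeres that the
discovery algorithm is sensitive to — long tandem arrays corrupted by
sequencing error — and nothing else: no quality strings, no
platform-specific indel clustering, no subtelomeric degenerate repeats, no
higher-order repeat (HOR) mixtures beyond a simple two-unit alternation
helper for fixtures. Passing the benchmark therefore demonstrates
robustness to homogeneous per-base noise, not to structured telomere
variation.

The benchmark grid crosses lengths {600, 12,000, 30,000} nt with per-base
rates {0, 0.1, 1, 1.5, 2, 5, 10}% — 21 conditions. The reference harness
analyses each condition's replicates as one pooled multi-record input with
k 4–12 and threshold 50 (the k range brackets the 6-mer, its dimer and its
period-shifted substrings; the threshold follows the "50+" guidance
above). "Most abundant" compares counts across all k jointly; ties break
to the lexicographically smallest unit. The library default is 1,000
replicates per condition; `scripts/acceptance.py` uses 200, which is
enough to resolve the condition-level outcomes that are the quantity of
interest.

With seed 1 at 200 replicates the script computes: the most abundant
canonical unit equals the simulated AACCCT in **16/21** conditions, and
AACCCT is absent from the output in **5/21**, all at rates ≥ 2% (600 nt
and 12,000 nt arrays at 5% and 10%, and 30,000 nt at 10%). The two
statistics are complementary by construction under this error model:
because errors strike positions independently, any run that survives the
threshold is a rotation of the true unit, so wherever the repeat is found
at all it is also the top unit. Promoting a substring artefact (e.g.
ACCCT above AACCCT) would require ≥ 250 nt of 5-periodic sequence, which
independent per-base events essentially never produce — that failure mode
needs correlated errors, e.g. a corrupted unit tiled into an array. The
script's sensitivity table makes the same point empirically: sub-only,
indel-only, indel-free and uniform mixes all give identical headline
counts, since a run is broken by *any* event inside a chunk regardless of
type. The absent count sits on a knife edge at one condition (30,000 nt
at 5%: the probability that some replicate contains 50 consecutive
event-free chunks is ≈ 0.1 per grid run), so t2 varies between 5 and 6
with the seed.

## Numerical and degenerate-input choices

- Empty FASTA stream → empty explore table; empty record → no search rows;
  empty window table → `plot` error ("nothing to plot").
- Lowercase input is folded to uppercase at the FASTA reader and at the
  search motif; case never reaches the algorithms.
- Event fractions must sum to 1 within 1e-9; error rate is clamped to
  nothing — it must be a probability.
- Tie-breaks are total and deterministic everywhere: explore sorting
  (k, −count, unit), benchmark top unit (−count, unit), plot track order
  (−length, id).
- CLI outputs never overwrite existing files without `--force`; logs go to
  stderr, data to stdout or files.

## Known limitations

- Higher-order repeats defeat chunk-level run detection: an alternating
  AACCT/AACCCG telomere yields few runs of any single unit, and the true
  compound unit is only visible at larger k if its period divides k.
- Non-repeat telomeres (retrotransposon-based ends, as in drosophilids)
  are invisible to this approach by design.
- The scan never restricts itself to sequence ends; interstitial telomeric
  repeats count toward discovery tallies.
- The simulator's independence assumption is optimistic for real long-read
  error processes, which cluster indels in homopolymers; see above for
  what this implies about the benchmark.
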