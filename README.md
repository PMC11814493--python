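# telokit

Identify, search for and visualise **telomeric repeats** in genome
assemblies and long reads.

Telomeres — the ends of eukaryotic chromosomes — are built from short,
G-rich units (TTAGGG in vertebrates, TTAGG in most arthropods, TTTAGGG in
flowering plants) repeated in tandem for hundreds to thousands of copies.
Whether an assembled chromosome reaches its telomeres is a standard
completeness check for modern (telomere-to-telomere) assemblies, and for
many clades the repeat unit itself is unknown and must be discovered de
novo. telokit is aimed at genome assemblers and curators who need to
answer two questions quickly: *what is the telomeric repeat of this
organism?* and *does each pseudomolecule end in it?*

## The algorithm

**De-novo discovery (`explore`).** Each sequence is scanned once in
non-overlapping chunks of size *k* (frame fixed at offset 0). Maximal
groups of ≥ 2 identical consecutive chunks are collapsed into tandem runs;
runs with at least `--threshold` units are tallied (the tally is the number
of repeat units, so long arrays dominate). Tallies are then merged under
**canonical equivalence**: the canonical form of a unit *u* is

```
canonical(u) = min over lexicographic order of
               { all rotations of u } ∪ { all rotations of revcomp(u) }
```

so TTAGGG, GGGTTA and CCCTAA all report as AACCCT. The minimal rotation is
found with Booth's linear-time algorithm. The scan is O(n) per *k*; an
indel inside a telomere merely splits one run into two runs of rotated
units, which the canonical merge re-unites. Repeat discovery is usually
run over a range of k (4–15 covers almost every known telomeric unit).

**Known-motif search (`search`, `find`).** Every (including overlapping)
exact occurrence of a motif and of its reverse complement is counted in
fixed-width windows tiling each sequence; `find` first looks the motif up
in a bundled clade → repeat table (Chordata → AACCCT, Arthropoda → AACCT,
Magnoliopsida → AAACCCT, Vespidae → AACCCAGACCC, Bombus → a compound
AACCCG/AACCT/AACCCT landscape) and then searches for each repeat.

**Visualisation (`plot`)** renders the window-count TSV as a deterministic
SVG: one track per sequence (longest first), one line of
forward + reverse counts per window. A complete chromosome shows a peak at
each end of its track.

**Benchmarking (`simulate-grid`)** simulates telomeric arrays of 600,
12,000 and 30,000 nt with independent per-base errors (substitution /
insertion / deletion) at rates 0–10% and measures how well `explore`
recovers the simulated unit.

## Worked example

Build a toy 3-chromosome assembly (two complete, one missing a telomere)
and discover its repeat:

```bash
telokit explore toy.fasta --minimum 4 --maximum 12 --threshold 50
```

```
canonical_repeat_unit	kmer_length	count
AACCCT	6	998
AACCCTAACCCT	12	498
```

The 6-mer AACCCT (canonical form of TTAGGG) dominates with 998 tandem
units across the assembly; the 12-mer row is its dimer — every 6-periodic
array is also 12-periodic, at half the unit count — and is read as the
same repeat. Now count the motif in windows and plot:

```bash
telokit search toy.fasta --string TTAGGG --window 2000 | head -6
```

```
id	window_start	window_end	forward_repeat_number	reverse_repeat_number
chr_1	0	2000	0	201
chr_1	2000	4000	0	1
chr_1	4000	6000	0	0
chr_1	6000	8000	0	1
chr_1	8000	10000	2	0
```

The first window holds ~200 reverse-strand copies (the 5′ telomere is the
C-rich strand, so TTAGGG is found reverse-complemented); interior windows
show only background. `telokit find toy.fasta --clade Chordata` gives the
same picture without knowing the motif, and

```bash
telokit search toy.fasta --string TTAGGG --window 1000 -o toy
telokit plot --tsv toy.search.tsv -o toy.svg
```

writes an SVG with one track per chromosome — telomere peaks at both ends
of complete molecules, a single peak on the incomplete one.

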