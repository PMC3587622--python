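# Methods

This note documents the models and procedures implemented in `barkit`, the
defaults they ship with, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Distance kernels

All measures are unit-cost Levenshtein variants (substitution, insertion,
deletion each cost 1; no affine gaps).

**Plain edit distance** `levenshtein(a, b)`.  An `N` in a read matches
nothing — it costs one edit against every base, including another `N`.
This is deliberately conservative: a no-call should push a read toward
*ambiguous*/*unmatched*, never rescue a match.  For N-free inputs the
computation is delegated to edlib's bit-parallel algorithm; a reference
dynamic program defines the semantics and handles the N-vs-N case.

**Padded distance** `padded_distance(a, b, P)` flanks *both* sequences
with `P` wildcard positions on each end before the DP.  A wildcard column
is free whether the wildcard aligns to a base or to a gap.  This makes the
design metric tolerant to frame shifts: `"ACGTAC"` vs its one-base rotation
`"CGTACA"` is distance 2 plain but 0 at `P = 1`, which is exactly the kind
of pair an indel-robust design must exclude.  Padding both sequences keeps
the measure symmetric.  `P = 0` reduces to plain distance, and the padded
value never exceeds the plain one.

**Semi-global alignment** `semi_global_align(barcode, window)` requires
every barcode base to be aligned while the window's flanks are free; the
distance equals the minimum plain distance between the barcode and any
substring of the window.  Ties on distance are broken by smallest alignment
offset, then fewest indel columns, making the reported edit columns
(`mismatch_positions`, one window position per edit) a pure function of the
inputs — required for reproducible quality tie-breaking.

## Barcode design

Generation is greedy randomized search.  Candidates are drawn uniformly
among sequences of length `L` whose G+C count lands in the configured GC
window (the count is drawn uniformly from the admissible integers, then
placed uniformly), screened by the filter chain, and inserted first-fit.

Filter chain, in fixed evaluation order (the first failure is reported, so
rejection tallies are deterministic): GC content; homopolymer run;
di-nucleotide and tri-nucleotide tandem repeats; 3-mer complexity;
forbidden motifs on either strand; edit distance to the sequence's own
reverse complement; hairpin/self-dimer melting temperature; primer
cross-hybridisation melting temperature.

Defaults for length-18 tags: GC in [0.45, 0.65]; homopolymer ≤ 4; di-/tri-
mer tandem copies ≤ 3; complexity ≥ 0.5; reverse-complement distance and
pairwise threshold `d_min` = 4; self-/cross-hybridisation Tm ≤ 50 °C.
The complexity score is the fraction of distinct overlapping 3-mers among
the `L−2` windows: cheap, monotone with linguistic complexity, and low
exactly for the repeat-degenerate sequences the repeat filters target from
another angle.  The repeat-copy limits and the complexity floor are this
package's choices; they reject only a few percent of random candidates
while removing the pathological ones.

**Strict distance acceptance.** A candidate is accepted only if its padded
distance to every accepted barcode is *strictly greater* than `d_min`, so a
finished set has all pairs at distance ≥ `d_min + 1`.  This is what makes
the error-correction claim exact: with `d_min = 4`, pairs are at distance
≥ 5 = 2·2+1, and a read with ≤ 2 errors can never tie between two barcodes
— the zero-ambiguity behaviour the benchmarks show is a theorem, not luck.
Equivalently, tolerated errors = `⌊d_min/2⌋`.

The screen is exact but cheap: a banded plain distance (edlib) prunes
pairs first.  Since deleting the `4P` wildcard columns from an optimal
padded alignment costs at most one edit each,
`levenshtein ≤ padded + 4P`, so any pair with plain distance
`> d_min + 4P` passes without running the padded DP.

Candidate generation and set insertion are independent stages; the scan of
the accepted set is a conjunction over pairs, so it may be partitioned
freely without changing any accept/reject outcome.  The default
single-worker mode screens candidates in strict arrival order from the
seed, making a run bit-reproducible.  Exhausting the attempt budget
(default `1000 × count`) returns the partial set plus a report (attempts,
per-filter rejection tally, distance rejections) — impossible constraint
combinations terminate, they do not loop.

## Thermodynamic screen

The design intent is a reject/accept gate against a Tm threshold, not
structure prediction.  The screen enumerates all perfectly complementary
ungapped stems: hairpin decompositions (stem ≥ 3 bp, loop ≥ 3 nt; sequences
shorter than 8 nt cannot close a scored hairpin and are structure-free by
definition) and all antiparallel registers of the sequence against itself
(self-dimer) or against a primer (cross-dimer).  Each stem is scored with
unified nearest-neighbor ΔH/ΔS sums and a two-state melting temperature at
50 mM monovalent salt and 0.25 µM strand concentration (Biopython's
`Tm_NN`, DNA_NN3 table); the maximal-Tm structure is compared against the
threshold.  Structure-free sequences carry a `Tm = −∞` sentinel and always
pass.

Limitations, accepted by design: no bulges, internal loops or
minimum-free-energy folding; hairpins are scored with the bimolecular
two-state formula rather than a unimolecular loop-entropy model.  On the
extremes that matter the gate behaves correctly — a 10 bp GC stem melts
above 50 °C and is rejected, random stem-free 18-mers pass — and that
threshold behaviour, not absolute Tm accuracy, is what the tests pin down.

## Demultiplexing

For each read a window `[start − pe, start + L + pe)` is extracted
(`pe` = positional error; `pe = −1` scans the whole read, slower and less
specific).  The k-mer index proposes candidates; candidates sharing more
k-mers with the window are aligned first, which lets a banded
distance-only pass (edlib, band = current best) prune the rest cheaply.
Full alignments with edit columns are computed only for the final
minimal-distance ties.  Decision rule, with acceptance cut-off
`max_distance` (default `⌊d_min/2⌋`, the largest cut-off the design
guarantee covers):

* no candidate within the cut-off → **unmatched**;
* unique minimal-distance candidate → **matched**;
* ties → quality tie-break: sum the read's Phred scores at each
  candidate's edit columns; a unique lowest sum wins (its edits sit on the
  least trustworthy bases), otherwise **ambiguous**.

A read equidistant from two barcodes under uniform qualities is therefore
never matched.  Design-time padding needs no counterpart in the aligner:
with free window flanks, a wildcard flank column can always be had at zero
cost, so padded and unpadded semi-global distances coincide — the
`padding` parameter matters at design time and is accepted at demux time
only to mirror the design configuration.

One consequence of free-flank alignment is worth naming: at `pe = 0` with
an unpadded design, a substitution-only read can in rare configurations
tie two barcodes through a flank-trimmed (indel-like) alignment that the
unpadded design metric does not exclude.  Such reads are reported
ambiguous — of the order of 0–2 per 50,000 in the benchmark below.
Designing with padding removes the underlying pair geometry.

Classification is per-read and order-independent; `--threads` partitions
the work and output is restored to input order, so results are identical
at any thread count.  Paired-end input is classified on read 1 and the
mate inherits the assignment.  Matched FASTQ records carry
`+BC:<sequence> ID:<id> ED:<distance>` on the separator line (this
package's layout).  Coordinates are 0-based, intervals half-open;
qualities are Sanger Phred+33.

## Read simulation

Each simulated read picks a barcode uniformly, places it at the configured
start (flanks, if any, are uniform random bases), then walks the sequence
applying independent per-base events: deletion first, then substitution
(to a uniformly chosen *different* base), then insertion of a uniform base
after the current one.  "2% error" means per-base and independent; in
mixed mode the total is split 80/10/10 among substitution, insertion and
deletion (each rate also individually settable).  Read length defaults to
the barcode length — bare-barcode reads, the hardest case for
demultiplexing since there is no anchoring context.  Qualities are
constant Q30 so that quality tie-breaking is exercised by dedicated
fixtures, not by simulation noise.  Indels change read length; reads are
not re-trimmed.

What the simulator does **not** model: position-dependent or
platform-specific error profiles, quality-correlated errors, GC bias, PCR
duplicates, chimeras.  Passing benchmarks on this generator demonstrates
the combinatorial/geometric claims (distance guarantee, q-gram recall,
tie handling) under the stated error rates; they do not certify accuracy
on any particular instrument's error spectrum.

## Benchmark scale and acceptance script

`scripts/acceptance.py` runs two experiments end to end at desk scale,
chosen to finish in minutes on one CPU while keeping the binomial error
counts large enough to be meaningful (50,000 reads ≈ 18,000 erroneous
bases at 2%): 2,000 barcodes / 50,000 substitution-only reads (k=6,
`pe=0`), and 1,000 padding-1 barcodes / 50,000 mixed-error reads (k=6,
`pe=1`); both with `L=18`, threshold 4, cut-off 2.  It reports the
percentage of wrongly classified and of ambiguous reads per experiment.
The accuracy trend with k (larger k → faster but lossier retrieval once
two errors can cover every window) is asserted separately in the test
suite in cut-off-free best-hit mode, where index misses surface as wrong
or not-uniquely-classifiable assignments instead of silent unmatched
reads, averaged over three simulation seeds.

## Known limitations

* Greedy first-fit gives no maximality claim: the set size achievable at a
  given (L, d_min) is explored, not optimised.
* The thermodynamic gate is a screen (see above), not a folding engine.
* Only Sanger Phred+33 qualities are handled.
* The barcode is not trimmed from output reads, and no sample-sheet or
  BAM/SAM handling is provided.
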