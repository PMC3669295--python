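# Methods

## Index

The reference sequences are concatenated with one sentinel per
sequence. Sentinels compare below `A < C < G < T` and are pairwise
distinguished by sequence order during suffix sorting, so the suffix
array is well defined for any number of sequences; the ACGT occurrence
counts that drive backward search are unaffected by the sentinels'
relative order, and the few BWT rows whose preceding character is a
sentinel carry their suffix-array values explicitly so that `locate`
never needs an LF step through a sentinel. The suffix array is built by
Manber–Myers prefix doubling (numpy `lexsort`), O(n log² n), which is
comfortable up to tens of megabases on one core; an induced-sorting
construction could be substituted without any API change.

The occurrence table is sampled at one level only, every 128 BWT
positions (a lookup adds the checkpoint to a short scan of the
remaining block). Suffix-array values are kept at every 1st, 2nd or 4th
rank (`sa_stride`); a sparser SA costs extra LF steps per `locate` but
never changes any result, and the test suite asserts byte-identical SAM
bodies across the three strides.

Ambiguity codes: an isolated `N` in the reference is replaced by a
pseudo-random base from a fixed seed (the index alphabet must stay
4-letter); runs of ≥ 10 consecutive `N`s are additionally recorded as
masked intervals and alignments overlapping them are suppressed. `N` in
a read is treated as a mismatch at every position.

## Step-1 mismatch search

`all_best_mismatch_search` returns exactly the both-strand hits whose
mismatch count equals the minimum achievable m\* ≤ k (default k = 2,
valid 0–4). The default route is pigeonhole case splitting: the read is
cut into k+1 contiguous segments; any placement with ≤ k mismatches
leaves at least one segment exact, so exact backward search of each
segment followed by whole-read verification against the packed
reference enumerates every hit. An exhaustive branch-and-bound backward
search over SA ranges (`method="branch"`) implements the same contract
independently and serves as its oracle in the tests.

**Complexity stratification.** Reads are graded into three effort tiers
by the number of live SA ranges observed while the search runs; with
the all-best output mode and k = 2 the tier thresholds are 4 and 32,
with strict "exceeds" semantics. What exactly counts as a live range is
an interpretation made here: the deterministic exact-segment extension
phase involves no branching and contributes nothing, while in the
subsequent mismatch-budgeted extension each distinct surviving
placement counts as one live range (identical placements tracked by
different cases are deduplicated). Under this definition a read unique
in a 100 kb genome stays within 4 live ranges (tier 1), while a
homopolymer read over dozens of planted sites exceeds 32 (tier 3). A
read whose count exceeds the active tier's threshold is suspended at
that extension and re-run in the next tier (the last tier is uncapped);
tiers therefore affect scheduling only, and the hit set is provably
identical with stratification on or off — asserted by test.

## Fit-alignment DP

Given candidate region T (length m) and read R (length n), the score of
the best alignment of all of R against any sub-region of T is computed
with the three coupled tables M, I, D given in the README. Base cases:
`M(i,0) = 0` (the fit may start anywhere in T), `M(0,j) = -(S_GO +
S_GE·j)` (leading read bases as one insertion run), `I(i,0) = D(0,j) =
-∞`. The result is `max_i M(i,n)`; among equal scores the smallest end
position is reported. There is no soft clipping: the CIGAR consumes the
read end to end.

Two implementations share one traceback (which needs only the M table —
the reason table I can be dropped):

* three-table: per inner iteration 7 stored-table reads (2 for I, 2 for
  D, and M(i−1,j−1) plus the write-backs of I(i,j), D(i,j)) and 3
  writes;
* two-table: the running I value and the diagonal/vertical M values
  (M^u = M(i−1,j−1), M^d = M(i−1,j)) live in per-iteration scalars, so
  only M(i−1,j) and D(i−1,j) are read and M(i,j), D(i,j) written —
  2 reads / 2 writes.

The production path runs numba-compiled kernels; `instrument=True`
switches to pure-Python twins whose tables count every access
(base-case initialisation excluded — it is not inner-loop traffic). The
twins and kernels are asserted equivalent, the two recurrences are
asserted equivalent on 1,000 random instances, and the three-table form
is asserted equal to exhaustive alignment enumeration on instances with
m ≤ 12, n ≤ 8.

Traceback tie-break: diagonal over deletion over insertion. Gap runs
are recovered directly from M (the smallest run length explaining the
score), which can shift an ambiguous gap within a repeat run — e.g. a
deletion inside a `TT` run may surface as `3M1D5M` rather than
`4M1D4M`; both rescore identically and rescoring every emitted CIGAR
is part of the test contract.

**Cost bounding.** Rather than a diagonal band — ill-posed for a fit
alignment whose start row is free — DP problem size is bounded at the
call sites: every candidate or rescue window is the implied read span
padded by `max_gap` on each side, where `max_gap(n) = (S_MA·n − cutoff(n)
− S_GO) / S_GE` is the longest single deletion an otherwise perfect read
could carry (68 bp for n = 100 under defaults). A window that cannot
contain an accepted alignment is never created.

**Acceptance cutoff.** `cutoff(n) = ⌈0.3·n⌉`. The fraction 0.3 is the
unique small-integer-consistent choice that realises the advertised
default tolerance for 100 bp reads (68 bp single gap: score 100−70 = 30 = cutoff; 23 one-bp
gaps: 100−69 = 31 ≥ 30, 24 fails). Insertions consume read bases, so
the same cutoff admits only shorter insertion runs (~33 bp at n = 100);
no special-casing is applied.

## Seeding and candidate regions

Seeds of 25 bp are taken at offsets 0, 25, 50, … along the read and its
reverse complement, plus an end-anchored seed when the last regular
offset stops short; reads shorter than the seed length contribute one
full-length seed per orientation. Seeds are matched exactly; a seed
hitting more than 1,024 loci is discarded before clustering (a poly-A
seed can hit every homopolymer in the genome and would swamp `locate`
long before any later cap applies). Hits are reduced to implied
anchors (hit position − read offset), clustered within a merge window
equal to the DP pad, scored by the number of distinct supporting seeds,
sorted by (support desc, start asc) and cut to the best 30 regions (the
configurable DP effort ceiling). Defaults assume ≥ 50 bp reads: a
100 bp read with one indel and two scattered mismatches always retains
at least one clean 25-mer.

## Pairing

Proper pair = both ends on one reference, orientation as configured
(FR: leftmost mate forward, rightmost reverse; FF: both same strand),
and outermost span — SAM TLEN convention, both reads inclusive — within
[min_insert, max_insert], both bounds inclusive. Step-1 proper pairs are
chosen by maximal combined score, ties by leftmost coordinate then
forward-first. Mate-rescue windows are derived from the anchor
placement and the insert bounds (mirrored for a reverse anchor,
two-sided for FF), clipped to the sequence. Pairs that align on both
ends but never properly are reported individually (`unpair`) without
entering step 3; pairs failing rescue, or with both ends unplaced,
proceed to step 3, where each unresolved end is aligned via seeding +
DP and pairing is re-evaluated per-end (joint insert-constrained region
pairing across mates is a possible alternative design). Single-end mode runs steps 1 and 3 only.

Output categories: pure step-1 proper pairs → `gout`; proper pairs
involving any DP product (steps 2–3) → `dpout`; everything else →
`unpair`. The three files carry identical full headers. The boundary
between "few" and "extensive" mismatches is defined operationally:
routing every DP-produced alignment to `dpout` preserves the
observable invariant that `gout` contains only ungapped, ≤ k-mismatch
records.

## MAPQ

0 whenever ≥ 2 co-optimal placements exist; 60 for a unique placement
with no runner-up; otherwise `min(60, ⌊60·(best − second)/(S_MA·n −
cutoff(n))⌋)`, floored at 1. This scaled-difference rule is a heuristic on the BWA 0–60 scale; the
two hard conventions downstream callers rely on (0 = ambiguous,
high = unique) are preserved exactly, but the value is not a calibrated
error probability. Up to 10 co-optimal alternatives are listed in
an `XA`-style tag.

## Simulator and evaluator

The generator emulates the standard haplotype-resampling protocol used
for aligner benchmarking: i.i.d. uniform ACGT reference (optional
tandem-repeat planting for stressing tier 3 and the seed-hit cap); two
haplotypes with SNPs at 10⁻³ and indels at 10⁻⁴ per base (geometric
lengths with mean 2, capped at 50, insertions and deletions
equiprobable); fragments
with insert ~ N(500, 25²), mates read from opposite ends (FR), first/
second mate orientation randomised; uniform 0.5% substitution error
with constant Q30 quality strings. The truth table maps every read to
its pre-mutation reference coordinate. Identical seeds give
byte-identical output.

What it does not model: coverage and GC bias, position-dependent error
profiles, quality-correlated errors, recombination hotspots, and real
repeat structure. Passing the recovery targets on this generator
demonstrates the pipeline's mechanics (search completeness, rescue,
category accounting), not performance on human data.

The evaluator scores a SAM stream against the truth: correct = mapped
primary record, same reference and strand, leftmost position within
50 bp (inclusive — the boundary choice is ours) of the assigned origin.
Sensitivity = correct / all simulated reads; FDR = incorrect / all
aligned reads, 0/0 defined as 0; a cumulative table of correct and
incorrect counts from high to low MAPQ supports ROC-style plots.

## Problem sizes and defaults

The test suite and acceptance script run on synthetic instances sized
for a single core: 50–100 kb genomes, up to 20,000 pairs of 100 bp
reads at the rates above, 1,000-instance DP equivalence sweeps, and
10×10 instrumentation instances. Batch size in the streaming drivers
affects memory only, never results. All tunables (`max_mismatch`,
`level_thresholds`, seed geometry, `candidate_ceiling`,
`seed_hit_limit`, scoring penalties, `score_cutoff_fraction`,
insert bounds, orientation) are exposed via `AlignParams`,
`ScoringScheme`, `PairConfig` and the JSON config file of the CLI.

## Known limitations

* The k-mismatch search is exact but assumes reads fit entirely within
  one reference sequence; alignments spanning sequence boundaries are
  discarded by construction.
* The live-range trace definition (see above) fixes what counts as a
  branching range; absolute tier populations are specific to that
  definition even where the thresholds agree.
* MAPQ is heuristic; it is monotone in the score gap but not calibrated
  as a posterior error probability.
* Base qualities are ignored by scoring (the DP is quality-agnostic);
  BAM/CRAM output is delegated to external conversion of the SAM text.
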