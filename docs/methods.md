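# Methods

## Triplex prediction model

A DNA:DNA:RNA triplex is modelled at the sequence level: a
single-stranded RNA stretch (TFO) binds the purine-rich strand of
duplex DNA (TTS) through Hoogsteen triplets.  Three motif codes are
supported — R (third strand A/G, antiparallel, triplets G·GC and
A·AT), Y (C/T, parallel, C·GC and T·AT) and M (G/T, either
orientation, G·GC and T·AT).  U is identified with T throughout;
orientation conventions are *parallel* = TFO 5'→3' against the purine
strand 5'→3' and *antiparallel* = TFO 3'→5' against the purine strand
5'→3'.  No thermodynamics, pH-dependent cytosine protonation, or
structural accessibility is modelled: the prediction is purely
combinatorial, which is the standard first-pass abstraction for
genome-scale triplex screens.

### Window semantics

The shared primitive is **maximal-window enumeration** over a boolean
"good position" sequence.  A window `[s, e)` is *valid* when

* `e − s ≥ min_length` (default 35 nt),
* its count of error positions is ≤ `max_error_rate · (e − s)`
  (default 0.10; the comparison carries a `1e-9` absolute slack so
  that, e.g., 4 errors in 40 nt passes a 10% bound exactly),
* an optional guanine-rate bound holds (TFO side only; default
  ≤ 0.20, switchable to a minimum via `guanine_bound_direction`
  because both readings of a "guanine rate 20%" constraint exist in
  the field — both are supported, the permissive maximum is the
  default),
* optionally, no run of consecutive errors exceeds
  `max_consecutive_errors` (unlimited by default).

and *maximal* when neither one-base extension is valid.  All maximal
windows are reported; overlapping maximal windows with different error
counts are all kept (no greedy merging), precisely so that the output
is checkable against an enumerable oracle.

Error positions are: bases outside the motif's third-strand alphabet
(TFO), non-purine bases on the candidate purine strand (TTS), and
invalid triplets (pairing).  N is always an error.  Soft-masked
(lowercase) sequence is uppercased and scanned — the screen treats
repeats as scannable sequence; an interval-based repeat filter can be
applied downstream on the BED output if desired.

### Exactness with sub-quadratic behaviour

Naive enumeration is O(n²) per sequence and infeasible beyond short
inputs.  The production enumerator is exact but prunes with a
pigeonhole argument: any valid window of length `L` contains a run of
at least `A = ceil((1−e)·l / (e·l + 1))` consecutive error-free
positions (its ≤ `e·L` errors split it into at most `e·L + 1` runs,
and the bound is minimised at `L = l`).  Runs of length ≥ A are
*anchors*; sequence without anchors has error density > `1/A` ≥ … > e
on every window, so no valid window exists there.  Summing the flank
error density against the error budget bounds the total length any
valid window can reach beyond the anchors it contains:
`L ≤ C + ((k+1) + e·C) / (1/A − e)` where `C` is the total anchor
content and `k` the number of anchors.  The vectorised per-length
sweep therefore stops at that cap, which makes anchor-sparse sequence
(the run-capped synthetic background, random genomic sequence at
stringent parameters) effectively linear while remaining exhaustive —
the property suite checks equality with a brute-force enumerator on
arbitrary boolean sequences.  On pathologically anchor-dense input
(e.g. a megabase of pure purine) the sweep degrades toward O(n²);
genome-scale index acceleration is out of scope.

### Pairing

Candidate TFO and TTS windows are paired by sliding the shorter window
across the longer at every offset (gap-free, no overhangs), in the
motif's orientation(s).  Within each alignment the same maximal-window
primitive runs on the triplet-validity sequence; each maximal
sub-window of length ≥ `min_length` and violation fraction ≤
`max_error_rate` becomes one hit.  Duplicate hits (identical
coordinates and orientation, reachable through overlapping candidate
windows) are emitted once.  TTS coordinates are always reported on the
+ strand with `purine_strand` recording the tract's strand; hit tables
are sorted by (chrom, tts_start, transcript_id, tfo_start), making
scans deterministic and order-insensitive to FASTA record order.
The guanine bound constrains TFO *candidates*; hits report the guanine
rate of their third-strand stretch but re-apply no bound, since the
paired sub-window is already drawn from a bound-satisfying candidate.

## Feature mapping

Intervals are 0-based half-open everywhere (BED convention);
chromosome names are normalised to the `chr` dialect on comparison.
Three mapping rules are deliberately distinct:

* **Feature frequency** — a PTS counts toward a track when its TTS
  interval overlaps any track interval by ≥ 1 base; once per track,
  possibly toward several tracks (genomic feature classes overlap).
  Frequencies are count / union-footprint, reported per base and per
  Mb; zero-footprint tracks are flagged, never divided.
* **Containment** — peak tracks (TFBS, Hi-C domains) count only when a
  peak lies entirely within a PTS.
* **Metagene profiles** — the PTS *midpoint* (configurable choice;
  the midpoint is the least biased single-point summary for windows of
  varying length) is binned relative to stranded anchors: offset
  `mid − anchor` on +, `anchor − mid` on −, bin
  `floor((offset + window) / bin)` for offsets in `[−window, +window)`;
  `bin` must divide `2·window` exactly.

## Enrichment statistics

The 2×2 chi-square test of independence is computed in closed form
without continuity correction (df = 1); zero margins are a hard error.
Contingency tables default to **base units** (is a base covered by the
PTS footprint × is it covered by the track, with a genome-size anchor);
a region-unit mode exists but requires an explicit background region
set, since a region-level 2×2 has no natural universe otherwise.
Across many tracks, Benjamini–Hochberg q-values are reported alongside
raw p-values.  The random-region baseline places regions uniformly
over all positions where a full region fits (chromosomes weighted by
valid starts), scans each for TTS windows, and reports sites per base
scanned with the Monte-Carlo standard error — the count-per-base
convention matches the per-chromosome frequency tables.

## Co-expression network

Candidate pairs are (lncRNA, gene) combinations where some TTS of the
lncRNA overlaps the gene's promoter interval.  Pearson r is computed
on FPKM values as-is (log2(x+1) is available as an option); the
two-sided p-value comes from `t = r·sqrt((n−2)/(1−r²))` with n−2 df
(scipy's `pearsonr` implements exactly this; a test cross-checks the
closed form).  Edges require `|r| > 0.80` and `p < 0.01`; zero-variance
profiles and pairs absent from the matrices are skipped and logged.
Exports: SIF (`lnc positively_correlates gene`), TSV (lossless
round-trip) and GraphML with r/p edge attributes.

## Synthetic data

The generator produces the full input suite with exact ground truth.
Design choices that make recovery tests structural rather than
statistical:

* **Background run capping.**  Background is i.i.d. uniform ACGT, then
  repaired so that every purine/pyrimidine run (genome) and every
  motif-alphabet run (lncRNAs) is ≤ R, with R derived from the search
  parameters: any window of length L over runs ≤ R contains at least
  `floor(L/(R+1))` errors, and R is the largest value for which that
  floor exceeds the error budget for every L ≥ l (R = 7 at the
  defaults).  Zero-tract genomes therefore yield *provably* zero
  candidates, and every hit on a planted genome must overlap planted
  sequence.  Planted regions are frozen during repair.
* **Budget-exhausted planting.**  Each recoverable planted tract of
  length L carries exactly `floor(e·L)` evenly spread error positions
  (pyrimidines on the purine strand), and its partner TFO carries the
  motif's off-alphabet character at the *same aligned positions* plus
  on both immediate flanks.  One more base would push the TFO window
  over the error budget, so the planted TFO stretch is exactly one
  maximal window; lengths where the one-base extension would land
  exactly on the budget boundary (L ≡ 9 mod 10 at e = 0.1) are not
  drawn.  Because the TFO window never exceeds its tract's window, the
  core-to-core alignment offset always exists and the planted hit is
  recovered at the planted coordinates.
* **Positional truth matching.**  Recall is the fraction of
  recoverable planted pairs (tract length ≥ l) joined by a hit of the
  partner transcript overlapping the tract; precision is the fraction
  of hits whose TTS overlaps a planted tract *and* whose TFO overlaps
  a planted stretch.  Exact-coordinate equality is not demanded: a
  maximal window lawfully extends into flanking background while the
  error budget allows, and planted stretches can legitimately pair
  across motifs (a pyrimidine-motif stretch is locally a valid mixed-
  motif third strand), which are genuine triplexes between planted
  elements, not false positives.
* **Tracks** wrap a chosen exact count (`round(fraction · n_tracts)`)
  of tracts with 20 bp margin; filler intervals never touch planted
  tracts.  The default preset contains every tract in a promoter, half
  in introns, none in CpG islands, giving a planted enrichment
  gradient.
* **Expression** is lognormal: standard-normal log-abundances (sd 0.5,
  a moderate spread chosen so FPKM values are non-negative and
  right-skewed) around per-feature baselines uniform in [0, 3] natural
  log.  Planted pairs share a latent factor whose log-scale
  correlation is calibrated through the lognormal identity
  `rho_log = log(1 + rho·(exp(σ²)−1)) / σ²` so the *FPKM-scale*
  Pearson correlation targets the requested rho; null profiles are
  independent.

What the generator does **not** emulate: real base composition and
repeat-family sequence (tracks are positional stand-ins), transcript
splicing structure, expression heavy tails beyond lognormal, and
correlated null structure (batch effects).  Passing recovery tests
therefore demonstrate algorithmic correctness under controlled
conditions, not performance on real genomes.

## Problem sizes and numerical choices

The test and acceptance workloads use a 100-kb single-chromosome
genome with 20 planted tracts (30–60 nt) and 50 transcripts
(500–1500 nt); oracle-equivalence fuzzing uses 200 sequence pairs of
24–80 nt across all three motifs and the grid l ∈ {10, 20, 35},
e ∈ {0, 0.1, 0.2}; the random baseline uses 1000 regions of 1000 bp;
network calibration uses 500 planted pairs at n = 100 samples and
analytic-vs-observed null comparisons at n = 50 and n = 10.  These
sizes exercise every code path at full strength while keeping the
suite fast.

Floating-point policy: all count-vs-rate comparisons use a `1e-9`
absolute slack on the count side, identically in the scanner and in
the brute-force test oracle, so boundary cases (10% of 40) are
well-defined.  Degenerate inputs fail loudly: empty margins in the
chi-square, zero-variance expression rows, malformed BED lines (with
line numbers), duplicate FASTA ids, bin widths that do not divide the
metagene window.  Statistical recovery guarantees are stated at
rho = 0.9 with threshold 0.8 at n = 100, where the pass probability
per planted pair is ≈ 0.9999; at rho = 0.85 the Fisher-z sampling
spread alone caps the per-pair pass rate near 94%, so no generator or
threshold setting can promise ≥ 95% there — a limitation of the
threshold/sample-size combination, not of the implementation.

## Limitations

Correctness-first design: no q-gram index, no multithreaded scan
(a `threads` knob is accepted for interface parity; results are
independent of it), genome-scale (gigabase) inputs are out of scope.
The screen predicts *potential* sites; biophysical validation,
R-loop competition, chromatin accessibility and expression context are
outside the model.
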