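# Methods

This note records the models implemented by `readscrub`, the defaults and
why they were chosen, what the synthetic-read generator does and does not
emulate, and the numerical/design decisions made where the problem left
room.

## Read model and coordinates

A read is a sequence over {A,C,G,T,N} with optional per-base Phred scores
and a *clean interval* `[start, end)` in 0-based half-open coordinates of
the original sequence.  Every stage narrows this interval (or discards the
read with a named reason) and appends `(stage, before, after)` to a trim
log; intervals in the log are therefore nested.  Bases are physically
removed only at write-out.  Virtual trimming makes stage effects separable
for QC and makes the whole pipeline auditable from the log alone.

`N` matches nothing, including another `N` — an uncalled base can never
be evidence for a contaminant, so it always counts as a mismatch.

## Barcode matching

Barcodes are matched with a semi-global dynamic program: the barcode must
be consumed in full, the read suffix is free, and mismatch/insert/delete
all cost 1 (no gap-open penalty; there is no biological reason to treat a
1-base 454 homopolymer slip as more than one error).  `read_end` is the
shortest prefix achieving the minimum, so ties trim conservatively.  The
DP is evaluated row-wise with a vectorised insert-closure
(`min-accumulate` over candidate costs), and only the first
`len(barcode) + max_errors` read bases are scanned — a within-budget
alignment can never consume more.

Defaults: `max_errors = 2` (one 454 homopolymer slip plus one miscall on a
10-mer MID while still separating tags at pairwise edit distance ≥ 5),
`require_barcode = true`, `max_offset = 0` (tags are ligated at the very
5' end; an offset search is available but off).

Two distinct barcodes tied at the minimal error count discard the read as
`ambiguous_barcode` rather than picking arbitrarily; the QC report counts
these separately so a protocol with confusable tags is visible.

## Seed-and-extend contaminant search

Adapters, primers and vectors are located with an exact shared-word seeder
(word size configurable, generic default 11) followed by banded
Needleman–Wunsch extension.  Co-diagonal seeds are merged into candidate
regions; each region is extended to both subject ends inside a diagonal
band (half-width 5, enough for two uncorrelated indels across a ≤ 30 bp
subject).  Scoring is match +1 / mismatch −1 / gap −2 with penalty-free
unaligned ends on both sequences; the traceback starts at the best-scoring
cell and, on ties, prefers the longest extension so zero-net terminal
columns (a trailing match+mismatch) stay aligned — dropping them erodes
hit boundaries by 2–3 bp at contaminant junctions and misclassifies reads
under realistic error rates.  Reverse-orientation search always
reverse-complements the *subject*, keeping read coordinates stable.

The pipeline default word size is 9 rather than the seeder's generic 11:
for a subject of length L a single substitution erases every w-mer seed
when 2w − L > 0, and the shortest common adapters are ~19 bp, giving an
11-mer seeder a 3-base blind spot per adapter that alone costs several
percent of reads their correct classification.  With w = 9 no single error
can unseed any subject ≥ 18 bp, while random 9-mer collisions are still
filtered out by the identity criteria below.

## Middle vs end acceptance criteria

A hit whose read interval starts within `end_zone` of the clean 5'
boundary, or ends within `end_zone` of the 3' one, is judged as an *end*
match, otherwise as a *middle* match.  Middle matches must be near-perfect
(`aln_len ≥ 15`, `pid ≥ 94`): an isolated internal primer copy with real
sequencing errors still clears 94% identity, while chance 9–12 bp
collisions fail the length floor.  End matches may be partial and are
gated by `pid ≥ 90`, subject overhang past the read end ≤
`len(subject) − 8` (at least eight subject bases must align — an end match
on less is indistinguishable from chance), and read overhang outside the
hit toward that end ≤ 2.  `end_zone` defaults to the read-overhang
allowance + 3.  These numeric defaults are this package's documented
choices; the criteria themselves (near-perfect middle matches, partial end
matches bounded by identity and unaligned-base counts) are the method's
contract.

## Error taxonomy and trimming policy

Classification uses amplification-primer hits only.  Precedence when
several patterns apply is `RF > fr > NF > NR > SF > RE`: concatenation and
misorientation (`RF`, `fr`) are unrecoverable library artifacts and
dominate; multiplicity (`NF`, `NR`) beats boundary defects (`SF`, `RE`).
A hit counts as "flush" with an end if at most `classify_flush_tol = 3`
read bases separate them — strict zero would let a single junction
sequencing error reclassify an ordinary read as `SF`/`RE`, whereas real
structural defects insert many more bases.

Actions are configurable per type: `RF`/`fr` discard (default), the rest
salvage the longest hit-free sub-interval (ties leftmost).  A read whose
clean interval vanishes is discarded as `primer_only`.

## Poly-A / poly-T model

The tail model has three parameters: minimum length `min_len` (L_p ≥ 8 —
shorter A-runs are common genomic sequence), strict minimum A-fraction
`min_fraction` (0.75, tolerating 454 miscalls inside the tail), and
`max_end_offset` (L_e = 3), the allowance between the tail's outer edge
and the clean 3' end.  The trimmer considers every window that starts and
ends on an A (tails expand A-runs; they cannot begin or end on a foreign
base) with outer edge within L_e, takes the longest qualifying window
(ties toward the end), moves the clean end to its left edge, and repeats
until no window qualifies.  The fixpoint matters: a single pass can leave
a qualifying window that only becomes end-anchored after the first cut,
which would make trimming non-idempotent.  The 5' poly-T head is the exact
mirror.

A consequence worth stating: a window may bridge interior non-A bases, so
the model deliberately removes genome-templated A-rich sequence adjacent
to a true tail.  That boundary is unidentifiable in principle — no cleaner
can tell a templated A next to the tail from the tail — so the generator
(below) *defines* ground truth on the tail side by this same rule.

## Quality trimming

From each end of the clean interval the boundary advances while the
boundary base's own score **or** the mean of its inward window (10 bases,
clipped to the interval) is below `min_mean_q = 20`; a surviving interval
shorter than `min_len = 40` discards the read.  The own-score condition
keeps the rule from stranding a run of bad bases behind a window mean
propped up by good inner bases.  Both conditions are monotone in the
threshold and stable under re-application, so trimming is idempotent and
raising the threshold never lengthens a read.  Internal low-quality
stretches are not split — single-pass cDNA reads are short enough that
end-trimming is the appropriate contract.

## Evaluation module

Two cleaners are compared through genome alignments (21-column PSL).
Reads with multiple hits in either file are excluded (a multi-mapped read
has no unique "best" boundary), as are pairs on different
targets/strands or with genomic overlap < `overlap_min = 40` bp.  Per
read end: *under* if unaligned query bases remain on that side (strictly
none allowed by default; `end_slack` is configurable), else *over* if the
cleaner's genome boundary is not the pair's best (minimum start / maximum
end), else *correct*.  Minus-strand hits map their genome sides back to
read ends (the 5' end of a '−' read faces the higher genome coordinate)
before labelling.  For each over-trimmed end the k bases of the original
read adjacent to the junction (default k = 6) can be tallied to attribute
over-trimming to adapter or poly-A sequence; windows clipped by the read
boundary are flagged.

## Synthetic-read generator

The generator emulates a pooled, two-primer amplified 454 cDNA run.  Each
read is `[barcode][adapter5][layout][adapter3]` where the layout plants
amplification primers according to the requested artifact type (`OK`
through `NR`), an optional pure poly-A tail (8–20 bp, 75% of eligible
reads) or poly-T head (10%), short junk segments (8–20 bp) for the
structural artifact types, and a uniform-random insert (80–250 bp).
Substitutions (default 1%) and indels (0.5%, half deletions, half
insertions) are applied per base, with a coordinate map so truth intervals
always index the final read.  Qualities are a high plateau (mean 37,
sd 2, floor 25) with a linear 3' droop toward 28 over the last 30% of the
read, mimicking 454 degradation.

Ground truth: the clean interval is the insert, with the tail-side
boundary defined by applying the tail model to the noise-free constructed
sequence (see above — the templated-vs-tail boundary is unidentifiable,
so the model's own rule is the definition).  Inserts and junk are
rejection-sampled to share no seed-length word with any protocol sequence
in either orientation, making the planted layout the unique explanation of
each read; artifact frequencies follow the configured mix and everything
is deterministic in the seed.

What the generator does **not** emulate: flowgram-level 454 homopolymer
noise (indels are position-independent), chimeric inserts, length-biased
sampling of transcripts, barcode cross-talk from pooling, or inserts with
biological base composition (they are uniform random).  Passing the
recovery tests therefore demonstrates that the pipeline inverts its
contamination model faithfully under realistic error rates — not that any
particular real library would be cleaned perfectly.

## Problem sizes used in the checks

The automated checks run the alignment kernels against brute-force
dynamic-programming oracles on 10,000 random pairs (patterns ≤ 20 bp,
reads ≤ 60 bp; banded-vs-unbanded on 1,000 pairs ≤ 40 bp), the poly-A
trimmer against the exhaustive window oracle on 10,000 planted-tail reads,
and the full pipeline on 5,000-read simulated sets per error condition;
`scripts/acceptance.py` uses 3,000 reads per condition.  These sizes give
sub-percent resolution on the reported rates while keeping a full run in
the low minutes on one core.

## Known limitations

* The seeder needs one exact shared word; two errors ≤ w apart inside a
  short subject can still hide a contaminant copy (observed as the
  residual few percent of type misclassification at 1% substitution +
  0.5% indel rates).
* The poly-A rule intentionally over-trims templated A-rich sequence next
  to tails; analyses of 3' UTR termini should account for this.
* Quality trimming is end-only and threshold-based, not an
  error-probability model.
* The evaluation module consumes existing PSL alignments; it does not run
  an aligner, and strict `end_slack = 0` counts a single soft-clipped
  base as under-trimming.
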