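# readscrub

Protocol-aware cleaning of cDNA shotgun reads from 454-style sequencing.

Single-pass cDNA (EST) reads carry layers of protocol sequence around the
transcript insert: a 5' barcode (MID) identifying the pooled sample, ligated
sequencing adapters at both ends, amplification primers from library
construction, and a poly-A tail (or poly-T head on antisense reads).  Badly
behaved libraries additionally produce concatenated or misoriented primer
copies.  Residual contaminants cause mis-assembly and inflate downstream
expression estimates, so they must be located and trimmed before any
analysis.  `readscrub` is a library + CLI for that cleaning step, for people
running (or designing) multi-primer amplified cDNA protocols: it
demultiplexes, trims, classifies malformed reads, reports protocol-level QC,
and can score two cleaners against each other using genome alignments.

## Method

**Barcode demultiplexing.** Each barcode *b* is aligned semi-globally
against the read start: *b* must be consumed entirely, the read suffix is
free, and mismatches and indels cost 1.  A read is assigned to the barcode
with the fewest errors *e* ≤ `max_errors` (default 2) and its clean interval
starts after the alignment; reads with no barcode in budget, or two distinct
barcodes tied at the minimum, are discarded (`no_barcode`,
`ambiguous_barcode`).

**Adapter / primer search.** Contaminants are found by exact shared-word
seeding (both orientations; the subject, never the read, is
reverse-complemented) followed by banded Needleman–Wunsch extension toward
the sequence ends (match +1, mismatch −1, gap −2, band half-width 5,
penalty-free unaligned ends).  A hit in the **middle** of a read must be
near-perfect: alignment length ≥ `middle_min_len` (15) and identity ≥
`middle_min_pid` (94%).  A hit at a read **end** may be partial and is gated
instead by identity ≥ `end_min_pid` (90%), at most `end_max_unaligned_subj`
subject bases hanging past the read end, and at most
`end_max_unaligned_read` (2) read bases left outside the hit.

**Erroneous-read taxonomy.** Amplification-primer hits classify each read:
`OK` (forward primer flush at 5' and/or reverse at 3'), `RF` (reverse then
forward — misoriented insert), `fr` (forward and reverse of the same
primer), `SF`/`RE` (flush-end match with unaligned read bases before/after
it), `NF`/`NR` (multiple forward/reverse matches — concatenation).
Precedence `RF > fr > NF > NR > SF > RE`.  `RF`/`fr` reads are discarded by
default; the others salvage the longest hit-free sub-interval.

**Poly-A model.** A tail is described by its length *L_p*, its A-fraction
*N_A/L_p*, and the distance *L_e* of its outer edge from the 3' end.  The
trimmer removes the longest window that starts and ends on an A, has outer
edge within `max_end_offset` (*L_e*, default 3) of the clean 3' end,
A-fraction > `min_fraction` (0.75) and length ≥ `min_len` (*L_p* ≥ 8),
re-applied until no window qualifies.  Poly-T heads are handled
symmetrically at the 5' end.

**Quality trimming.** From each end, a boundary base is removed while its
own Phred score or the mean of its inward 10-base window is below
`min_mean_q` (20); reads shorter than `min_length` (40) afterwards are
discarded.

**Over/under-trim evaluation.** Given genome alignments (PSL) of two
cleaners' outputs E = [s,t) and S = [v,w) with genome positions
A(E) = [s',t') and A(S) = [v',w'), multi-mapped reads and pairs overlapping
< 40 bp in the genome are excluded, the best boundary is
A(B) = [min(s',v'), max(t',w')), and per read end a cleaner is **under**-trimmed
if its read is not fully aligned on that side, else **over**-trimmed if its
boundary is not the best one, else correct.  The k bases spanning each
over-trimmed junction can be tallied to attribute over-trimming to
adapter/poly-A sequence.

All trimming is virtual — stages narrow a read's clean interval `[start,
end)` and log the change — so any stage order can be audited and the QC
report is exact.

## Worked example

Simulate a 500-read set from the built-in two-primer MID protocol (complete
with concatenation/misorientation artifacts, poly-A tails and 454-like
errors), then clean it:

```sh
readscrub simulate --n-reads 500 --seed 42 --out-prefix demo
readscrub clean --reads demo.fasta --qual demo.qual \
    --protocol demo.protocol.fasta --out-prefix demo.clean \
    --report-dir demo_report
# cleaned: 449 reads, discarded: 51
```

`demo_report/panel_A.tsv` tracks every stage:

```text
step	n_reads	n_bases	min_len	max_len
raw	500	138720	179	404
barcode	500	133730	169	394
adapter	500	113090	127	352
primer	449	79260	82	271
polya	449	72327	66	271
quality	449	72327	66	271
```

Reading it: barcode and adapter trimming remove ~10 and ~40 bases per read
without losing reads; the primer stage discards 51 fatally malformed reads
(`demo_report/discard_reasons.tsv`: 26 `primer_RF` misoriented + 25
`primer_fr` same-primer artifacts) and trims the rest; poly-A trimming
removes another ~7 k tail bases; quality trimming finds nothing left to cut.
Panel F counts primer combinations (here 336 `OK`, 31 `NF`, 18 `NR`
among survivors), panel D shows `AAAAAA` as the top 6-mer of the cleaned
sequences at 0.08% — residual tail sequence is gone, and
`demo.clean.intervals.tsv` holds the per-read clean coordinates, sample
assignment and error class:

```text
read_id	start	end	status	discard_reason	sample	class
sim000000	29	231	discarded	primer_fr	MID6	fr
sim000001	52	217	active		MID2	OK
```

Two cleaned sets mapped to a genome can then be scored against each other
with `readscrub compare --psl-a A.psl --psl-b B.psl --intervals-a
A.intervals.tsv --intervals-b B.intervals.tsv --min-overlap 40`, which
prints the under/over/correct table per cleaner and read end.

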