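# Methods

This note documents the model and procedure implemented by `itdscan`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The detection model

A tandem duplication of the reference segment `[s, e)` (0-based,
half-open; `n = e − s`) inserts a second copy of the segment directly
after the first. In the sample genome the junction between the copies
sits at coordinate `e`. A read crossing that junction cannot be aligned
contiguously; a soft-clipping-aware aligner represents it either as

* a **chimeric pair** — two alignments of the same read on the same
  chromosome and strand, one *MS* (mapped then soft-clipped, aligned end
  `e`), one *SM* (soft-clipped then mapped, aligned start `s`), linked by
  the supplementary-alignment (`SA`) tag; or
* for reads spanning the whole event plus at least one base on each side,
  a single alignment with an internal insertion, `aM nI bM`.

Both signatures are consumed. From a chimeric pair the event is

```
size  = (e − s) − max(q_overlap, 0)        start = s
```

where `q_overlap` is the overlap of the two alignments' query spans.
The correction matters: micro-homology at the junction lets the aligner
extend both pieces over the same read bases, so `e − s` alone
overestimates the size by the homology length. Candidates are
left-normalized (shifted to the leftmost equivalent placement, the
aligner's own convention) and clustered by exact `(start, end)`;
clusters below `min_support` (default 2) distinct reads are dropped.

### Duplication vs novel insertion

An insertion observed in a read is only evidence of a *duplication* if
the inserted bases replicate adjacent reference sequence. For a
candidate shorter than the read length, a supporting read is rewritten
as `aM nI bM` (insertion at the left breakpoint; the rewrite is refused
unless the read spans the whole segment with ≥1 anchoring base per
side), and the inserted sequence is tested by string rotation: the
insertion is cyclically rotated one base at a time — first moving the
last base to the front for `⌊n/2⌋` steps, then the first base to the end
for `⌊n/2⌋` steps, the rotation state carrying through — and each state
is compared against a junction window assembled from the reference
flanks (`seq_l`, `seq_r`, each `n − 1` bases). Fewer than `cutoff`
mismatches decides duplication.

Two numerical choices here:

* **Cutoff** `= max(2, round(0.1 · n))`, compared strictly (`< cutoff`).
  The floor of 2 is load-bearing: a *left-normalized* perfect tandem
  duplication always shows exactly one mismatch in the one window the
  schedule can match (left-normalization means the base before the
  segment differs from the segment's last base), so any floor of 1 would
  reject every perfect duplication shorter than 15 bp.
* **Schedule fidelity.** The stepwise inspector visits a specific subset
  of (rotation, window) configurations; a broad scan of *all* cyclic
  rotations against *all* junction windows is also provided
  (`inspector="oracle"`) and is strictly more permissive. The stepwise
  form is the default; the tests verify it against an independent
  recomputation of its schedule and verify that each of its positives is
  confirmed by the broad scan. A perfectly right-aligned insertion can
  require the broad form.

Candidates at least as long as the read length are duplications by
geometry (no single read can contain the insertion) and are tagged
`(TDUP, POS, SIZE)` on their supporting reads rather than rewritten.

### Allele frequency

`VAF = AO / DP`.

**AO** is the number of distinct reads supporting the junction: the
chimeric/insertion reads from step 1 plus *rescued* reads. Rescue
targets reads soft-clipped at the candidate's junction whose overhang
was too short for the aligner to place a second alignment. Each side of
the junction keeps its own seed — the longest clipped segment among the
supporters on that side (MS-side clips carry sequence downstream of the
junction, SM-side clips upstream; comparing across sides would reject
valid support). A clipped segment is Smith–Waterman-aligned to the
same-side seed (match 2, mismatch −2, gap open −3, gap extend −1;
conventional local-alignment weights, configurable) and accepted at
identity ≥ 0.8 over a span ≥ 0.8 × min(len(clip), len(seed)). There is
**no minimum clip length beyond 1 base**: a clip at the exact junction
coordinate is informative however short it is, and the coordinate gating
supplies the specificity. Gating accepts a clip whose coordinate either
matches a junction coordinate observed on the supporters (± a
configurable tolerance, default 0) or implies a duplication that
left-normalizes onto the candidate — the latter absorbs micro-homology
shifts exactly. Optionally (`rescue_mismatch_ends`), fully aligned reads
whose end disagrees with the reference in ≥3 bases at the junction are
treated as pseudo-clipped; default off, since error-free clipping-aware
alignment never produces such reads.

**DP** is the number of reads whose footprint — aligned span plus
soft/hard-clipped overhangs and SA pieces projected onto the reference —
covers the anchor base `start − 1`, immediately left of the duplicated
segment, unioned with the supporting reads so `AO ≤ DP` always holds.
The anchor location is deliberate: at any column at or right of `start`
the second copy contributes extra reference-looking coverage, deflating
the estimate further.

**Known, quantified bias.** A read-count VAF at a duplicated locus
underestimates at high allele fraction regardless of where depth is
measured. AO can only capture junction-crossing mutant reads — about
`(L−1)/L` of the mutant depth, minus reads whose overhang is absorbed by
junction homology and reads clipped below the aligner's anchor length —
while every junction-adjacent depth column also counts mutant reads that
end inside the duplicated segment and are sequence-identical to wild
type (roughly `min(n, L)` per unit coverage rate). To first order the
estimate is `η·v / (1 + v·min(n, L)/L)` with capture `η ≈ 0.85–0.95`:
at `v = 0.5`, `n = 60`, `L = 100` this is ≈ 0.38; at `v ≤ 0.2` the bias
is within a few points. `examples/vaf_titration.py` and the VAF tests
measure exactly this behavior. The filters applied to final calls are
`AO ≥ 3`, `DP ≥ 10`, `AF ≥ 0.01` (annotation only; `--pass-only` drops
failures).

## The synthetic-data generator

The generator reproduces the two study designs used to characterize the
caller, hermetically:

* **Hotspot grid** — a seeded 2,430-bp region standing in for the
  *FLT3* hotspot; the full Cartesian product of duplication lengths
  1–201 bp and 201 consecutive start positions (40,401 configurations);
  per configuration a balanced mixture of 1,000 duplication-carrying and
  1,000 wild-type read pairs (true VAF 50%), error-free by default.
* **Genome-wide** — a seeded pseudo-random reference (default 2 Mb,
  GC 0.41, matching the GC content of the human chromosome the original
  design used) with coding intervals tiling ~30% of it in 150–3,000 bp
  blocks; 1,000 non-overlapping tandem duplications of 3–300 bp placed
  uniformly inside coding intervals, sizes drawn as
  `3 + ⌊297·B⌋, B ~ Beta(2, 5)` (right-skewed toward short events, the
  observed shape of ITD sizes; shapes configurable, unstated in the
  source design); read sets over the grid read length {75, 100, 150,
  200} × depth {20, 50, 100}× × VAF {10, 20, 50}% — 36 configurations —
  with insert size 500 ± 50 bp and a uniform per-base substitution rate
  (default 0.1%).

Reads are paired-end: fragment length Normal(500, 50) truncated below at
twice the read length, start uniform, haplotype Bernoulli(VAF) per
fragment (so realized VAF fluctuates binomially — tests use tolerance
bands and replicate means, not equality). Truth records carry
left-normalized breakpoints in wild-type reference coordinates.

The **aligner emulator** maps reads back to the reference by exact
maximal extension around 20-mer anchors and emits exactly the record
shapes the caller consumes: chimeric primary + supplementary with SA
tags (junction-spanning reads), single `aM nI bM` records
(`mode="insertion"`/`"mixed"`, for reads spanning a short event
entirely), soft-clipped-only primaries (overhang < 20 bases — the
rescue targets), full-length matches, and unmapped records for
unanchorable reads. Alignments are emitted as unpaired records: the
caller is split-read-based and never consults insert-size evidence.

What the emulator does **not** model — and what passing tests therefore
do not show about real data: mapping-quality ambiguity in repetitive
sequence (every alignment gets MAPQ 60; real references have repeats
that produce multi-mapping and wrong anchors), indel sequencing errors,
PCR duplicates, base-quality variation, coverage waviness, and aligner
scoring idiosyncrasies (the emulator splits greedily at exact-match
boundaries; BWA-MEM's affine-gap scoring can prefer slightly different
clip points). Results on real BAMs will be correspondingly noisier,
especially for events in low-complexity or repetitive context.

## Evaluation

Predicted calls are matched one-to-one to truth records greedily by
left-breakpoint distance (deterministic position tie-breaks), under
three criteria: `hotspot` (left breakpoint inside a stated region, size
exactly equal), `exact_1bp` (left breakpoint within 1 bp, size exactly
equal), and `overlap_20_90` (left breakpoints within 20 bp, reciprocal
overlap ≥ 90% — configurable to reference-directional — and the
predicted right end at most 20 bp past the true right end). Predictions
reported as insertions count the same as duplications. Precision
= TP/(TP+FP), recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN); 0/0 is
reported as undefined, not zero. Per-size-bin tables use closed,
disjoint intervals; true events bin by true size, false positives by
predicted size.

## Problem sizes used in the shipped checks

The test suite and acceptance script run everything at desk scale,
chosen so the full suite completes in a few minutes on one core: the
genome-wide protocol at its stated 2 Mb / 1,000 events for the
truth-table checks and at 60–300 kb / 8–60 events for end-to-end calling
checks; breakpoint round-trip checks at one event per (size, read
length) on 4-kb references at 100×; the balanced hotspot mixture at its
stated 1,000 + 1,000 pairs; VAF-recovery checks as means over 3–6
seeded replicates at 100×. The rotation test is verified exhaustively
for all 4^n insertions of length ≤ 8 and on 10^4 random larger
instances; the local aligner against an independent implementation on
all 2-letter pairs of length ≤ 8 and 1,000 random pairs.

## Known limitations

* Dispersed (non-tandem) duplications, inversions, translocations and
  deletions are out of scope; chimeric reads from such events fail the
  same-strand/opposite-mode/geometry filters.
* Events whose junction attracts no anchorable split read (very short
  reads over long events, or junctions inside repeats) are invisible.
* The VAF estimator's high-fraction bias is structural (above); callers
  consuming these VAFs for clinical-style thresholds should calibrate
  against the titration behavior, not assume unbiasedness.
* Multi-sample VCF, CRAM input, and base-quality weighting are not
  implemented.
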