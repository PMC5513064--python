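# Methods

This note documents the models, scoring contracts, parameter choices and
known limitations behind `ribodevtyper`. Coordinates are 1-based inclusive
throughout; sequences are stored in the DNA alphabet (T) with transcribed
semantics, and variant names are rendered in RNA (U) as is conventional for
rRNA.

## 45S unit discovery

Element hits are found by exact 15-mer seeding of each element reference
against both strands of the genome, clustering seeds that lie within 300 nt
of each other, and refining each cluster. Clusters whose seeds agree on a
single diagonal (substitution-only copies) are extended along that diagonal
with an x-drop rule (match +1, mismatch −2, stop 12 below the running
maximum, trim to the best-scoring endpoint); clusters spanning several
diagonals (indel-containing copies) fall back to a local affine alignment
of the candidate window (same scheme as below). Hit identity is
matches/aligned-length × 100. Hits below 80% identity or shorter than
100 nt are discarded; overlapping same-element hits merge into one maximal
hit.

Hits on one contig and strand are grouped greedily in transcription order
(18S → 5.8S → 28S) within a 20 kb span cap — no documented 45S unit
approaches this span, and the cap only needs to separate tandem neighbours.
A unit is **Complete** when all elements reach their minimal lengths
(18S ≥ 1,800 nt; 5.8S ≥ 150 nt; 28S ≥ 4,000 nt), **Partial** when exactly
one is short or absent, and silently dropped otherwise. ETS flanks are the
1 kb of genomic sequence 5′ of 18S and 3′ of 28S in transcription
orientation, truncated (and flagged) at contig edges.

Type clustering is single-linkage on global percent identity of
concatenated element sequences, default threshold 97%. The linkage choice
is not critical at the divergences this analysis deals with (≥99% within a
type, ~86–93% between types); it is configurable.

On synthetic genomes the reconstruction guarantee is: exact coordinates and
completeness calls for full-length element copies. At a planted truncation
junction a hit may overrun the boundary by a few nucleotides when the
random spacer happens to continue matching the reference; the generator
forces the first three spacer bases after a junction to mismatch, which
bounds the overrun in practice to ≤5 nt — far from any completeness
threshold, so calls are unaffected.

## Read typing

**Markers.** A marker is a k-mer (default k = 26, matching the length of
type-discriminating subsequences used in this kind of analysis) that occurs
in one type's reference — in either orientation — and in no other type's
reference in either orientation. Marker scanning assigns a read to a type
if the read contains at least one marker of that type and none of any
other; reads with markers of two or more types are ambiguous, reads with
none unassigned. Because the marker index holds both orientations, the
scan is strand-agnostic.

**Alignment typing.** Each read is aligned end-to-end against each type
reference with free reference end gaps, in both orientations, under:
match 0, mismatch −6, ambiguous base (N) 0, gap of length L costing
1 + 6L on either side. A read is accepted iff its score is at least
−0.3 × read length, which caps the mismatch load at 5% of the read (a
100-nt read passes with 5 mismatches, −30, and fails with 6, −36). The
read goes to the reference with the higher accepted score; equal accepted
scores are ambiguous (a deterministic choice, preferred over emulating any
particular mapper's tie-breaking); double rejections are unassigned.

Percentages are computed over assigned (maternal + somatic) reads only;
the ambiguous/unassigned buckets are reported alongside. Profiles of empty
read sets carry `None` percentages. Length filters default to 100 nt for
5.8S (small-RNA-seq-style libraries) and 25 nt for 18S/28S
(rRNA-seq-style); a read passes when its length is ≥ the cutoff.

## Variant profiling

The two type sequences of an element are aligned globally with affine
gaps: match +1, mismatch −2, a gap of length L costs 5 + 2L. Tie-breaking
among co-optimal alignments is delegated to the alignment engine's
deterministic traversal; all derived quantities asserted in the test suite
(scores, round-trip reconstruction, difference counts in short highly
similar regions) are invariant across co-optimal alignments.

Every non-identical column yields a record on somatic coordinates;
consecutive gap columns on one side merge into a single indel event.
Substitutions are named somatic-base/position/maternal-base (`U3780C`);
insertions are anchored at the preceding somatic position (`78_insAC`,
with the maternal coordinates of the inserted bases also recorded).
Per-domain statistics use percent = (substitutions + indel events) /
somatic domain length × 100; an indel run counts once regardless of
length, and the somatic length is the denominator. (The alternative —
per-alignment-column — changes percentages by well under the rounding
precision at the divergences involved.) Domains may own several intervals
(dispersed core domains); membership is looked up at the somatic anchor.

A covariation is a pairing-map entry (i, j) where both positions carry
substitutions and both the somatic and the maternal base combination form a
legal pair — Watson–Crick by default, G·U wobble behind a flag. Domain,
expansion-segment, sticky and pairing annotations are *inputs* (they derive
from structural work, not from sequence), carried in a flat TSV.

## Sticky-region analysis

For a stretch of 18S and a 5′ UTR, all maximal ungapped matches of ≥ 5 nt
between the UTR and the reverse complement of the stretch are enumerated
(complement mode — the biology is mRNA base-pairing to rRNA; an identity
mode exists because match-based search pipelines can be run either way).
"Unidirectional" means one strand orientation only; there is no
reverse-orientation re-scan. The per-UTR count is the number of UTR
nucleotides covered by at least one qualifying match (interval union, so
overlapping matches are not double-counted; a summing mode is available).

Counts are averaged per gene over its transcripts; the ms-ratio is the
maternal mean over the somatic mean. A zero somatic mean with positive
maternal mean is class gt1 (ratio +∞); both zero is undefined and
excluded. Equality (eq1) is decided by exact rational comparison of the
two means, never floating point. The enrichment table is (maternally
labelled yes/no) × (gt1/lt1), excluding eq1 and undefined genes, tested
with Fisher's exact test implemented from the hypergeometric definition:
the two-sided p sums the probabilities of all tables no more probable than
the observed one, with a 1 × 10⁻⁷ relative tie tolerance (matching common
statistical-package behaviour); probabilities are computed in exact
rational arithmetic. The default alternative is two-sided.

Default stretch coordinates ship with the reference annotations:
"range 3-I" (maternal 188–207 / somatic 187–206) and "range 6-I"
(maternal 776–797 / somatic 738–756) — the maternal offsets follow from
insertions upstream in the maternal 18S.

## Synthetic data

`make_type_pair` plants `round(rate × domain length)` substitutions per
domain into a uniform-random somatic sequence, plus explicit indels and
stem covariations (a Watson–Crick pair swapped to a different legal pair).
Substitution positions avoid stem pairs and keep a 2-nt margin around indel
anchors, and insertion anchors are made shift-unambiguous, so the planted
truth is recoverable exactly by alignment. A post-check re-draws the pair
(deterministically) in the astronomically rare case a planted difference
recreates a 26-mer of the other type elsewhere.

`synthetic_refs.build_reference_pairs` is a fully synthetic stand-in for a
curated pair of type references. Its sequences are random but its
difference *architecture* is planted to match the documented zebrafish
situation: 5.8S with the maternal AC insertion at maternal positions 79–80
and two ITS2-proximal-stem differences; 18S with 2.9% variation in core
domain A, 10.3% in the 5′ domain, a 3′-minor stem with eight paired
altered nucleotides of which two pairs covary, and the two sticky ranges at
their shifted coordinates; 28S with per-domain variation spanning
0.6–20.8%, one PTC difference (U3780C), three GAC differences, two SRD
differences forming a U–A → G–C covariation, and one ITS2-proximal
difference. Interval boundaries are inventions consistent with those
counts.

`make_genome` lays units out in tandem (maternal-type units first) with
random spacers (default 1 kb between units, 200 nt internal) and optional
prefix truncations. `simulate_reads` draws per-read origin Bernoulli(
maternal fraction), placement uniform, lengths uniform in range (defaults
30–150 nt, matching single-end rRNA-seq read lengths; 110–155 nt for
5.8S-style libraries), and i.i.d. substitution errors — no platform error
model is implied; the i.i.d. model is a stand-in. FASTQ qualities are a
constant 'I' since nothing downstream reads them. `make_utr_set` gives
each gene 1–3 transcripts with 150–300 nt random UTRs and plants one
reverse-complement match (default 8–14 nt) per transcript toward the
maternal or somatic stretch with probability set by the gene label
(default maternal genes 0.8 toward the maternal stretch, others 0.2).

What the generator does *not* emulate: platform-specific error and
homopolymer profiles, quality variation, coverage bias, rRNA secondary
structure constraints on read sampling, real UTR base composition, or
transcriptome-wide expression. Passing tests therefore demonstrate the
correctness of the algorithms under the stated statistical model, not
performance on any particular sequencing platform.

## Verification scales

The test suite verifies alignment scores against brute-force dynamic
programming on 500 random instances (reads ≤ 50 nt vs references ≤ 200 nt;
type pairs ≤ 300 nt), match enumeration against exhaustive substring
enumeration on 100 random UTRs, and the Fisher implementation against a
vectorised hypergeometric enumeration over all 2×2 tables with total ≤ 40.
Typing recovery runs at 10,000 error-free reads per truth fraction
{0, 0.2, 0.5, 0.8, 1} (estimates within three binomial standard errors)
and 200 repetitions of 2,000 reads at 0.5% error for calibration (mean
absolute error ≤ 2 percentage points; measured ≈ 0.9). Unit
classification is checked on a 52-unit randomized genome; enrichment
recovery on 200-gene UTR sets (planted effect significant at α = 0.01,
20-seed null median p > 0.05). These sizes keep the full suite around half
a minute while leaving the statistical claims well-powered.

## Known limitations

- Copy-number estimation, repeat resolution and misassembly handling are
  out of scope for the unit finder; tandem arrays collapse to however many
  copies the assembly represents.
- The marker estimator counts reads, not marker occurrences; a read
  carrying several markers of one type still counts once.
- Alignment typing loads both orientations of every read through the
  aligner and is therefore ~100× slower than marker scanning; it is the
  right tool for short references (5.8S) and spot checks, not for
  tens of millions of reads against 28S.
- The sticky analysis scores exact complementarity only — no
  thermodynamics, no G·U pairing in UTR matching, no accessibility.
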