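# Methods

## Coordinate model

All coordinates are 1-based and inclusive, the convention in which organelle
repeat locations are usually printed. On a circular chromosome of length
`L`, an interval with `start > end` wraps across the origin and has length
`(end − start) mod L + 1`; linear sequences reject wrapping intervals.
BED output converts to 0-based half-open coordinates (stated in a header
comment) and splits wrap-around intervals at the origin, since BED cannot
represent them. `N` residues are allowed but never match anything —
including another `N` — in repeat search or overlap scoring; this is the
conservative reading of ambiguity.

Published coordinate sets are not always internally consistent: the
reference two-chromosome assembly this package was exercised against prints
its two direct-repeat copies with inclusive lengths differing by one base
(15,516 vs 15,517). The package fixes a single convention and reports what
the arithmetic gives; it does not attempt to repair such off-by-ones.

## Circularization by terminal overlap

A linear contig assembled from a circular template typically repeats its
start at its end. Candidate overlap lengths (from `min_overlap`, default
50 b, up to half the contig) are seeded by exact 16-mers taken from the
contig prefix at staggered offsets, so that isolated sequencing errors
cannot hide the overlap; each candidate is scored by ungapped identity, and
candidates within 2 percentage points of the threshold are re-scored with a
gapped alignment (edlib). The rationale for the mostly-ungapped scheme is
that terminal overlaps produced by overlap-layout assemblers are near-exact;
the gapped refinement only has to rescue borderline cases. On success one
overlap copy is trimmed and the sequence is marked circular. The procedure
is idempotent: re-running it on its own (re-linearized) output reports
not-circular.

## Maximal exact repeat finding

The repeat census that frames the recombination analysis counts *maximal
exact repeat pairs* of length ≥ `min_len` (default 30 b, the lower edge of
the conventional 30–80 / 81–360 / >360 b size census): pairs that cannot be
extended by one base on either side and still match. Matching is exact —
no mismatches or gaps — which corresponds to the default maximal-exact-
repeat mode of classical repeat finders.

Implementation: every circular sequence is doubled before the search and
hits are mapped back modulo `L`; matching is seeded with `min_len`-mers and
a seed pair is extended only when it is *left-maximal* (the characters
immediately to its left differ), which produces each maximal match exactly
once without quadratic blow-up. Inverted repeats are found by indexing the
reverse complement of each (doubled) sequence alongside the forward
strings; hits are mapped back to forward coordinates with the second copy
on the minus strand. Match length is capped at the chromosome length;
inverted hits whose two copies map to the same palindromic locus are
excluded, and pairs contained in a longer reported pair on both copies are
dropped. Repeats with more than two copies appear as all canonical pairs,
and the census counts pairs. The whole finder is checked against an
independent brute-force oracle (exhaustive start-pair extension) on
sequences up to 2 kb, including circular wrap, both orientations and
two-chromosome cases, and is rotation-equivariant and reverse-complement-
invariant by property test.

## Arrangement enumeration

For a repeat pair a single intramolecular (or intermolecular) crossover
produces exactly one class of product, with two observable novel junctions:

* **direct, same circle** — excision: a subgenomic circle carrying one
  repeat copy plus the inter-copy segment, and the reclosed remainder; the
  two product lengths sum to the parent length;
* **inverted, same circle** — the segment between the copies is inverted
  in place and both copies are retained;
* **different circles** — fusion into one circle of length `L1 + L2`.

Junctions are represented as unordered pairs of breakends
`(chrom, pos, orient)`, where orient `+` means the joined segment lies at
coordinates ≤ pos and `-` that it extends upward from pos; the
representation is therefore independent of which strand a read was
sequenced from, and relabeling the two copies of a pair yields identical
recombinant signatures (the geometry is canonicalized internally).

Because the repeat copies are exact, an aligner may place the switch point
of a junction-crossing read at either copy's boundary; the two descriptions
denote the same physical adjacency. The package (and its simulator) use the
canonical placement in which colinear runs split at the boundaries of the
copy listed first; when consuming alignments from an external aligner, the
`breakpoint_tol` window absorbs end jitter but a switch assigned to the
*other* copy's boundary (several kb away for long repeats) is counted as
uninformative rather than guessed at.

## Read classification

A read supports the reference arrangement at a copy when one colinear chain
of its alignment segments covers the entire copy plus at least `min_anchor`
bases of unique flank on both sides. It supports a recombinant junction
when two consecutive chain blocks abut on the read (gap ≤ `breakpoint_tol`)
and form a junction matching one of the pair's recombinant signatures at
both breakends within `breakpoint_tol`, with ≥ `min_anchor` aligned bases
outside both repeat copies on each side. Colinear chaining is wrap-aware,
so a read crossing a chromosome's origin (represented as two SAM records)
is reassembled into one block and produces no spurious junction.

Defaults: `min_anchor` = 200 b — longer than typical short repeats, far
shorter than long reads — and `breakpoint_tol` = 50 b. A read can only be
informative for a pair if it exceeds `repeat_length + 2 × min_anchor`;
short-read data therefore cannot resolve multi-kilobase repeats, by
construction. A read spanning *both* copies (master-circle evidence) is
tallied in a separate `ref_both` counter and contributes to both per-copy
reference counts, while the disjoint counters (copy1-only, copy2-only,
both, per-junction recombinant, uninformative) partition the evaluated
reads exactly. A read showing both reference and recombinant evidence for
the same pair — possible only with conflicting alignments — is
uninformative. A read crossing both junctions of the same recombinant
product (common when the inverted or excised segment is shorter than the
read) counts once, under the first junction in read order.

Verdicts: *reference-only* requires zero recombinant reads (zero evidence
of either kind also yields reference-only, with a `low_evidence` flag
raised, mirroring how absence-of-evidence conclusions should be surfaced);
*recombinant-only* and *mixed* follow from the counts. When both
arrangements have support the package reports both counts and *mixed*
rather than electing a winner.

## Junction calling and depth

Candidate junctions are breakend pairs between consecutive blocks of a read
whose read coordinates abut (gap ≤ `cluster_window`) but whose reference
loci are discontinuous; blocks shorter than `min_clip` (default 100 b) are
discarded as alignment noise. Candidates are clustered greedily within
`cluster_window` (default 100 b) on both breakends after grouping by
chromosome and orientation; clusters with ≥ `min_reads` distinct reads
(default 3) are reported, with loci at the median of the cluster and the
human-readable rendering rounded to 0.1 kb ("x Kb (+) join y Kb (+)");
machine output keeps full precision. Junctions explained by a known repeat
pair's recombinant signature are annotated as such. Per-sample call sets
are merged into a 1/0 presence matrix by the same breakend-matching rule.

Depth is accumulated per base, wrap-aware, from all aligned segments;
median and mean are taken over the concatenated per-base series of all
chromosomes and summarized per window (default 100 b). Maximal runs of
bases below `low_frac × mean` (default 10%) spanning at least `min_span`
(default 1 kb) are flagged — the signature of non-organellar sequence
stitched into an assembly.

## Variant summary

Variants arrive as a VCF with per-sample allelic depths (AD); multiallelic
sites are split per alternate allele, and SNP/InDel class follows allele
lengths. Presence per sample applies the minor-allele-proportion rule with
depth `d = ref + alt`: absent when `d = 0`, `alt = 0` or `alt/d <`
`min_minor_prop` (default 10%, an error filter for organelle resequencing);
homozygous-like when `alt/d ≥ homo_threshold`; mixed otherwise.
`homo_threshold` defaults to 0.9, a conventional cutoff for
homoplasmy-style organelle calls; "homozygous" has no standard definition
at the read level, so the threshold is exposed. An alternative reading of
the 10% rule — dropping a whole site unless some sample passes, then
counting any sample with alternate reads as a carrier — is available as
`site_filter=True`.

Variants inside the merged repeat mask (all repeat copies plus any supplied
extra intervals, e.g. chloroplast-derived segments as BED) are excluded
before summarization, and the removed count is reported so that totals are
conserved. The sharing histogram counts, for each variant with ≥ 1 carrier,
how many samples carry it; the number of samples is arbitrary (printed
sharing tables sometimes include more columns than genomic samples). The
per-sample homozygous fraction is homozygous-like calls over present calls.

## The synthetic-data generator

The generator's defaults are the study conditions of a two-chromosome plant
mitochondrial genome: circles of 300 kb and 145 kb; a 15 kb direct repeat
and a 4 kb inverted pair on chromosome 1; 109 short repeat pairs (30–296 b)
partitioned 45 within chromosome 1, 11 within chromosome 2 and 53 shared,
with 97 of 111 total pairs (87%) in the 30–80 b bin; reads of 12–50 kb
(truncated log-normal, mode ≈ 15 kb, σ = 0.45) at 14× depth with 0.5%
substitution, insertion and deletion rates each (post-correction error
levels — raw-read error profiles are not modeled); and eight variant
samples with 2,243 variants whose sharing levels follow the empirical
monotone-decreasing shape, two samples carrying a 10% homozygous fraction
and six carrying 1%, at 50× site depth.

Background bases are i.i.d. uniform (GC structure is not emulated), repeats
are planted by copying (reverse-complement copying for inverted pairs) into
randomly chosen non-overlapping locations with a 300 b margin, and the base
immediately flanking each planted copy is forced to differ from its
counterpart so that planted repeats are exactly maximal — truth coordinates
and the finder's output then agree exactly rather than within a base or
two of chance extension. At these lengths the expected number of *chance*
30-mer repeats is ≪ 1, so the census of a default genome equals the planted
layout with overwhelming probability.

Molecule populations carry the configured recombinant fractions as weights
(excision produces both product circles at the pair's fraction; masters are
reduced accordingly); reads choose a molecule proportional to
weight × length, a uniform start and strand, and are projected through the
molecule's block structure onto reference segments, splitting at
chromosome origins and recombinant junctions. Errors are applied per base
with exact CIGAR tracking, so the emitted truth SAM is internally
consistent (reference spans equal M+D, read spans equal M+I) and loading it
reproduces the in-memory truth paths exactly. Identical config and seed
give byte-identical FASTA/FASTQ/SAM/VCF.

What passing on synthetic data does **not** show: robustness to real
aligner behaviour in exact repeats (switch-point ambiguity, soft-clip
noise), chimeric reads, heteroplasmy gradients, GC-dependent coverage, or
mapping artefacts at nuclear/chloroplast homologies. The simulator's truth
alignments place junction switches at canonical repeat boundaries; real
split alignments may need a larger `breakpoint_tol`.

## Problem sizes and numerical choices

Tests run on scaled-down genomes (30 kb + 15 kb circles, 1.5 kb / 0.4 kb
large repeats, 1.2–5 kb reads), which preserve every contract of the
full-size configuration; the acceptance script runs the repeat census and
read stages at the full default scale (445 kb, ~300 reads). Planted-
fraction recovery is asserted within 95% binomial intervals at ≥ 30
informative reads; homozygous-fraction recovery within binomial error at
the per-sample present-call counts. Ties in circularization candidates
resolve to the highest identity, then the longest overlap. Degenerate
repeat pairs (overlapping copies) raise on enumeration and classify as
uninformative during counting; zero-depth sites are absent; empty inputs
yield empty, well-formed outputs.

## Known limitations

* Exact repeats only; diverged (approximate) repeat copies are not found,
  and recombination through them is consequently invisible.
* Junction matching assumes the canonical switch placement (see above);
  support counted from external aligners is conservative.
* The recombinant-fraction estimate ignores length-biased sampling of
  informative reads across products of different sizes; at the simulated
  configurations the bias is negligible relative to binomial error.
* The variant model treats samples independently; linkage between variants
  and structural carriers is not simulated beyond shared carrier sets.
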