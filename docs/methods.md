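# Methods

This note documents the models, parameters, and numerical conventions the
package implements, the assumptions behind the synthetic data, and the
design decisions taken where several reasonable choices existed.

## Coordinates and normalization

All internal coordinates are 0-based half-open; 1-based conventions appear
only at the GFF3 boundary. A junction flanked by microhomology is
positionally ambiguous: a deletion `[s, e)` equals `[s-1, e-1)` whenever
`ref[s-1] == ref[e-1]`, and similarly for insertions. Every call is
**left-normalized** (shifted to its leftmost equivalent representation)
before clustering, so independent reads of the same event agree on one
canonical key. Microhomology is measured on this normalized representation;
at either extreme (leftmost or rightmost) the type I measure equals the full
shift ambiguity of the junction, whereas an intermediate representation
splits it across the two sides — one reason normalization is applied before
measurement, and a property the test suite checks explicitly.

## Synthetic data

The generator's purpose is a cohort in which every downstream inference has
a known answer. Defaults describe the study conditions the package targets:
nine strain genomes, reads of mean 105 bp (normal, sd 20, truncated to
[50, 2×mean]), per-strain coverage 1.2× (≈10.8× combined), CNV sizes
log-normal with median 35 bp clipped to [25, 500] (insertions to [25, 60]
so they can fit inside a read), and the breakpoint-class mix
35% blunt / 41% microhomology / 22% complex / 2% complex+microhomology.

Signatures are *enforced*, not sampled: after site placement the reference
is edited so that a "blunt" junction has exactly zero type I microhomology
(the bases immediately inside each breakpoint are forced to differ from the
bases the junction could otherwise absorb), `microhomology(k)` junctions
have exactly k (the k bases after the deletion are copied from the deleted
segment's start and the run is broken at k), junction filler bases cannot
extend either flank match, filler insertions have no full-length match
anywhere in the reference (verified exhaustively on both strands, ends
forced to break flank identity), repeat expansions sit in phase next to a
written three-unit tract whose left edge is phase-broken, and NAHR-style
events carry two repeats of stated length and percent identity written
flush against the deletion's outer flanks. This makes every ledger entry
verifiable from sequence alone.

Implant sites are laid along each masked interval with a moving cursor and
random jitter, keeping events ≥ 1 kb apart (twice the 500 bp flank window)
so per-event analyses never interact; positions are therefore quasi-random
rather than uniform, which nothing downstream depends on.

The outgroup applies the derived allele to a chosen fraction of events
(`share`) and substitutes the rest of the genome at the stated divergence,
sparing 20 bp guard zones around every junction so that polarization errors
reflect logic rather than simulated noise. What the simulator does *not*
emulate: 454 homopolymer indel errors (the error model is substitution-only
with a configurable rate), realistic transposable-element families (TE
islands share one consensus and serve only the exclusion filter), and any
population structure among strains. Passing tests therefore demonstrate
correctness of the inference machinery under clean and moderately noisy
conditions, not robustness to platform-specific artefacts.

## Split-read calling

Reads are anchored by exact 13-mer seeds (k configurable, ≥ 11). A read
aligning contiguously with mismatches under 5% of its length is concordant
and leaves the analysis, mirroring the two-pass strategy of discarding
everything the strict mapper places. Remaining reads are decomposed into a
maximal exact prefix block and a maximal exact suffix block; anchors whose
best and second-best placements differ by < 2 bp of extension are treated
as ambiguous and dropped — without this margin, a one-base chance extension
past a junction can slip an anchor onto the wrong copy of a near-identical
repeat and fabricate a duplication call. Block geometry then yields the
signature: a reference gap ≥ 25 bp is a deletion (unaligned junction bases
allowed — the complex-end case), abutting blocks with ≥ 25 unaligned read
bases are an insertion, and a second block re-mapping upstream of the first
block's end is a tandem-duplication junction.

Filters follow the source study: ≥ 2 distinct supporting reads, pooled
across strains; not all supporting reads sharing one alignment start
position (PCR-duplicate rule; applied to the 5′-most sequenced base per
strand); junction ≥ 10 bp from both ends of a read for that read to count
as support; both breakpoints inside the euchromatin mask; and < 80% of the
mutated sequence in annotated TEs. For insertions, whose sequence has no
reference footprint, the TE rule is approximated by insertion-point TE
membership. Tandem duplications are called but can be excluded by a switch,
reproducing the conservative final dataset of the source analysis. Discards
are logged with the failing filter. Insertions are only detectable when the
inserted sequence plus two seed anchors fit inside one read — with 105 bp
reads an intrinsic ceiling of roughly 60–64 bp, stated here as a limit
rather than enforced.

PSL import/export provides interoperability with external gapped aligners;
malformed lines fail with their line number.

## Breakpoint classification

Supporting reads are realigned across the junction by anchoring both flanks
(maximal extension with ≤ 1 mismatch per 20 bp); bases unexplained by
either flank are the junction extras, and reads implying different extras
mark the call inconsistent and exclude it downstream.

Three microhomology geometries are measured, all junction-anchored and
capped at 50 bp:

- **type I** (mechanistic): max(longest common prefix of the event segment
  with the sequence following the 3′ breakpoint, longest common suffix of
  the segment with the sequence preceding the 5′ breakpoint). The maximum,
  not the sum — a junction shiftable through k bases has type I = k.
- **type II** (control): longest k with the k bases before the 5′
  breakpoint equal to the k bases after the 3′ breakpoint.
- **type III** (control): longest k with the k bases before the 5′
  breakpoint equal to the event's first k bases.

These control definitions are declared conventions (the underlying
geometries are pluggable); note type I is the maximum of two one-sided
scans while each control is a single scan, so under a pure null type I is
stochastically slightly larger — the excess test is therefore read for the
k at which excess *begins*, not as a calibrated null at k = 1.

Classes: BLUNT (type I < 2, no extras), MICROHOMOLOGY (type I ≥ 2, no
extras), COMPLEX (extras, type I < 2), COMPLEX_MH (both); 2 bp is the
threshold at which type I shows excess over the controls. `long_identity`
flags type I > 20 bp — the scale at which single-strand annealing becomes a
plausible mechanism. The excess test compares, per k, the proportion of
breakpoints with type I ≥ k against the pooled type II/III proportion with
a two-proportion chi-square (continuity-corrected), alpha 0.05, no
multiplicity correction across k (configurable).

Polarization aligns the ancestral (reference-allele) and derived junction
sequences, each 500 bp of flank around the event, against the outgroup
(edit distance via edlib). The call stands if the ancestral form fits
better, flips lineage if the derived form fits better *and* a 25+25 bp
junction probe matches within 10 edits (the junction-similarity tolerance),
and is left unpolarized when flank identity falls below 70% or the two
alleles tie. States distinguish insertions from deletions in both
directions (four outcomes plus UNPOLARIZED).

Recurrence: calls are clustered with a 500 bp proximity link; a region is
recurrent when different strains carry overlapping calls with distinct
junctions, and complex when one strain carries ≥ 2 distinct junctions
within 500 bp.

## Insertion origins and neighbourhood matching

Order of attribution: phase-consistent short-unit (1–6 bp) expansions of an
adjacent tract are recognised first — such insertions are also trivially
full-length local copies, so testing tandem duplication first would shadow
every expansion. Then a full-length ≥ 90%-identity copy within 1 kb (either
strand, the event's own footprint excluded — critical for
reference-resident events and shuffled controls) makes a tandem
duplication; everything else is filler.

The neighbourhood matcher enumerates all maximal exact matches ≥ 7 bp
(default, configurable) between the insertion and each flank, forward and
reverse complement; `matched_nt` is the union coverage of the insertion (no
double counting) and a greedy longest-first non-overlapping tiling is
recorded. Shuffled controls preserve each insertion's size and chromosome,
landing uniformly inside the euchromatin mask, with the reference sequence
at the landing site as the pseudo-insertion. Per window, a rank-sum test
compares matched fractions and a Fisher exact test compares the counts of
events with ≥ 1 match.

## Flank homology (SSA/NAHR)

Precise coordinates take 200 bp flanks outside the event; imprecise
(array-style) coordinates take flanks reaching 500 bp outward and 25% of
the CNV length inward past each nominal breakpoint. Homology is scanned in
three geometries (5′ flank × CNV, 3′ flank × CNV, 5′ × 3′) with two
filters: ≥ 30 bp at ≥ 98% (type I, SSA-capable) and ≥ 200 bp at ≥ 95%
(type II, NAHR-capable). Identity is matches / alignment columns, so gaps
count against it. The engine clusters exact 11-mer seeds; single-diagonal
clusters are resolved by an exact longest-qualifying-segment scan (weights
1−q for a match and −q for a mismatch make qualifying segments exactly the
non-negative-sum ones), and clusters spanning several diagonals fall back
to a local affine-gap alignment (match +1, mismatch −1, open −2, extend
−1). In imprecise mode, hits lying on the genomic identity diagonal
(flank and CNV pieces covering the same bases) are removed as self-hits. A
k-mer-diversity heuristic annotates hits in low-complexity sequence; it
never filters. Note a geometric consequence of flush flanking repeats: two
repeats of length L immediately outside the breakpoints share at most
min(L, 400−L) alignment columns within 200 bp flanks, so the type II filter
is only attainable at L = 200 in precise mode (imprecise flanks, reaching
500 bp, lift this).

## Non-B DNA

Detector definitions (all configurable; arms/units perfect so every motif
is re-checkable and the brute-force oracles are exact): Z-DNA = maximal
alternating purine–pyrimidine tract of GC/CG/GT/TG/AC/CA dinucleotides
≥ 10 bp (AT alternation excluded); G-quadruplex = ≥ 4 runs of G≥3 with
1–7 nt loops, both strands, runs chained while loops stay short;
inverted/mirror repeats = perfect arms ≥ 10 bp, spacer ≤ 8 bp; direct
repeats = perfect unit ≥ 10 bp, spacer ≤ 8 bp. Reporting is maximal and
non-nested per class. These thresholds are common motif-database
conventions, pinned by tests.

Each deletion contributes two 225 bp regions (25 bp inside + 200 bp outside
per junction; the inside is truncated at the midpoint of short events). A
region is motif-positive when a motif overlaps its 50 bp test window (25 in
+ 25 out); scanning pads the span by 30 bp so boundary motifs are not
truncated. Controls are size-preserving within-chromosome shuffles, 10 per
region by default; the 2×2 positives table is tested with Fisher's exact
test, and motif-midpoint histograms over the 225 bp span provide the
positional profile (controls come out flat; breakpoint regions peak at the
junction when motifs are planted there).

Because the exact test's p-value is discrete, raw null p-values are
conservative rather than uniform. For calibration studies the test can also
report the randomized probability-integral-transform p of the conditional
hypergeometric null, which is exactly uniform under H0; inference always
uses the conservative p.

## Statistics

Fisher's exact test is two-sided in the "minlike" convention (sum of table
probabilities ≤ the observed one). The rank-sum test is an exact
permutation test (midranks for ties) when the pooled sample is ≤ 20 and a
tie-corrected, continuity-corrected normal approximation otherwise. The
two-proportion test is the chi-square with continuity correction; the
independence test is Pearson's chi-square without correction. No
multiple-testing correction is applied anywhere; reports carry raw
p-values. Table percentages are integers except values < 1%, which keep
one decimal. Kernels are backed by scipy and checked in the test suite
against independent enumeration oracles (hypergeometric sums via binomial
coefficients; permutation enumeration via combinations).

## Problem sizes used by tests and the acceptance script

Cohort recovery runs 320 events on a 480 kb genome at ~10.8× combined
coverage (about 48,000 reads); homology recovery runs 400 single-strain
deletions with 2.5% NAHR implants; the false-positive scan covers 1,000
blunt events; oracle-equivalence suites use 1,000 random instances per
component; enrichment calibration uses 200 replicates of 50 regions and the
power check 100 replicates of 447 + 4,470 planted windows. These sizes make
binomial confidence intervals tight enough to be informative while keeping
the whole suite around a minute of compute.

## Known limitations

- The mapper anchors splits at read ends only; a sequencing error in the
  first or last seed-length window of a read discards it from split
  analysis (sensitivity, not accuracy, degrades with error rate).
- Insertions larger than read length minus twice the anchor length are
  invisible by construction.
- Multi-junction reads (three or more blocks) are not decomposed; the
  paired filters treat them as unmapped.
- The homology engine reports at most one hit per seed cluster, which is
  sufficient for flag-setting but not an exhaustive local-alignment list.
- Low-complexity annotation is a k-mer heuristic, not a repeat library.
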