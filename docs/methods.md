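# Methods

This note documents the models, parameter choices, numerical details
and known limitations of the package. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The analysis model

The package targets a specific experimental design: a **clonal diploid**
animal whose only reference sequence is a de novo transcriptome
assembly. Three consequences drive the methods:

1. Every sequence difference between the two haplotypes is a site of
   heterozygosity shared by all individuals, so variant calling reduces
   to detecting a second allele at ~50% frequency — no population model,
   no genotype likelihoods.
2. The transcriptome is an (uneven, but genome-wide) sample of loci, so
   the modal per-contig coverage of genomic reads estimates the
   genome-wide sequencing depth, and total read bases divided by that
   depth estimates genome size.
3. Contigs may be mis-assembled; two specific checks are built in:
   paired-end orientation concordance and inverted-repeat (hairpin)
   detection.

## Read preparation (`readprep`)

* **Duplicate collapsing.** Reads (or pairs) are grouped by the exact
  prefix of length `prefix_len` (default 30) of each mate; one
  representative per family carries the per-position majority base
  (ties: higher summed quality, then lexicographic) and the maximum
  member quality per position. This is a deliberate simplification of
  full amplification-duplicate correction: the contract is one
  representative with improved qualities per family. It is idempotent,
  and family sizes conserve the input count.
* **Trimming.** The published constraint is on the result — no base
  below Q10, no Ns — not on the procedure. The implementation keeps the
  longest contiguous valid window (leftmost on ties); whether the
  original pipeline trimmed from the ends only is unknowable, so the
  choice is documented here rather than inferred. Q10 passes (the
  failure condition is "less than 10").
* **Length floor** 45 bp, inclusive.

## Hairpin repair (`hairpin`)

No algorithm or thresholds were published for the original repair; the
scan here is fully parameterised and deliberately simple. For each
candidate apex `a` the scanner extends anti-diagonally, comparing
`seq[a-1-j]` with the complement of `seq[a+j]`, and keeps the longest
arm `m ≥ min_arm` (default 100) whose identity is ≥ `min_identity`
(default 0.95); the best apex maximises arm length, ties toward the
lower coordinate. This is an un-gapped criterion: hairpins whose arms
are separated by a long loop, or that require gapped arm alignment, are
out of scope. Splitting returns `seq[:apex]` and `seq[apex:]`, so bases
are conserved; the 200 bp contig floor is applied downstream of
splitting (disable with `min_len=None`). At the default thresholds a
random 1 kb sequence essentially never triggers a call (expected
maximal self-inverted match for random DNA is far below 100 bp), which
the test suite checks empirically.

## Alignment and validity (`mapcov`)

`align_read_to_contig` is a k-mer-seeded **exact** local aligner:
13-mer seeds nominate candidate strands, then a full Smith-Waterman
with match +1, mismatch −1 and linear gap −2/base produces the
alignment. Because the DP is exact, the score provably equals any
exhaustive implementation; the tests cross-check against Biopython's
`PairwiseAligner` as an independent oracle. Ties between equal-scoring
cells resolve to the plus strand, then the leftmost contig coordinate.

Validity follows the published rule with inclusive boundaries:
`aligned ≥ 0.40 × read_length` and `matches/aligned ≥ 0.96`, evaluated
with a 1e-9 slack so that exact boundary cases (40 of 100 aligned) are
not lost to floating-point representation. The read length is the
post-trimming length. The permissive 40% floor exists because reads can
straddle exon-intron boundaries when genomic reads are mapped to
transcript contigs.

Coverage accounting assigns each read to its single best gap-free hit
(first listed on ties) to avoid double-counting paralog-like contigs.
The coverage mode is computed on integer-rounded (half-up) per-contig
means, zero-coverage contigs excluded, ties toward the lower value; the
original binning was unpublished, so the rounding rule is a documented
choice rather than a claim.

## Variant calling (`varcall`)

At each pileup site with depth ≥ 10, the most frequent non-reference
base is called iff its fraction of **total** site depth is ≥ 0.35, both
boundaries inclusive. Design choices, all taken as the most literal
reading of the rule:

* the denominator is total depth, not ref+alt;
* only the top alternative base is considered (biallelic framing); ties
  between alternative bases break lexicographically;
* sites where the reference base itself is below 35% remain single
  SNVs, flagged `ref_below_frac`;
* indels are called from indel-opening tallies at their left-flanking
  position under the same floors, with the most common descriptor
  winning; sizes are histogrammed 1–8 with an 8+ overflow bin.

VCF output is minimal 4.2: 1-based positions, indels left-anchored with
the preceding reference base, DP/AF in INFO.

## Paired-end concordance (`estval`)

"Best alignments" of a read are all alignments within 0.5% identity of
its top identity, after applying the 90% identity floor — alignment
tools emit co-optimal hits, and the multi-map category explicitly
counts them, so a near-tie window is required; its width is a flag.
Unique-unique pairs (each read on exactly one contig) are concordant
iff same contig, opposite strands; multi-map pairs iff some contig is
hit by both reads in opposite orientations. Percentages are integer,
half-up. Cleavage of the categories is a partition: no pair is counted
twice, which the tests assert.

## Neuropeptide grammar (`peptides`)

ORFs are maximal stop-to-stop stretches (no start-codon requirement —
precursors are recognised by motif content), minimum 60 aa by default
since multi-motif precursors are long. Processing per motif:

1. cleave after the nearest upstream K/R and before the nearest
   downstream K/R (beyond the motif core and its amide-donor G);
2. iteratively trim X-A/X-P dipeptides from the N-terminus; trimming
   stops at an N-terminal Q because cyclisation to pyroglutamate blocks
   the dipeptidylaminopeptidase;
3. if the motif class provides an amide-donor G and it terminates the
   fragment, remove it and set the amide flag;
4. flag pyroglutamate when the processed peptide starts with Q.

A "prefer dibasic sites within 5 residues" rule was considered and
rejected: preferring a more distal dibasic site over a nearer single
basic residue would leave a basic residue inside the mature peptide,
contradicting the processing model (and when the dibasic site is
nearer, nearest-basic cleavage already selects it). `CPP` sequences
immediately preceding a motif are reported as an annotation flag only;
no processing function is assigned to them.

Query notation: `pE` maps to a leading Q, `-NH2`/`-NH_2_` strips to the
amide flag. Exact matches require identical core, identical amidation,
and pyroglutamate compatibility; C-terminal suffix matches are reported
separately.

## The synthetic-data generator (`simulate`)

The generator's defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| contig length law | log-normal, median ≈ 453 bp, σ(log) = 1.03, floor 200 bp, cap 13,061 bp | reproduces the published assembly's median/mean (453/770 bp) and range |
| `snv_rate` | 1/808 per bp | published heterozygosity |
| `tstv_ratio` | 1.6 | ratio implied by the published class counts (39,893 transitions vs 24,926 transversions); a default, not a claim — the published total (55,300) and the class-count sum (64,819) disagree, so the ratio is configurable |
| `indel_rate` | 8,691 / 44.7 Mb | published indel count over assembly size |
| `indel_size_weights` | 5773, 1289, 862, 372, 165, 143, 57, 30 (sizes 1–8) | published size spectrum; monotonically decreasing |
| `read_length` | 100 bp | genomic lane read length |
| `coverage` | 30 | emitted read bases per haplotype base |
| `error_rate` | 0.005 | typical short-read substitution rate |
| qualities | constant Q40 | trimming is exercised by explicitly crafted reads instead |

Haplotype A equals the reference; haplotype B carries the planted
variants. Indels are planted only away from contig ends (one read
length of margin) and variants keep ≥ 15 bp of separation so they never
interact — this keeps recovery tests free of edge-case ambiguity that
the caller is not being tested for. Transition probability is
`tstv/(1+tstv)`; transversions pick either alternative with equal
probability.

**Coverage convention.** `coverage` counts emitted read bases per
haplotype base. On a diploid pair both haplotypes map to the same
reference coordinates, so pileup depth is ≈ 2×`coverage`; the
genome-size experiment passes haploid pieces, where modal coverage ≈
`coverage`.

**Provenance and truth alignments.** Every read records its source
sequence, haplotype, offset, strand and injected error positions.
`true_alignments` projects haplotype-B reads through the planted-indel
block map, yielding exact reference-coordinate alignments. The recovery
experiments in `pipeline` use these rather than the heuristic aligner —
they measure the caller and the coverage estimator under known mapping,
while the aligner is validated separately against an exhaustive DP
oracle; the `matches` field of a truth alignment is a tight lower bound
(an error landing on a planted SNV is counted as an extra mismatch),
which is conservative for the validity filter.

**What the generator does not emulate**, and hence what passing tests
do not show about real data: sequencing indel errors and quality-decay
profiles; GC and amplification bias; spliced alignment across introns
(transcripts are embedded contiguously); paralogous gene families and
alternative isoforms (each contig is an independent random sequence, so
cross-mapping is absent by construction); bacterial contamination. The
recovery numbers are therefore upper bounds on real-data performance,
and the acceptance experiments are read as internal-consistency checks
of the implementation, not as benchmarks.

## Problem sizes

The test suite runs the recovery experiments at ~2 Mb of transcriptome
(30x, 0.5% error) and a 5 Mb genome (40% transcribed, 20x); the
acceptance script uses ~1 Mb and 2.5 Mb. These sizes put several
thousand planted variants behind the recall/precision estimates —
enough for stable two-digit percentages — while keeping a full run in
tens of seconds. At these scales the SNV caller's residual misses are
concentrated at contig ends, where reads (being wholly contained in a
contig) cannot maintain full depth and sites fall below the 10x floor.

## Numerical conventions

* Coordinates 0-based half-open internally; 1-based only in VCF.
* Percentages and the coverage mode round half-up; the mean contig
  length is rounded only at report time.
* Threshold comparisons use a 1e-9 slack so inclusive boundaries
  survive floating-point representation.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; generators are pure functions of
  (inputs, seed), and per-contig streams derive from a `SeedSequence`
  so results are independent of contig processing order.
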