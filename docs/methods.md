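# Methods

## Overview

`multihla` models the computational half of a multiplex-PCR NGS HLA
genotyping workflow for nine classical loci (HLA-A, -B, -C, -DRB1,
-DRB3/4/5, -DQB1, -DPB1).  Middle-ranged locus-specific primer pairs
amplify each gene from (roughly) promoter to 3'UTR for class I and from
intron 1 to exon 4 (or the 3'UTR for DPB1) for class II, the pooled
barcoded amplicon libraries are sequenced on an Ion-Torrent-like
instrument, and alleles are assigned by mapping reads to reference
allele sequences under a strict perfect-match condition.  The package
implements in-silico PCR, a read simulator that serves as the synthetic
data generator, demultiplexing and quality trimming, the allele caller,
depth/uniformity QC statistics, and DRB1–DRB3/4/5 haplotype validation.

## Allele assignment

The caller works per sample and locus:

1. **Candidate selection.**  Alleles are ranked by the number of
   distinct k-mers (default k = 15) they share with the sample's read
   set, both strands considered; the top 10 per locus are retained and
   an allele sharing no k-mer is never a candidate.  For speed the
   k-mer pool is built from an evenly strided subsample of at most
   4,000 reads; ranking is insensitive to this because every locus
   contributes thousands of reads.
2. **Perfect-match mapping.**  A read is placed on a candidate allele
   iff it equals a substring of the allele sequence (or its reverse
   complement) with zero mismatches and zero indels.  This deliberately
   sacrifices error-containing reads in exchange for immunity to
   cross-locus mismapping and to PCR crossover chimeras, which by
   construction match neither parental allele exactly.  The
   implementation seeds on the read's first k bases through a database
   k-mer index and verifies the full read by string comparison; because
   any full match must match at its first k bases, this is exactly
   equivalent to brute-force substring comparison (property-tested
   against that oracle).
3. **Pair choice.**  The called genotype is the allele pair (a, b),
   a = b allowed, that maximises the number of reads placed on a or b
   with a placement overlapping the *genotyped region* (exons 2+3 for
   class I, exon 2 for class II).  Reads that also place on another
   locus's candidates (shared ancestral segments between DRB paralogs,
   for instance) contribute to depth but are excluded from this
   objective so they cannot pull a genotype across loci.  Ties break
   toward the pair with the more even allele depths, then
   lexicographically; pairs are enumerated in sorted order, so calls
   are fully reproducible.  The published assignment software is
   unpublished, so this joint pair-maximisation rule is this package's
   own reconstruction of "sequence-alignment-based assigning"; a greedy
   best-then-second-best rule is the obvious alternative and would
   differ only when the two true alleles share most of their reads.
4. **Zygosity.**  With the best pair in hand, each allele's *unique*
   support is the count of reads explaining it but not its partner.
   When the minor allele's unique support falls below `hom_fraction`
   (default 0.1) of the major's, the call collapses to homozygous.
5. **Ambiguity widening.**  Each called allele is expanded to the set
   of alleles whose sequences are identical over the amplified region
   (`ambiguity_scope="amplicon"`, the default, since nothing outside
   the amplicon was sequenced; `"genotyped_region"` gives the
   exon-only grouping).  Sets are rendered slash-joined in
   lexicographic order, e.g. `DPB1*107:01/*13:01`.
6. **Novel variants.**  Reads left unmapped are re-aligned against the
   called alleles allowing exactly one substitution (edlib infix
   alignment with k = 1, indel solutions rejected).  A position is
   reported when ≥ `novel_min_fraction` (default 0.3) of all reads
   covering it — perfect placements plus re-aligned reads — agree on
   the same substitution, with ≥ 3 supporting reads.  The fraction
   threshold is calibrated for the heterozygous case (a true novel SNP
   on one chromosome sits near 0.5) while scattered sequencing errors
   stay near the per-base error rate.  When the two called alleles are
   identical around the variant site the attribution between them is
   arbitrary; the position and substitution are still exact.

### Depth metrics and flags

Average depth is mean redundancy per site over the genotyped region;
the allelic depth ratio is min/max of the two allele averages (1.0 by
convention for homozygotes, where the two chromosomes are
indistinguishable and each is assigned half the observed depth); locus
depth is the sum of the two allele depths.  Reads explaining both
alleles count toward both depth vectors, which bounds the ratio from
below — documented because it makes the ratio an optimistic imbalance
measure.  Normalised depths rescale by (reference draft reads / sample
draft reads), the reference defaulting to the run's mean per-sample
draft read count.  Flags: ratio < 0.2 ⇒ `excessive_imbalance`,
0.2–0.5 ⇒ `imbalanced`; per-allele depth < 30 ⇒ `low_depth` (below
~30× variant detection loses sensitivity); summed pair depth < 25 ⇒
`no_call` (25 being just below the smallest per-allele depth at which
full concordance has been observed in practice).

### DRB haplotype validation

DRB1 first fields map to serogroups (03/11/12/13/14 → DR52 → DRB3,
04/07/09 → DR53 → DRB4, 15/16 → DR51 → DRB5, 01/08/10 → none).  For
each sample, every DRB1 allele implying a paralog must be matched by a
call at that locus and every paralog call must be implied by some DRB1
allele; violations are `inconsistent` findings and set
`paralog_inconsistent` on the DRB1 call.  Observed paralog allele
*identity* is compared against the bundled haplotype reference table
only informationally, since several DRB1 alleles segregate with more
than one paralog allele.  Ambiguity sets validate through their shared
first-field family.

## The synthetic data generator

`fixtures.toy_reference(scale)` builds a deterministic synthetic allele
database (63 alleles over the nine loci) plus the matching primer set.
It is generated, not copied from any public database: each locus gets
a random backbone laid out as promoter/exons/introns/3'UTR, and alleles
differ by bit-pattern SNPs planted in exon 2 (and exon 3 for class I).
Primer sites are embedded so predicted product sizes reproduce the
multiplex design exactly at `scale=1.0` — 5.5/4.6/4.8 kb for A/B/C,
4.0–5.2 kb for DRB1 with the DR4 family at 5.2 kb (an intron-1 length
polymorphism), 4.1/4.5/4.1 kb for DRB3/4/5, 3.9–4.3 kb for DQB1 and
7.2 kb for DPB1 — and shrink proportionally at the 1:10 test scale.
One shared "DRB" primer pair amplifies all four DRB paralogs.
Structural analogues of real ambiguity cases are planted:
DPB1*13:01/*107:01 and DRB1*09:01:02/*09:21 differ only in exon 1
(upstream of the amplified region), and B*40:02:01/B*40:02:03 differ
in intron 2 (inside the amplicon, outside the exons).

`simulate_reads` draws each sample's reads from its predicted
amplicons:

- **Locus weights** set relative amplification efficiency; the defaults
  (A 1.00, B 1.24, C 1.45, DRB1 2.14, DQB1 1.86, DPB1 0.99, DRB
  paralogs 1.0) were derived once from the observed per-locus depth
  hierarchy of a real pooled run — highest at DRB1/DQB1, lowest at
  A/DPB1 — scaled by amplicon length.  A hemizygous DRB3/4/5 locus
  contributes half its weight (one template copy).
- **Allelic skew** is the expected low/high depth ratio at a
  heterozygous locus; the panel generator draws it near 0.9 (clipped
  normal, sd 0.08), matching the observed mostly-even ratios, and a
  constant (e.g. 0.25) can be forced to study imbalance.  The major
  allele is chosen at random per locus.
- **Read lengths** follow a discrete truncated skew-normal (shape −4)
  calibrated so the truncated distribution's mean and interior mode hit
  their targets (mean ≈ 273, mode ≈ 359, range 25–400 at full scale;
  mean 72, mode 88, range 30–110 at the 1:10 test scale).  The shape
  mimics 400-bp-chemistry behaviour: a peak near the chemistry limit
  with a long left tail of short reads.  Fragment starts are uniform
  over the amplicon with edge truncation (a sonication-like model, no
  end-bias beyond truncation).
- **Errors.**  Substitutions at 0.002/base and homopolymer ±1-length
  errors at 0.005/run (the dominant Ion-Torrent error mode); run counts
  per fragment are computed exactly from precomputed run boundaries.
  Errored bases get QV 8; clean bases draw QV 29–33 per read; 12% of
  reads get a short low-QV (6) 3' tail so quality trimming has real
  work to do.  Barcodes (10-mers, pairwise Hamming distance ≥ 3) are
  prepended error-free.
- Identical seeds give byte-identical FASTQ output.

What the generator does *not* emulate: flow-space signal processing,
PCR crossover chimeras (the mapping condition is designed to reject
them, so simulating them would only exercise read loss), coverage bias
along the amplicon, barcode synthesis errors, and cross-sample index
hopping.  Passing round-trip tests therefore demonstrate the internal
consistency and discriminative power of the caller under realistic
error and imbalance regimes, not performance on real flowgram data.

## Quality trimming

"Remove poor sequence at the end of reads below QV 10" is implemented
as stripping the maximal 3' suffix in which *every* base has QV < 10 —
the simplest reading, chosen over a sliding window so the suite is
unambiguous; a 5' option exists but defaults off (Torrent-style
trimming is 3'-only).  Reads shorter than `min_length` after trimming
are discarded (default 50 at full read length, 30 at the 1:10 test
scale; the threshold is a free parameter and is kept above the seed
k-mer length).

## Problem sizes used in tests and the acceptance script

All simulation-based checks run on the 1:10-scale reference: a
46-sample panel at 12,000 reads/sample (reproducing per-allele depths
near the observed run: ~60× at DPB1 up to ~200× at DRB1), a 14-sample
round-trip panel at 24,000 reads/sample (≥ 60× per allele everywhere,
≥ 100 scored sample-locus genotypes, repeated with forced skew 0.25),
100 seeded novel-variant replicates at ~60× with 100 error-free
negative controls, and 1,000 randomized mapping-oracle instances.

## Known limitations

- Field-4 (intron-phased, full-gene) calling is out of scope; alleles
  differing only outside the amplified region are reported as ambiguity
  sets, exactly as the assay would see them.
- An allele entirely absent from the reference is not assembled de
  novo; it surfaces as a novel-variant candidate (single SNP) or as
  depleted depth / no_call (larger divergence).
- The homozygosity rule cannot distinguish a true homozygote from
  complete dropout of the second allele; the depth-ratio flags are the
  guard rail there.
- Whether depth normalisation should rescale per sample or per run is
  ambiguous in the assay description; per-sample scaling against the
  run-mean draft read count was chosen.
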