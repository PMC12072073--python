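# Methods

This note documents the models, conventions, defaults and known limits of
pirnakit, in the order the pipeline applies them.

## Coordinates and sequence conventions

All internal coordinates are 0-based half-open; conversion happens only at
file boundaries (GFF3/GTF and SAM are 1-based in the files, BED/bedGraph
0-based). The 5′ end of a minus-strand alignment is the highest genomic
coordinate of its interval — the ping-pong overlap arithmetic depends on
this. `N` bases are permitted in assemblies but never match any read base
(N vs N counts as a mismatch), so assembly gaps cannot absorb reads; a
read containing N therefore has no zero-mismatch placement at all.

## Preprocessing

Inputs are pre-trimmed reads; adapter/quality trimming is delegated to
upstream tools. Identical sequences are collapsed to one record with a
count and every downstream statistic is count-weighted. The piRNA fraction
is 23–29 nt; 20–29 nt is used for size-profile plots. Contaminant
subtraction removes a read iff it occurs as a substring of any
rRNA/tRNA/snRNA/miRNA sequence on either strand with at most
`max_mismatch` mismatches; the default is 0 (exact), chosen as the
reproducible default because no tolerance is standard, and exposed as a
flag.

## Mapping

The internal aligner is exhaustive, not heuristic: every ungapped placement
on either strand with ≤ `max_mismatch` (default 3) mismatches is
enumerated (string search at 0 mismatches, numpy sliding-window comparison
otherwise). Best-stratum unique filtering keeps a read only when its
minimal-mismatch stratum holds exactly one placement; ties are never broken
arbitrarily — multi-best reads are discarded. The aligner is intended for
desk-scale genomes (≤ ~10 Mb); external aligner output can be substituted
through the SAM reader (mismatches from NM, multiplicity from NH, collapsed
weights from an XW tag) for anything larger. Gapped/spliced alignment is
out of scope; spliced RNA-seq must arrive via SAM.

Allele-specific mode merges two haplotype assemblies into one diploid
reference (contig names prefixed `label|`) and retains reads with exactly
one perfect placement genome-wide. Sequencing errors are rejected by the
zero-mismatch rule, deflating counts uniformly across alleles; no error
correction is attempted. Because an observed allelic share conflates
expression share with local variant density, the informative fraction
(retained/input) is reported alongside the percentages.

Mappability marks position *i* with 1 iff the k-mer starting there occurs
exactly once among all forward-strand k-mers of the genome, matching the
k-mer-mappability convention of the tool class it emulates;
reverse-complement collapsing is off by default and available as a flag.
Defaults: k = 25 for piRNA-length reads, k = 50 for mRNA/ChIP reads.

## piRNA statistics

The ping-pong histogram pairs plus-strand and minus-strand 5′ positions at
overlaps 1…20 (the `max_overlap` background window is configurable since
the convention varies), weighting each pair by the product of collapsed
counts at the two positions. z10 uses mean and sample SD (ddof = 1) of the
non-10 bins; it is undefined (NaN, flagged) when no pair exists or the
background has zero spread. The 1U/10A fractions are count-weighted over
read-orientation sequences; position 10 is evaluated only on reads ≥ 10 nt.
Feature counting assigns a read to a feature iff it overlaps an exon of
that feature; reads overlapping exons of ≥ 2 features are dropped as
ambiguous (fractional assignment is deliberately not the default, to keep
counts reproducible), and per-feature counts + unassigned + ambiguous
always equal the input total. RPKM = count × 10⁹ / (length × library
size); the piRNA library size is the total genome-mapped 23–29 nt read
count after ncRNA subtraction and unique filtering.

## Cluster profiling and locus diff

Cluster calling merges positions with any combined-strand coverage across
gaps ≤ `max_gap` (default 1,000 bp) and drops regions with fewer than
`min_reads` (default 100 weighted reads); a cluster is dual-strand when
minority/majority strand reads ≥ `dual_ratio_threshold` (default 0.1).
These three thresholds operationalize "continuous piRNA mapping" and are
explicit because no standard values exist. "All-mappers" coverage
distributes each placement with weight 1/n_best. Locus extraction takes
the cluster ± 10 kb, truncating (and flagging) at contig edges.

The pairwise locus diff chains k-mers (k = 21) that are unique in both
sequences into a colinear backbone (longest increasing subsequence, then
thinned to mutually non-overlapping anchors) and aligns each inter-anchor
segment globally with edlib, reading SNPs from X runs and indels from I/D
runs. Indels ≥ `gap_min` (default 500 bp) are additionally exposed as
gaps. A long (≥ 100 bp aligned span) segment whose substitution divergence
exceeds `max_divergence` (default 10%) is not base-aligned but reported as
a single length-difference gap — the dot-plot level of description for
unanchorable repeat material. Short segments are always base-aligned, so
isolated variants are never swallowed by the divergence bailout.

Two representation caveats are inherent rather than bugs: indel positions
are reported left-aligned within their equivalence class (a planted indel
whose boundary bases match its flank can shift by a few bp while keeping
its exact length), and inside tandem satellite arrays the decomposition of
a copy-number difference into indel runs can differ between diff(a,b) and
diff(b,a) even though the total inserted length is conserved. Satellite
array lengths are therefore compared through annotation features, not
through the diff.

## ChIP enrichment

Fragments are deduplicated by (contig, start, strand). Single-end reads
are extended to a fixed fragment length from their 5′ end (default 200 bp
— a library-prep-typical value, since no standard exists for single-end
extension); paired-end spans would be used as observed. Bin values are
mean per-base fragment coverage (overlap-proportional, default 10 bp
bins). RPGC divides by total fragment bases / effective genome size
(default: non-N genome length), making the genome-wide mean per-base
coverage exactly 1 (an arithmetic identity, tested to 10⁻⁶). Input tracks
are subtracted elementwise on the same grid; negative values are retained.

The enriched-region prefilter is a deliberately simple Poisson caller, not
a peak-caller reimplementation: per-bin one-sided Poisson upper tail of
the treat count against scale × max(input count, genome-wide mean input) —
the local-lambda floor guards zero-input bins — with Benjamini–Hochberg
adjustment and merging of significant bins across ≤ 1-bin gaps. Under the
complete null this controls the family-wise any-region rate at ≈ α
(measured ≤ α + 3σ over 200 null simulations). Between-sample comparison
is a two-sided Mann–Whitney U over per-region mean treat-minus-input
values: exact null distribution when n_a·n_b ≤ 10,000 and tie-free,
tie-corrected normal approximation otherwise, p = 1 by convention for
fully tied data. ChIP-qPCR percent-input is (IP/input) normalized to a
reference gene's ratio × 100; RT-qPCR relative expression is 2^−ΔCt.

## Synthetic data

The generator emulates the studied system's structure: strain A carries a
5,403 bp TE insertion immediately upstream of a gene inside the piRNA
cluster and a 30-copy 370 bp satellite array flanking it; strain B lacks
the TE, carries a 10-copy array, and differs by SNPs (default rate 0.01 —
typical intraspecific divergence), scattered 1–6 bp indels (rate 10⁻⁴),
and one planted 69 bp indel in the downstream intergenic region. Edits
are spaced ≥ 25 bp apart and away from segment edges so each variant sits
in unambiguous alignable context. A 36 bp satellite analogue and a
two-exon gene model (UTR5/CDS/intron/CDS/UTR3) are annotated. Defaults:
100 kb contig, 20 kb cluster, GC 0.40.

piRNA libraries draw primary 5′ ends uniformly over both strands of the
cluster; each primary spawns an opposite-strand partner at an exact
10 nt 5′ overlap with probability `pingpong_fraction` (default 0.3).
The primary 5′ base is T with probability `frac_1U` (default 0.88, the
top of the observed range) and otherwise uniform over the other bases, so
the configured probability is exactly the expected recovered fraction;
partners analogously get A at position 10 (`frac_10A` = 0.6). Lengths are
Normal(26, 1.5) rounded and clipped to 23–29. Contaminants are exact
substrings of a bundled **synthetic** ncRNA set (random sequences labeled
rRNA/tRNA/snRNA/miRNA — not real sequences, adequate only for
subtraction-logic testing) at 5% of the library; 1% genome-wide background
reads are added. Hybrid libraries draw error-free reads from allele B with
probability `minor_allele_fraction` (default 0.054, the larger of the two
observed shares; 0 models the no-maternal-deposition cross). ChIP treat
fragments multiply their start density by `enrichment_fold` (default 8)
inside the target regions; input is uniform. All generators are
deterministic under a fixed seed.

What the simulations do not model: sequencing errors and quality scores
(an error-rate path exists only implicitly through the mismatch-tolerant
aligner), PCR amplification bias, chromatin accessibility structure in
ChIP input, transcription-driven non-uniform piRNA precursor coverage,
splicing, and real repeat families. Passing tests therefore demonstrate
correctness of the estimators and algorithms under the stated generative
assumptions, not robustness to every artifact of real libraries.

## Problem sizes and tolerances in the test suite

The acceptance checks run on scaled problem sizes chosen to exercise every
code path with comfortable statistical power: 60–100 kb genomes, 20 kb
clusters, 10,000-primary-read libraries (≈ 5,000 ping-pong pairs at
fraction 0.5), 55,000-read hybrid libraries (≥ 10,000 allele-informative
after filtering), 100-seed null calibrations and 200-seed false-positive
controls. Stochastic recoveries are asserted within 3σ binomial at the
realized n; oracle equivalences (all-pairs ping-pong, exhaustive
placement enumeration, substring-search mappability, permutation
Mann–Whitney) are exact or to 10⁻¹². Structural-variant recovery asserts
exact lengths and positions within the indel left-shift equivalence class.
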