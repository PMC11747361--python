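# Methods

This note documents the models, conventions and numerical choices behind
`gapseq`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and format conventions

All internal coordinates are 0-based half-open (the BED convention). The
AGP writer converts to 1-based inclusive coordinates at the output
boundary; gap rows are written as gap type `scaffold`, linkage `yes`,
evidence `paired-ends`. FASTA output wraps at 60 columns; readers accept
any wrapping, uppercase on read and restrict sequences to `ACGTN`.

Mean read quality is the Phred scaling of the *mean error probability*,
`-10*log10(mean(10^(-q/10)))`, the convention of common long-read
filters — not the arithmetic mean of per-base Phred scores. This matters
for filtering: a read with a few very bad bases is penalised more than the
arithmetic mean would suggest.

## Adaptive-sampling target design

Targets are the outermost `target_len` bases (default 5,000) of each
contig end; a contig shorter than `2 * target_len` yields a single merged
region covering the whole contig. In repeat-aware mode an end is emitted
only when the union of repeat annotations covers *strictly less than*
`max_repeat_fraction` (default 0.50) of its terminal `repeat_window`
(default 100,000 bp; truncated to the contig length for short contigs).
Repeat intervals are unioned first, so overlapping annotations never
double-count. An end failing the repeat criterion is suppressed outright
rather than slid inward to a cleaner window; sliding is a possible
extension but complicates the downstream bookkeeping for little benefit on
the genomes this targets.

Read QC keeps reads with length >= 20,000 bp and mean QV >= 10. A read
failing both thresholds is counted once, under length, in the report.

For gap-spanning classification, an alignment counts as reaching a contig
end if it comes within `epsilon` = 100 bp of the terminus (alignments
rarely reach the exact end); the overhang is the number of unaligned read
bases on the outward side beyond what the contig could still absorb.

## k-mer-pair link scaffolding

The scaffolder re-implements the LINKS idea: two k-mers observed exactly
`d` bp apart (start-to-start) on one long read, each placed *uniquely*
across the whole contig set (canonical form: lexicographic minimum of the
k-mer and its reverse complement), vote for an oriented adjacency between
two contig ends. The read's local direction at each hit determines which
end faces the gap; the implied gap is `d` minus the two distances from the
k-mers to their outward contig ends, and can be negative for overlapping
contigs.

Defaults are the conservative set for ~20-kb nanopore reads: `k = 51`,
`min_links = 15`, `d = 20,000`, distance error 2%, maximum link ratio
0.1, extraction step 2. The distance-consistency filter keeps estimates
within `e*d` of the *batch median* of all estimates for the edge; a batch
median (rather than a running one) makes the result invariant under read
order, which we treat as a hard requirement for reproducibility. Pairs
with either k-mer multi-copy or absent contribute nothing: repeats are the
known failure mode of end-targeted enrichment, and uniqueness is the
defence.

A join is made only when the edge is the *best* (highest support) at both
of its ends, meets `min_links`, and the runner-up at each end is at most
`max_link_ratio` of it. Each end then participates in at most one join, so
the join graph decomposes into paths and cycles; cycles are broken at
their lowest-support join. All tie-breaks are lexicographic on
(contig id, side), making the output deterministic and invariant under
permutation of reads and contigs. Internal gaps are the rounded median gap
estimate floored at 1 N; negative estimates (overlapping contigs) become a
1-N gap rather than a sequence merge — overlap resolution is out of scope.
Scaffolds are named `scaffold_NNNN` in descending total length.

## Cross-assembly bridging and reference anchoring

A scaffold of assembly B whose alignments chain into exactly two anchors
(>= `min_anchor` = 20 kb aligned bases each, both within `end_window` =
500 kb of an A-scaffold end, disjoint and ordered on the bridge sequence,
and geometrically exiting one A-end and entering the other) bridges those
two A-scaffolds; they are joined with exactly `join_gap` = 100 N
characters. The thresholds exclude spurious repeat-driven anchors and are
configurable. Conflict handling is conservative: if two bridges claim the
same A-scaffold end with different partners, *all* claimants are dropped;
duplicate bridges of the same junction merge their support; cycles drop
the smallest-support bridge.

Pseudomolecule construction assigns each super-scaffold to the reference
chromosome receiving the largest share of its aligned bases, provided that
share is at least `min_cov_frac` = 0.3; orientation is the majority
strand; ordering within a chromosome is by the weighted median reference
position of the aligned blocks. Unassigned sequences are reported as
unplaced. Pseudomolecules carry the reference chromosome names verbatim;
gaps between anchored super-scaffolds reuse the 100-N join by analogy with
the bridging step. Synteny-gene collinearity is not computed; alignment
share stands in for it.

## Assembly QC

* **N50/L50**: length at which the cumulative descending-sorted length
  first reaches half the total, and its rank. Verified against a
  brute-force oracle on 1,000 random length multisets.
* **Genome size from a k-mer spectrum**: error cutoff at the first local
  minimum of the counts scanning up from multiplicity 1 (overridable);
  peaks are local maxima of the 3-bin moving average above the cutoff (a
  single-spike spectrum falls back to the arg-max, since boundary peaks
  are invisible to interior peak detection); size is the k-mer mass above
  the cutoff divided by the highest-multiplicity peak. Two peaks flag a
  heterozygous spectrum; using the highest peak as the homozygous one is
  the convention matching single-peak reporting for heterozygous genomes.
  The 3-bin window is the minimal smoothing that suppresses single-bin
  noise.
* **Telomere scan**: non-overlapping counts of the motif and its reverse
  complement in each terminal window (default 3,000 bp, motif `TTTAGGG` —
  the canonical plant telomere repeat — minimum 10 copies); the larger of
  the two orientation counts is reported per side, which makes the scan
  exactly symmetric under reverse complement.
* **Coverage fold** is kept at full precision internally and rounded to
  one decimal only in reporting.

## Windowed population-genomic scan

Site filters follow standard hard-filter practice for reduced-
representation data: per-genotype depth < 5 masked to missing first, then
sites kept iff biallelic SNP, QUAL >= 200, call rate >= 0.8, and
post-mask alt-allele frequency within [0.05, 0.95] (the upper bound taken
literally as an alt-frequency cap).

**Tajima's D** is computed from allele counts (phase never needed): pi
accumulates per-site `c(n-c)/C(n,2)` with the per-site observed haplotype
count `n`; S counts segregating sites; the normalising constants use the
window-mean observed haplotype count rounded to the nearest integer. A
`per_site` flag instead sums Watterson contributions `1/a1(n_i)` per site.
D is missing when S = 0 or the variance term is non-positive.

**F_ST** is Weir & Cockerham's theta-hat for two populations: per-site
variance components a (among populations), b (among individuals within)
and c (within individuals) from sample sizes, allele frequencies and
observed heterozygosities; the window estimate is the ratio of sums
`sum(a) / sum(a+b+c)`. Sites need two called diploids per population to
contribute; small negative estimates are legitimate for the estimator.

Windows tile each sequence as `[0, w), [w, 2w), ...` including the
trailing partial window (default w = 100 kb).

**Permutation nulls** (10,000 permutations and alpha = 0.01 by default;
seedable): for F_ST, sample-to-population labels are permuted and every
window recomputed — the standard null for differentiation. For Tajima's D,
label permutation is undefined (a one-population statistic), so sites are
resampled without replacement into pseudo-windows of matched SNP count.
P-values use the add-one estimator `(1 + #extreme)/(n_perm + 1)` and are
never zero. Undefined permuted statistics count toward the tail, which can
only enlarge p (conservative). The reported regions are the high-F_ST
windows (p < alpha), and within them the per-population low-D windows —
differentiated between groups and unusually uniform within one. Raw
permutation p-values are reported without multiple-testing correction.

All permutations share one label-permutation set across windows for
vectorisation; p-values remain marginally uniform (windows are
conditionally independent given the permutation set), which the seeded
null-uniformity test confirms (Kolmogorov-Smirnov statistic < 0.05 over
~1,000 windows).

## Synthetic data: what it emulates and what it does not

* `simulate_genome`: uniform-random DNA with telomere arrays (default 40
  motif copies) at both ends and a fixed 500-bp repeat cassette copied at
  a chosen density. No GC structure, no tandem repeat families, no
  centromeres.
* `fragment_genome` / `fragment_genome_at`: contig sets with withheld gap
  sequence, random or explicit cut points, random per-contig
  reverse-complementing, and exact truth adjacencies. Concatenating
  fragments and gaps reproduces the genome byte-for-byte.
* `simulate_long_reads`: normal-truncated lengths, substitution-only
  errors at a constant rate, constant per-read quality at the Phred
  equivalent of the error rate, random strand, origin recorded in the read
  id. No indels (an extension point — substitution-only errors keep the
  k-mer linking tests interpretable), no chimeras, no quality decay along
  the read.
* `simulate_kmer_histogram`: a Poisson toy model — per-k-mer depth
  `Poisson(c*(1-e)^k)`, an optional heterozygous fraction at half depth,
  and error k-mers (k per substitution, assumed unique) at multiplicity 1.
  It reproduces the *shape* a k-mer counter reports without counting reads.
* `simulate_two_pop_genotypes`: Balding-Nichols population frequencies
  `Beta(p(1-F)/F, (1-p)(1-F)/F)` around Uniform(0.05, 0.95) ancestral
  frequencies — the minimal standard model parameterised directly by F_ST;
  no linkage, no demography (a coalescent simulator would provide those).
  Planted outlier windows are fixed differences. VCF output fills QUAL and
  DP so the default filters pass by construction.

Every generator is a pure function of its parameters and seed. Passing
tests on this data demonstrates algorithmic correctness against known
truth; it does not demonstrate robustness to indel-rich reads, segmental
duplications, reference bias, or linked selection, none of which the
generators model.

## Problem sizes used in tests and the acceptance script

Simulations are scaled to desk size: 1-Mb genomes with 10 contigs and
~1,500 reads for scaffolding (link parameters scaled to k = 21,
d = 2,000, 5 links, ratio 0.1); 600-kb genomes for bridging round-trips;
~1,000 10-kb windows with 1,000 permutations for the null-uniformity
check; 2,000-5,000 sites and 20-50 diploids per population for the
genotype scans. At these sizes the full suite and the acceptance script
each complete in well under a minute of CPU-heavy work apiece. Full-scale
genome counts from real sequencing runs depend on deposited reads and are
deliberately not test targets.
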