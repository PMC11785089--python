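# Methods

## Edit calling

A candidate site is emitted from a per-sample pileup iff the reference base
is A with G-supporting reads (or T with C-supporting reads, the minus-strand
image), the site passes `coverage >= 10`, `edited_reads >= 2`, and the edit
fraction lies in the half-open window `[0.05, 0.95)`. No other mismatch
class is ever emitted. The fraction ceiling guards against homozygous
variants that escaped the exome filter (they present at fraction ~1); the
floor suppresses isolated sequencing errors at high depth. These thresholds
follow common practice for pileup-based editing callers and are fully
configurable; nothing in the analysis depends on their exact values beyond
the recovery results quoted by the acceptance script.

Germline exclusion removes any call whose (contig, position) appears in the
line's exome variant set. Matching is by position only, not allele — the
conservative choice: an exome-documented variant position is distrusted
entirely. Strand orientation then resolves each call against the gene
annotation: A>G is A-to-I only on a plus-strand transcript and T>C only on
a minus-strand one; a call lying exclusively in genes of the inconsistent
strand is discarded, and calls in unannotated space are kept with strand
`ambiguous` so that intergenic editing — a major category — survives. A
`drop_ambiguous` switch discards them instead.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based conventions of GFF3, VCF and the pileup/call TSVs happens only in
the I/O layer and is covered by round-trip tests.

## Region and repeat attribution

Each site receives exactly one region category by a priority ladder
evaluated over all genes overlapping the position:
3'UTR > 5'UTR > CDS-exon > intron > intergenic (gene-id lexicographic
tie-break for determinism). "Exon" is implemented as CDS-exon so the
categories are disjoint from the UTRs, which are reported separately; a
`collapse_utr5` switch folds 5'UTR into CDS-exon for a four-category view.
Repeat attribution is independent of region attribution — a 3'UTR SINE
site carries both labels, which matters because retroelements concentrate
in ISG 3'UTRs. When repeat intervals overlap, the smallest interval wins,
with ties broken by class order LINE > SINE > DNA transposon > other.

## Consensus and comparison

Site identity is (contig, position, change); the edit fraction is not part
of identity — the comparison is of presence, not level. A genotype's
consensus sites are the n-fold intersection of its replicates' call sets; a
consensus gene requires at least one genic call in every replicate, so the
supporting sites may differ between animals and the consensus gene set
always contains the gene projection of the consensus site set. The
all-replicates rule is the default; `min_replicates=k` relaxes it.
Consensus sites are annotated from the shared genome annotation, never per
replicate, so annotation is replicate-invariant by construction. The
four-genotype comparison emits the per-genotype counts table, region and
repeat breakdowns, the 15-cell Venn partitions for sites and genes (each
genotype's "unique" set is its singleton cell), and the double-het/WT
site-count ratio.

## Expression statistics

Counts are normalized per million (length-scaled when gene lengths are
supplied) and transformed as log2(x + 1). Differential expression per gene
is a Welch two-sample test on the log scale with Benjamini–Hochberg
adjustment; a gene with zero variance in both groups gets p = 1 when the
means agree. The DEG rule is `|log2FC| >= 1 and q <= 0.05`, both
configurable. This module's claims are about these defined statistics, not
about reproducing any particular DE engine. ISG membership is an input
file (one gene per line); the Interferome-style database it stands in for
is external and versioned, so it is never bundled.

The edited-ISG proportion test builds the 2×2 table
[in-ISG, in-other] × [genotype A, genotype B] over uniquely edited *genic*
sites (intergenic sites have no transcript to classify and are excluded; a
nearest-gene mode is deliberately not the default) and applies a
conditional exact test: with all margins fixed, the two-sided p sums the
probabilities of every table no more probable than the observed one.
Probabilities are compared as exact integer numerators over a common
denominator, so ties need no floating-point epsilon; the test suite checks
the implementation against an independent factorial-based enumeration and
against `scipy.stats.fisher_exact`. The odds ratio is ad/bc with the
Haldane 0.5 correction when a cell is zero; a zero margin is flagged
untestable rather than forced through the test.

## The synthetic study

The generator emulates the four-genotype design (WT, *Adar*⁺/⁻, *RdRp*ᵗᵍ,
double heterozygote; four replicates each) at desk scale. Defaults, chosen
once as a realistic miniature:

| parameter | default | rationale |
|---|---|---|
| genome | 2 contigs × 100 kb, 40 genes, 120 repeats | smallest scale at which every region category and repeat class is well populated |
| ISG fraction (editing study) | 0.25 | keeps genic unique-site 2×2 tables populated |
| planted sites | 500 per genotype; double het = 1.6 × WT exactly | the double-het excess is planted, not sampled, so recovery is checked against a known ratio in the middle of the 50–65% excess band |
| double-het extras | 55% 3'UTR weight, 65% repeat preference (vs 30% / 35% baseline) | produces the 3'UTR/retroelement shift the comparison must detect |
| edit fractions | uniform on [0.2, 0.6] per active site and genotype | intermediate editing levels; configurable to a point mass for calibration checks |
| coverage | NB, mean 30, size 8 (var = μ + μ²/8), gene-level lognormal depth multipliers σ = 0.3 | chosen analytically: P(coverage < 10) ≈ 1.5% and single-replicate recall ≈ 0.95 at fraction 0.3, before any test was run |
| sequencing error | 0.3% per base, uniform to the three other bases | typical post-filter Illumina mismatch rate |
| SNPs | 50 heterozygous A>G / T>C, shared across lines, never colliding with edit sites | exactly the confounder class the exome filter targets |
| expression | NB around lognormal baselines (mean 200, σ = 1), dispersion size 20 (replicate CV ≈ 0.22) | inbred littermate bulk RNA-seq; tight enough that a per-gene Welch test at n = 4 detects 8× effects at ≥ 80% power, the design point the generator is meant to emulate |
| ISG tiers | ×3 (*Adar*⁺/⁻), ×100 (*RdRp*ᵗᵍ), ×400 (double het), per-gene lognormal jitter σ = 0.25 | mild / large / largest induction tiers, with the double het 3–5× above RdRp |
| transgene row | `RdRp_transgene`, mean 500 in transgene-bearing genotypes, exactly 0 elsewhere | countable pseudo-gene analogous to the viral RdRp transcript |

A single top-level seed fans out through
`SeedSequence(seed, spawn_key=(stage, ...))` with fixed stage keys
(genome 0, truth 1, pileups 2 with one child per sample, expression 3), so
every stage is a pure, independently reproducible function of
(config, seed).

Read counts at a position follow a binomial cascade: with edit (or SNP
allele) fraction f and error e, the alternative base is observed with
probability f(1−e) + (1−f)e/3, the reference with (1−f)(1−e) + fe/3, and
each other base with e/3. Heterozygous SNPs use f = 0.5 in every sample.

### What the generator does not emulate

Read-level artifacts (misalignment near splice junctions and indels,
strand bias, PCR duplicates), hyper-edited read clusters, allele-specific
expression, isoform structure, and genuine biological variability in
editing fractions between animals. Passing recovery tests therefore shows
the *logic* of calling, filtering, consensus and comparison is correct
under realistic depth/error statistics — not that the thresholds are
optimal for any particular real aligner's error profile.

### A note on per-million normalization at miniature scale

When strongly induced ISGs are a large fraction of a miniature
transcriptome, their own induction inflates the library total and
compresses their CPM fold changes (the ×100 and ×400 tiers become nearly
indistinguishable). Real transcriptomes have thousands of genes, so the
expression fixtures use 1000 genes with 4% ISGs, where the compression is
mild and the planted tier ordering is cleanly recoverable. The editing-side
default (40 genes, 25% ISGs) is unaffected, since editome comparison never
normalizes by library size.

## Problem sizes used by the tests and acceptance script

Caller recovery uses 2000 planted sites at fraction 0.3 on the default
genome with one sample; SNP-leakage checks run 20 independent miniature
studies; the consensus/Venn/annotation oracles run 100–500 randomized
instances; the null-FDR simulation runs 400 expression simulations of 300
genes; the exact-test sweep enumerates all ~5200 tables with margins ≤ 12.
These sizes make every check stable under a fixed seed while keeping the
whole suite desk-scale.

## Known limitations

* The caller operates on pileups; it cannot model read-level effects, and
  positions absent from the pileup are simply unobserved.
* Consensus is presence/absence; differential editing *levels* are out of
  scope by design.
* The Welch-plus-BH DE summary is a deliberately simple stand-in; for real
  data a negative-binomial GLM engine is preferable, and the module's
  outputs should be read as its own defined statistics.
* Multi-gene overlaps are resolved by a fixed priority ladder; an
  isoform-aware annotation could assign differently.
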