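# Methods

This note documents the models, conventions and numerical choices behind
`dgetags`, and what the synthetic-data generator does and does not emulate.

## Tag model and reference index

A DGE tag is the 21-mer beginning at a CATG (NlaIII) site with at least 17
nt following it. The reference index registers, for every gene, **all**
CATG-anchored 21-mers of the spliced transcript (sense) and of its reverse
complement (antisense) — not only the 3'-most canonical NlaIII site —
because internal priming and antisense transcription both contribute
observable tags. `site_rank` records the 3'-to-5' order per strand
(rank 1 = 3'-most), so a canonical-site-only analysis can filter on it.
A genome-wide tag set (all anchored 21-mers of every chromosome and its
reverse complement) backs the "maps to genome but not to a gene" category.

Queries resolve strictly by stratum: an exact match beats any
single-mismatch (1MM) match, and the 63 Hamming-distance-1 variants are
consulted only when no exact gene hit exists. The genome set is consulted
only when gene hits are absent. `N` never matches in either direction:
reference tags containing N are not indexed, and query tags containing N
return no match. Coordinates are 0-based half-open internally; GFF3 I/O is
1-based inclusive, with spliced transcripts assembled from exon features
strand-aware.

## Extraction and cleaning

Extraction returns the 21-mer at the first CATG with ≥ 17 nt following;
reads without such a site count as "empty". Cleaning applies three filters
in a fixed order — adaptor (exact substring match within the 21-mer), then
N-containing, then singleton (library-wide copy number 1) — and attributes
each removed copy to the first filter it triggers. This makes the fates
disjoint, so the conservation identity

    raw_reads = clean_total + n_empty + n_adaptor + n_lowquality + n_singleton_copies

holds exactly on every run and is asserted in tests. Singleton removal
operates after pooling all reads of one library, never across libraries.
FASTQ quality strings are parsed but unused beyond N detection; there is no
Phred-based trimming and no error-tolerant adaptor matching (tags are only
21 nt, and fuzzy adaptor rules would blur the fate accounting).

## Mapping categories and TPM

Each distinct clean tag falls in exactly one category at its best stratum:
gene-unambiguous (exactly one gene), gene-ambiguous (two or more),
genome-only, or unknown. The three top-level categories partition both the
total and the distinct clean-tag counts; `LibrarySummary.check_partition`
enforces this on every summary. "Tag-mapped genes" includes genes reachable
only through ambiguous hit sets (the reported gene counts exceed the
unambiguous gene counts, which requires this definition); unambiguous and
both-strand gene counts use unambiguous tags only. A tag hitting one gene
at several sites is credited once; a tag hitting one gene in both
orientations at the same stratum is credited as sense (the parsimonious
origin; occurrences are logged).

TPM uses the library's **total clean-tag count** as denominator — not the
mapped count — so per-gene TPM is comparable across libraries with
different mapping rates: `TPM = 1e6 * count / clean_total`. Consequently
per-library TPM sums to 1e6 only when every clean tag maps unambiguously.

## Differential expression

Without replicates, significance comes from the conditional count model:
given the pair total n = x + y of a gene's tag copies, the experimental
count is Binomial(n, q) with q = n_b / (n_a + n_b) — the weight printed in
the module docstring, r^y (x+y)!/(x! y! (1+r)^(x+y)) with r = n_b/n_a, is
exactly that pmf. The two-sided p-value doubles the smaller tail and caps
at 1. Conditioning on the pair total makes the test exactly symmetric
under exchanging the libraries, which in turn makes `compare_libraries`
exactly antisymmetric (swapping control and experimental negates every
log2 ratio and swaps the up/down counts). Tails are computed with the
regularized incomplete beta function (scipy); an exact rational summation
oracle verifies them to 1e-9 relative error over the full x, y ≤ 50 grid.

Screening thresholds are the standard stringent pair: BH FDR ≤ 0.001
(computed per comparison, across all tested genes of that comparison) and
|log2 ratio| ≥ 1. Genes with zero sense counts in both libraries are
excluded before correction. For ratio computation, TPM is floored at 0.001
for genes absent from one library; top-k rankings exclude genes expressed
in only one sample, whose fold changes are floor-driven. Testing uses
sense counts only; antisense profiles are reported but not tested.

## Mid-parent value and non-additivity

The MPV library is built in silico by pooling the parents' raw unambiguous
counts and clean totals — the generative analogue of sequencing an equal
RNA mixture at combined depth. With near-equal parental library sizes this
equals the mean of parental TPMs to first order; pooling counts (rather
than averaging TPMs) keeps the MPV on the count scale the significance
test needs. Non-additivity uses the same statistic and thresholds as DEG
screening. Genes with exactly equal parental TPMs form their own "Br=Bo"
cross-tabulation row rather than being merged into either bias class.

## Library summaries

Abundance distributions default to copy-number bins [2,5], [6,10], [11,20],
[21,50], [51,100], >100 (clean libraries contain no singletons). Saturation
subsamples tag copies without replacement (one shared permutation per
replicate, so each curve is non-decreasing by construction) and counts
genes detected through unambiguous tags; the replicate count is a flag
(default 1). Pairwise ratio distributions use per-million-normalized counts
by default (raw counts behind a flag), folded to ≥ 1 and binned
[1,2), [2,3), [3,4), [4,5], >5 over tags shared by the pair;
library-specific tags are tallied outside the shared denominator.
DEG clustering is agglomerative with average linkage on Euclidean distance
(both are flags), cut at 12 flat clusters by default; cells untested in a
comparison are imputed as 0 (no evidence of change). Enrichment is the
hypergeometric upper tail per term with ≥ 1 foreground gene, BH-corrected
across tested terms, significant at q ≤ 0.05; the background universe is
supplied by the caller (typically all tag-mapped genes of the libraries
being compared).

## Synthetic data: what it emulates, and what it does not

The generator emulates the seven-library allopolyploid design at desk
scale: 2000 genes on 5 chromosomes and one million 35-bp reads per library
by default (depth is a flag). Parental abundances are lognormal
(sigma = 2), giving the characteristic heavy tail — few high-abundance
genes, a long tail of rare ones. 5% of genes per parent are
parent-specific; 36% of genes are antisense-transcribed (30% of their reads
from the reverse strand); 5% of gene pairs share one exact planted 21-mer
(mapping ambiguity). Reads anchor on a gene's CATG sites with the 3'-most
site taking 70% of the gene's reads; per-base substitution errors (0.001),
N masking (0.0002) and whole-read adaptor contamination (0.005) are
applied at rates chosen to reproduce a ≥ 97% clean-tag yield typical of
filtered Illumina tag data. All randomness derives from one seed;
generation is bit-reproducible.

The F1 truth is the mid-parent mixture with log2 deviations planted on 30%
of genes (magnitudes uniform on [1, 3]; 60% upward, echoing the observed
excess of above-MPV genes in resynthesized allopolyploids); F2–F4 shrink
the deviations by half per generation, and the natural library is an
independent draw near MPV.

One property deserves emphasis: abundances are **compositional** (each
library's truth sums to 1), so planting mass-unbalanced deviations
necessarily shifts every other gene's relative abundance — with the
default up-biased planting, additive genes sit ~0.55 log2 below MPV in the
realized mixture, exactly as they would in a real hybrid transcriptome
where total mRNA output changed. Recovery tests for false-flagging of
additive genes therefore use a mass-balanced 4-fold planting (±2, equal
signs), where the residual shift is small; the planted-recovery and
null-calibration checks run under the full defaults.

Not emulated: realistic quality-score models, indels, PCR duplication,
isoform structure (genes are single-exon), chromosome rearrangements, and
homeolog-resolved expression (the two parental subgenomes are not
distinguished within the hybrid).

## Problem sizes

The default test suite runs three 30k-read libraries for the shared
fixture, one 200k-read triple for classification checks, and four
1e6-scale runs in the acceptance tests (about 11 s total for the
acceptance file on one CPU). The acceptance script repeats the 1e6-scale
runs from scratch under its own seed.
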