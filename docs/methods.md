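# Methods

This note documents the models, conventions and numerical choices behind
`apapipe`, and what the synthetic test bench does and does not demonstrate.

## Coordinates and orientation

All internal coordinates are 1-based inclusive genomic positions with
explicit strand (the GFF3 convention); conversion to 0-based half-open
happens only at the BED boundary. "Transcript orientation" means the sense
strand read 5'→3': windows around an anchor on a minus-strand gene are taken
from the reverse complement, so every A-content rule, PAS search and profile
is strand-symmetric by construction. A gene's 3'UTR anchor is
`stop_codon_end`, the genomic coordinate of the last CDS base in transcript
orientation; UTR length runs from the base after it to the cleavage site
inclusive.

## PolyA mapping chain

**Tail extraction.** A read is a polyA read iff its maximal terminal A-run is
≥ `min_tail` (default 30 nt, strict boundary: 29 is rejected). The run is
removed; remainders shorter than the aligner seed (18 nt) are dropped with a
counted reason. Base qualities are ignored.

**Alignment.** The built-in aligner is exact seed-and-extend: an 18-mer hash
of the forward genome, two disjoint seeds per query (so one substitution
anywhere still leaves an exact seed), full-length extension allowing ≤ 1
mismatch, minus-strand hits found by searching the query's reverse
complement. A read with ≥ 2 equally good loci is discarded as multi-mapped;
`longest_consecutive_match` is the full length for exact hits, else the
longer flank around the single mismatch. This contract — unique locus,
strand, leftmost position, longest exact-match run — is all downstream
stages need; externally produced SAM (with MD tags) is accepted through
`io_formats.parse_alignments`, which derives match runs from CIGAR + MD, and
tail lengths travel through a read-id registry so external aligners need no
custom tags.

**Cleavage site.** The last transcribed base: rightmost aligned base on '+',
leftmost on '−'.

**Internal-priming filter.** An event fails when the A fraction in either
30-nt flanking window (the window ending at the site, and the window
starting just after it, both in transcript orientation) is ≥ 65%, or when
`longest_consecutive_match` < 18. The 30-nt window length is a package
choice (matching the 30-A tail threshold); windows truncated at contig edges
use the available bases as denominator. Both thresholds are strict as
printed: 19/30 A (63.3%) with an 18-nt match passes.

**Clustering.** Single-linkage per (contig, strand): consecutive sorted
positions join iff the gap is ≤ 25 nt. The gap value is a package default
chosen so synthetic cluster footprints stay on the scale reported for real
libraries (~tens of nt); it is a parameter. The representative site is the
modal member position, ties broken toward the 3'-most position in transcript
orientation (the most-supported cleavage base, with the distal, conservative
choice on ties). Clustering is permutation-invariant and idempotent;
both properties are tested against a brute-force transitive-closure oracle.

**Gene assignment.** Candidates share the cluster's strand. Distance is 0
inside `[stop_codon_end, annotated 3' end]` and the gap to that interval
otherwise; clusters farther than 1,600 nt stay unassigned. Exact distance
ties go to the gene whose 3' terminus lies nearest upstream of the site.

**Cluster filters.** Per gene, in this order: (1) clusters whose genomic
footprint (sense strand, span inclusive) is > 40% A are discarded;
(2) usage fractions are computed over the survivors and clusters below 5%
usage discarded (5.0% exactly is retained); (3) surviving usage fractions
are renormalized to sum to 1 (± 1e−9, asserted). The ordering is a package
decision; with well-separated sites it is not outcome-sensitive.

## Expression

Union-exon FPKM: `C·10⁹ / (L·N)` with C the fragments assigned by
majority-overlap to the gene's merged exons (same strand; exact overlap ties
and zero overlap are unassigned), L the union-exon length, N the library's
total assigned fragments. FPKM ≥ 1 (inclusive) defines an expressed gene.
Single-end fragments are reads; no isoform deconvolution, TPM or bias
correction is attempted — downstream analyses consume only the gene-level
threshold. Tissue set algebra partitions the union of expressed genes by
exact membership pattern over the 2^k − 1 non-empty cells.

## Isoform catalogs and switch classification

One isoform per retained, gene-assigned cluster of a gene expressed
(FPKM ≥ 1) in that tissue; cleavage upstream of the stop codon is invalid
(excluded, counted) and the remaining usage fractions are renormalized.
Reference-3'UTRome matching uses |Δsite| ≤ 10 nt on the same gene. The
median of UTR-length distributions is the lower middle value for even n
(deterministic).

Switch calls compare each tissue's *dominant* isoform (highest usage; usage
ties break proximal). |ΔUTR| ≤ 10 nt → `same`; otherwise the tissue with the
shorter dominant UTR is the proximal one. A call is *confident* when the
dominant usage fraction is ≥ 0.6 in every tissue compared — this
usage-coverage ratio is the package's reading of a confidence rule based on
PAS coverage ratios, exposed as a parameter. Three-tissue categories come
from the pairwise same/different matrix: all same → `common`; exactly one
same pair → the odd tissue is `<tissue>_distinct`; none → `all_distinct`; a
non-transitive chain (two same pairs that do not close) is treated as
`common`, the conservative direction. UTR lengths, not genomic coordinates,
are compared throughout so strands mix freely.

## Sequence analyses

**PAS classification.** Among hexamers whose last base lies at offsets
−40..−10 from the cleavage site (sense strand), the minimal Hamming distance
to AATAAA wins; ties prefer the offset closest to −19 (the canonical
placement), then the more upstream offset. Distance 0 / 1 / 2 map to
canonical / one_permutation / two_plus_permutations; beyond 2 (or with
insufficient upstream sequence) the call is `none`. The search window and
the substitution reading of "permutation" follow the conventions of the
3'UTRome literature and are parameters, not facts of any data set.

**Cleavage-context profile.** The 70-nt window is the 50 sense-strand bases
ending at the cleavage site plus 20 downstream (−50..+20 with no position
0). Isoforms with truncated windows are excluded and counted; columns of the
4 × 70 frequency matrix sum to 1.

**Promoters.** The promoter is the 600-nt window −500..+100 around the
annotated TSS (gene start on '+', gene end on '−'), transcript orientation;
position +1 is the TSS base. Genes with truncated windows are excluded, as
are operon genes on request (their promoters are not their own). Hexamer
enrichment tiles the window into six 100-nt bins; overlapping hexamer
windows are assigned to the bin of their first base, so bins 1–5 hold 100
windows per promoter and bin 6 holds 95 (windows cannot extend past the
promoter). Target vs control frequencies are compared with a two-proportion
z-test; Benjamini–Hochberg q-values are computed across all hexamer × bin
tests actually observed. The enrichment ratio is primary (it is what the
field reports); p/q-values are guardrails. Controls are seeded random gene
draws of the same size as the target set.

## miRNA-target enrichment

Observed targeted proportion of the switching-gene set vs R (default 1,000,
minimum 100) random draws of the same size, without replacement, from the
expressed background. Two p-values: the two-tailed one-sample t-test of the
resampled proportions against the observed value, and the empirical
two-tailed resampling p with a +1 correction. The t-test is anti-conservative
under the null (it tests whether the control mean equals one observed draw
exactly), so the empirical p is the calibrated quantity: over seeded null
replicates its 5% rejection rate sits in the expected 2–9% band. Any
gene → flag table is accepted; the synthetic generator provides labels per
prediction set with a configurable rate among switching genes vs background.

## The synthetic generator

Defaults: 2 contigs × 200 kb (uniform ACGT, no N), 60 non-overlapping
two-exon genes (600-nt exon 1, 100-nt intron, 400-nt CDS in exon 2), 1–3
cleavage sites per gene with UTR lengths 80–150 nt (proximal) and 120–250 nt
spacing, 3 tissues, 20,000 reads per tissue (100 nt; 35% polyA-tailed, tails
30–60 nt, pure A; per-base substitution rate 0.001 outside tails), 8
priming traps (35-nt A-runs, half intergenic, half inside first exons), a
TGATAA promoter motif planted into bin 5 (−100..−1) of 40% of genes, PAS
hexamers 80% canonical / 20% single-substitution, and miRNA-target rates
0.5 (switching genes) vs 0.2 (background). Expression is log-normal
(log₁₀ mean 1.0, σ 0.4); half the genes are expressed in all tissues, the
rest in a random proper subset. Among multi-site genes, half switch their
dominant site (usage 0.7) between tissues. Each cleavage base is pinned to a
non-A so tail trimming stops exactly at the site; trap A-runs carry non-A
flanks so artifact reads have a defined apparent cleavage position. The
sizes keep an end-to-end run at a few seconds on one CPU while leaving
~100 polyA reads per expressed gene per tissue — enough that the recovery
checks measure the method, not counting noise.

What the generator does *not* emulate: indels, quality decay, PCR
duplicates, paired ends, unannotated splicing, trans-splicing at the TSS,
overlapping genes and operonic transcription units, and biological A-rich
3'UTRs that sit near the filter boundaries. Passing tests therefore
demonstrate the correctness of the rules and the recoverability of planted
signals under clean conditions, not performance on real libraries.

## Degenerate inputs and tie-breaks (summary)

Empty read sets, empty truth tables, empty promoter/isoform sets all return
explicit empty markers or header-only files. All filter inequalities are
strict as stated above. Deterministic tie-breaks: modal cluster
representative → 3'-most; gene-assignment distance tie → upstream gene;
dominant-isoform usage tie → proximal; PAS distance tie → offset closest to
−19, then more upstream. Every randomized component takes an explicit seed
and is bit-reproducible.
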