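# apapipe

Tissue-resolved polyA-site mapping and alternative-polyadenylation (APA)
analysis for 3'-end-tagged RNA-seq libraries, with a synthetic-data test
bench that makes every stage verifiable against ground truth.

## The problem

Most eukaryotic genes can end their mRNAs at more than one cleavage and
polyadenylation site, producing 3'UTR isoforms that differ in the regulatory
sequence (e.g. miRNA target sites) they carry. Libraries that capture
polyadenylated 3' ends — reads terminating in a long untemplated poly(A)
tail — let you map these cleavage sites per tissue, but the raw signal is
contaminated by *internal priming*: reads whose terminal A-run is templated
by an A-rich stretch of genome rather than a real poly(A) tail. `apapipe`
implements the complete analysis chain:

1. **polyA read extraction** — keep reads whose maximal terminal A-run is
   ≥ 30 nt, trim the run, and align the remainder (built-in seed-and-extend
   aligner, or any external SAM).
2. **Cleavage-site mapping and internal-priming filters** — an event is
   discarded if either 30-nt window flanking the cleavage site is ≥ 65% A in
   transcript orientation, or the alignment has < 18 consecutively matching
   nucleotides.
3. **PAS clustering and gene assignment** — single-linkage clustering of
   cleavage positions (gap ≤ 25 nt), each cluster attached to the closest
   same-strand gene within 1,600 nt of its 3' end; clusters with < 5% of a
   gene's polyA reads or a > 40%-A genomic footprint are dropped and the
   survivors' usage fractions renormalized.
4. **Expression** — union-exon FPKM (`C·10⁹ / (L·N)`), with FPKM ≥ 1
   defining an expressed gene, and the tissue set algebra of shared/unique
   expressed genes.
5. **3'UTR isoform catalogs and APA switches** — per-tissue isoforms with
   UTR lengths counted from the stop codon, reference-3'UTRome overlap at
   ± 10 nt, and pairwise / three-tissue switch classification on dominant
   isoforms (proximal vs distal, with a usage-dominance confidence rule).
6. **Sequence analyses** — PAS hexamer classification (AAUAAA and its
   single/double substitutions, searched upstream of the cleavage site),
   −50..+20 cleavage-context nucleotide profiles, −500..+100 promoter
   profiles and 100-nt-bin hexamer enrichment against random gene controls.
7. **miRNA-target enrichment** — targeted proportion of switching genes vs
   R random size-matched draws from the expressed background (one-sample
   t-test plus an empirical resampling p-value).

The `synthetic` module generates a toy genome in which every one of these
signals is planted with known parameters — cleavage sites with AATAAA ending
19 nt upstream, per-tissue isoform-usage mixtures, A-run priming traps,
promoter motifs, and miRNA-target labels — so the whole pipeline can be
validated end to end without any sequencing data.

## Worked example

```python
from apapipe import SimulationConfig, run_synthetic_pipeline
from apapipe.pipeline import site_recovery, switch_accuracy, trap_removal

result = run_synthetic_pipeline(SimulationConfig(seed=1))
for tissue, tr in result.tissues.items():
    retained = sum(1 for c in tr.map_result.clusters if c.retained)
    print(tissue, dict(tr.map_result.accounting), retained, len(tr.expressed_genes))
print(site_recovery(result))
print(trap_removal(result))
print(switch_accuracy(result))
```

prints (default study conditions: 2 × 200 kb contigs, 60 genes, 3 tissues,
20,000 reads per tissue):

```
intestine {'no_tail': 12918, 'unaligned': 11, 'filtered_a_rich_downstream': 123, 'clustered': 6948} 90 48
pharynx {'no_tail': 12918, 'unaligned': 9, 'filtered_a_rich_downstream': 124, 'clustered': 6949} 93 48
body_muscle {'no_tail': 12916, 'unaligned': 12, 'filtered_a_rich_downstream': 126, 'clustered': 6946} 87 49
{'n_sites': 112, 'n_recovered': 112, 'fraction': 1.0}
{'n_trap_events': 359, 'n_removed': 359, 'fraction_removed': 1.0, 'retained_trap_clusters': 0}
{'n_calls': 114, 'accuracy': 1.0}
```

Reading: per tissue, ~6,950 reads carried a qualifying poly(A) tail and
survived alignment and the internal-priming filter ("clustered"); ~125
events per tissue — the planted artifact reads plus a few body reads ending
in a templated A-run — were removed as A-rich internal priming; 87–93
clusters per tissue survive the usage and footprint filters. All 112 planted
cleavage sites are recovered within ±10 nt, every trap-derived event is
filtered, and all 114 pairwise gene comparisons reproduce the planted
same/proximal/distal switch labels.

Every stage is also exposed on the command line:

```bash
apapipe simulate --outdir sim --seed 1
apapipe map-polya --genome sim/genome.fa --annotation sim/annotation.gff3 \
    --reads sim/reads_intestine.fastq --out mapped
apapipe quantify --genome sim/genome.fa --annotation sim/annotation.gff3 \
    --reads sim/reads_intestine.fastq --tissue intestine --out expr.tsv
apapipe apa --clusters mapped/clusters.tsv --annotation sim/annotation.gff3 \
    --expression expr.tsv --tissue intestine --out apa_out
```

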