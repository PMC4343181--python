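"""Union-exon FPKM quantification, expression thresholding and tissue set algebra.

Gene expression is summarized as FPKM over the union-exon model:
FPKM = C * 1e9 / (L * N) with C the fragments assigned to the gene, L the
union-exon length in nt and N the total assigned fragments in the library.
A gene counts as expressed at FPKM >= 1 (inclusive) by default.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass

DEFAULT_FPKM_THRESHOLD = 1.0


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tissue: str
    fragment_count: int
    union_exon_length: int
    total_assigned: int
    fpkm: float
    expressed: bool


def assign_fragments(alignments, annotation):
    """Assign each fragment to the same-strand gene it overlaps most.

    Overlap is measured against the gene's union-exon intervals; ties and
    zero overlap leave the fragment unassigned. Returns (Counter per gene,
    n_unassigned); counts + unassigned == len(alignments).
    """
    by_group = defaultdict(list)
    for g in (annotation.values() if isinstance(annotation, dict) else annotation):
        by_group[(g.contig, g.strand)].append(g)
    index = {}
    for key, genes in by_group.items():
        genes.sort(key=lambda g: g.gene_start)
        starts = [g.gene_start for g in genes]
        max_len = max(g.gene_end - g.gene_start + 1 for g in genes)
        index[key] = (starts, genes, max_len)

    counts: Counter = Counter()
    unassigned = 0
    for aln in alignments:
        frag_lo = aln.leftmost_position + 1
        frag_hi = aln.leftmost_position + aln.aligned_span
        entry = index.get((aln.contig, aln.strand))
        best_gene, best_ov, tie = None, 0, False
        if entry is not None:
            starts, genes, max_len = entry
            i = bisect.bisect_right(starts, frag_hi)
            j = bisect.bisect_left(starts, frag_lo - max_len)
            for g in genes[j:i]:
                if g.gene_end < frag_lo:
                    continue
                ov = 0
                for s, e in g.union_exons():
                    ov += max(0, min(e, frag_hi) - max(s, frag_lo) + 1)
                if ov > best_ov:
                    best_gene, best_ov, tie = g.gene_id, ov, False
                elif ov == best_ov and ov > 0:
                    tie = True
        if best_gene is None or tie:
            unassigned += 1
        else:
            counts[best_gene] += 1
    return counts, unassigned


def compute_fpkm(counts: Counter, annotation, total_assigned: int, tissue: str,
                 threshold: float = DEFAULT_FPKM_THRESHOLD):
    """FPKM per gene. Genes with zero union-exon length are skipped."""
    if total_assigned <= 0:
        raise ValueError("total assigned fragment count must be positive")
    records = []
    genes = annotation.values() if isinstance(annotation, dict) else annotation
    for g in sorted(genes, key=lambda g: g.gene_id):
        L = g.union_exon_length
        if L <= 0:
            continue
        C = counts.get(g.gene_id, 0)
        fpkm = C * 1e9 / (L * total_assigned)
        records.append(ExpressionRecord(
            gene_id=g.gene_id, tissue=tissue, fragment_count=C,
            union_exon_length=L, total_assigned=total_assigned,
            fpkm=fpkm, expressed=fpkm >= threshold))
    return records


def expressed_gene_set(records) -> set:
    return {r.gene_id for r in records if r.expressed}


def tissue_gene_sets(records_by_tissue: dict) -> dict:
    """Partition expressed genes by tissue-membership pattern.

    `records_by_tissue` maps tissue -> ExpressionRecord list (or a gene set).
    Returns {frozenset(tissues): set(genes)} over the 2^k - 1 non-empty cells;
    the cells partition the union of expressed genes exactly.
    """
    if len(records_by_tissue) < 2:
        raise ValueError("tissue set algebra needs at least two tissues")
    sets = {}
    for tissue, recs in records_by_tissue.items():
        sets[tissue] = set(recs) if isinstance(recs, set) else expressed_gene_set(recs)
    membership = defaultdict(set)
    for gene in set.union(*sets.values()):
        pattern = frozenset(t for t, s in sets.items() if gene in s)
        membership[pattern].add(gene)
    return dict(membership)
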