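"""Per-tissue 3'UTR isoform catalogs, reference-3'UTRome comparison and
tissue-specific APA switch classification.

3'UTR length is counted in transcript orientation from the base after the
last CDS base to the cleavage site inclusive, so plus- and minus-strand genes
are handled uniformly and switch calls compare UTR lengths rather than raw
genomic coordinates. Two sites match when their separation is within the
10 nt tolerance used throughout the 3'UTRome comparisons.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

DEFAULT_TOLERANCE = 10
DEFAULT_DOMINANCE = 0.6


@dataclass(frozen=True)
class UtrIsoform:
    gene_id: str
    tissue: str
    cleavage_site: int
    utr_length: int
    usage_fraction: float
    source_cluster: str


@dataclass(frozen=True)
class SwitchCall:
    gene_id: str
    tissues: tuple
    sites: tuple          # dominant utr_length per tissue, tissue order
    call: str             # 'same' | 'proximal_in:<tissue>' | three-tissue category
    confident: bool


def build_isoform_catalog(clusters, annotation, expressed_genes: set, tissue: str):
    """One UtrIsoform per retained, gene-assigned cluster of an expressed gene.

    Clusters of genes below the expression threshold yield no isoforms.
    Cleavage upstream of the stop codon marks the isoform invalid (excluded
    and counted); per-gene usage fractions are renormalized over the valid
    isoforms. Returns (isoforms, accounting Counter).
    """
    accounting = Counter()
    per_gene = defaultdict(list)
    for c in clusters:
        if not c.retained or c.assigned_gene is None:
            continue
        gene = annotation[c.assigned_gene]
        if gene.gene_id not in expressed_genes:
            accounting["gene_not_expressed"] += 1
            continue
        if gene.stop_codon_end is None:
            accounting["no_stop_codon"] += 1
            continue
        if gene.strand == "+":
            utr = c.representative_site - gene.stop_codon_end
        else:
            utr = gene.stop_codon_end - c.representative_site
        if utr < 0:
            accounting["upstream_of_stop"] += 1
            continue
        per_gene[gene.gene_id].append((c, utr))
        accounting["isoform"] += 1
    isoforms = []
    for gid, pairs in sorted(per_gene.items()):
        total = sum(c.usage_fraction for c, _ in pairs)
        for c, utr in pairs:
            isoforms.append(UtrIsoform(
                gene_id=gid, tissue=tissue, cleavage_site=c.representative_site,
                utr_length=utr, usage_fraction=c.usage_fraction / total,
                source_cluster=c.cluster_id))
    return isoforms, accounting


def match_reference_utrome(isoforms, reference, tolerance: int = DEFAULT_TOLERANCE):
    """Classify each isoform as in_ref / novel against a (gene, site) table.

    `reference` is an iterable of (gene_id, cleavage_site) pairs. A match
    requires the same gene and |site - ref_site| <= tolerance. Returns
    (per-isoform bool list aligned with `isoforms`, summary dict).
    """
    by_gene = defaultdict(list)
    for gene_id, site in reference:
        by_gene[gene_id].append(int(site))
    flags = []
    for iso in isoforms:
        flags.append(any(abs(iso.cleavage_site - s) <= tolerance
                         for s in by_gene.get(iso.gene_id, ())))
    n = len(flags)
    matched = sum(flags)
    summary = {
        "n_isoforms": n,
        "n_in_ref": matched,
        "n_novel": n - matched,
        "fraction_in_ref": matched / n if n else float("nan"),
    }
    return flags, summary


def utr_length_stats(isoforms, bin_width: int = 25):
    """Median (lower of the middle pair for even n), mean and histogram."""
    lengths = sorted(iso.utr_length for iso in isoforms)
    if not lengths:
        return {"n": 0, "median": None, "mean": None, "histogram": None}
    n = len(lengths)
    median = lengths[(n - 1) // 2]
    mean = sum(lengths) / n
    upper = (max(lengths) // bin_width + 1) * bin_width
    counts, edges = np.histogram(lengths, bins=np.arange(0, upper + bin_width, bin_width))
    return {"n": n, "median": median, "mean": mean,
            "histogram": (counts.tolist(), edges.tolist())}


def isoform_count_distribution(isoforms):
    """Genes with 1 / 2 / >=3 isoforms and the isoform:gene ratio."""
    per_gene = Counter(iso.gene_id for iso in isoforms)
    dist = {"1": 0, "2": 0, "3+": 0}
    for n in per_gene.values():
        dist["1" if n == 1 else "2" if n == 2 else "3+"] += 1
    n_genes = len(per_gene)
    return {"genes_by_isoform_count": dist, "n_genes": n_genes,
            "n_isoforms": len(isoforms),
            "isoforms_per_gene": len(isoforms) / n_genes if n_genes else float("nan")}


def _dominant(isoforms):
    """Highest-usage isoform; usage ties break toward the proximal site."""
    return max(isoforms, key=lambda i: (i.usage_fraction, -i.utr_length))


def classify_pairwise_switch(gene_id: str, isoforms_a, isoforms_b,
                             tissue_a: str, tissue_b: str,
                             tolerance: int = DEFAULT_TOLERANCE,
                             dominance: float = DEFAULT_DOMINANCE) -> SwitchCall:
    """Compare a gene's dominant isoform between two tissues.

    Within `tolerance` nt of UTR length the gene keeps the same isoform;
    otherwise the tissue with the shorter dominant UTR uses the proximal site.
    The call is confident when the dominant usage fraction reaches
    `dominance` in both tissues.
    """
    a, b = _dominant(isoforms_a), _dominant(isoforms_b)
    confident = a.usage_fraction >= dominance and b.usage_fraction >= dominance
    if abs(a.utr_length - b.utr_length) <= tolerance:
        call = "same"
    elif a.utr_length < b.utr_length:
        call = f"proximal_in:{tissue_a}"
    else:
        call = f"proximal_in:{tissue_b}"
    return SwitchCall(gene_id=gene_id, tissues=(tissue_a, tissue_b),
                      sites=(a.utr_length, b.utr_length), call=call,
                      confident=confident)


def classify_three_tissue(gene_id: str, isoforms_by_tissue: dict,
                          tolerance: int = DEFAULT_TOLERANCE) -> SwitchCall:
    """Category of a gene's dominant isoforms across three tissues.

    All pairwise-same -> 'common'; exactly one tissue differing from the two
    (mutually same) others -> '<tissue>_distinct'; no pair the same ->
    'all_distinct'. A non-transitive chain (two same-pairs that do not close)
    is treated as 'common', the conservative direction.
    """
    tissues = tuple(isoforms_by_tissue)
    if len(tissues) != 3:
        raise ValueError("three-tissue classification needs exactly three tissues")
    dom = {t: _dominant(isos) for t, isos in isoforms_by_tissue.items()}
    lengths = {t: dom[t].utr_length for t in tissues}
    same = {}
    pairs = [(tissues[0], tissues[1]), (tissues[0], tissues[2]), (tissues[1], tissues[2])]
    for t1, t2 in pairs:
        same[(t1, t2)] = abs(lengths[t1] - lengths[t2]) <= tolerance
    n_same = sum(same.values())
    if n_same >= 2:
        call = "common"
    elif n_same == 0:
        call = "all_distinct"
    else:
        (t1, t2), = [p for p, s in same.items() if s]
        (odd,) = [t for t in tissues if t not in (t1, t2)]
        call = f"{odd}_distinct"
    confident = all(dom[t].usage_fraction >= DEFAULT_DOMINANCE for t in tissues)
    return SwitchCall(gene_id=gene_id, tissues=tissues,
                      sites=tuple(lengths[t] for t in tissues),
                      call=call, confident=confident)


def pairwise_switch_table(catalog_a, catalog_b, tissue_a, tissue_b,
                          tolerance: int = DEFAULT_TOLERANCE,
                          dominance: float = DEFAULT_DOMINANCE):
    """Switch calls for every gene with isoforms in both catalogs."""
    by_gene_a = defaultdict(list)
    by_gene_b = defaultdict(list)
    for iso in catalog_a:
        by_gene_a[iso.gene_id].append(iso)
    for iso in catalog_b:
        by_gene_b[iso.gene_id].append(iso)
    calls = []
    for gid in sorted(set(by_gene_a) & set(by_gene_b)):
        calls.append(classify_pairwise_switch(
            gid, by_gene_a[gid], by_gene_b[gid], tissue_a, tissue_b,
            tolerance=tolerance, dominance=dominance))
    return calls


def three_tissue_table(catalogs: dict, tolerance: int = DEFAULT_TOLERANCE):
    """Three-tissue categories for genes cataloged in all three tissues."""
    by_gene = {t: defaultdict(list) for t in catalogs}
    for t, catalog in catalogs.items():
        for iso in catalog:
            by_gene[t][iso.gene_id].append(iso)
    shared = set.intersection(*(set(m) for m in by_gene.values()))
    calls = []
    for gid in sorted(shared):
        calls.append(classify_three_tissue(
            gid, {t: by_gene[t][gid] for t in catalogs}, tolerance=tolerance))
    return calls
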