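"""End-to-end orchestration on synthetic data, plus truth-based evaluation.

`run_synthetic_pipeline` generates a data set under a SimulationConfig and
pushes every tissue through polyA mapping, expression quantification and
isoform cataloging. The evaluation helpers score the results against the
generator's ground truth; they are what the acceptance checks and the
recovery tests consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from . import apa, expression, polya
from .synthetic import (SimulationConfig, Truth, generate_genome_and_annotation,
                        parse_read_id, simulate_tissue_reads)


@dataclass
class TissueResult:
    tissue: str
    map_result: polya.PolyAMapResult
    expression_records: list
    expressed_genes: set
    isoforms: list
    isoform_accounting: dict
    n_unassigned_fragments: int


@dataclass
class PipelineResult:
    config: SimulationConfig
    genome: dict
    annotation: dict
    truth: Truth
    tissues: dict = field(default_factory=dict)  # tissue -> TissueResult

    def catalogs(self) -> dict:
        return {t: r.isoforms for t, r in self.tissues.items()}


def run_tissue(reads, genome, annotation, index, tissue: str,
               fpkm_threshold: float = 1.0, **map_params) -> TissueResult:
    """Map one tissue's reads and build its expression table and catalog.

    All reads (tailed and body) feed the expression estimate: tailed reads
    enter as their trimmed alignments, body reads are aligned directly.
    """
    reads = list(reads)
    map_result = polya.map_polya_reads(reads, genome, annotation, index=index,
                                       **map_params)
    # body reads = everything without a qualifying tail; tailed alignments
    # are reused from the mapping stage
    trimmed, _ = polya.extract_polya_reads(reads, min_length=index.seed_length)
    polya_read_ids = {r.read_id for r in trimmed}
    body_reads = [polya.TrimmedPolyARead(rid, seq, 0)
                  for rid, seq in reads if rid not in polya_read_ids]
    body_alns, _ = polya.align_reads(body_reads, index)
    all_alns = body_alns + map_result.alignments
    counts, n_unassigned = expression.assign_fragments(all_alns, annotation)
    total = sum(counts.values())
    records = expression.compute_fpkm(counts, annotation, total, tissue,
                                      threshold=fpkm_threshold)
    expressed = expression.expressed_gene_set(records)
    isoforms, iso_acc = apa.build_isoform_catalog(
        map_result.clusters, annotation, expressed, tissue)
    return TissueResult(tissue=tissue, map_result=map_result,
                        expression_records=records, expressed_genes=expressed,
                        isoforms=isoforms, isoform_accounting=dict(iso_acc),
                        n_unassigned_fragments=n_unassigned)


def run_synthetic_pipeline(config: SimulationConfig | None = None,
                           **map_params) -> PipelineResult:
    """Generate a synthetic data set and analyze every tissue."""
    config = config or SimulationConfig()
    genome, annotation, truth = generate_genome_and_annotation(config)
    index = polya.GenomeIndex(genome)
    result = PipelineResult(config=config, genome=genome,
                            annotation=annotation, truth=truth)
    for tissue in config.tissue_names:
        reads = simulate_tissue_reads(genome, annotation, truth, tissue, config)
        result.tissues[tissue] = run_tissue(reads, genome, annotation, index,
                                            tissue)
    return result


# ---------------------------------------------------------------------------
# truth-based evaluation
# ---------------------------------------------------------------------------

def site_recovery(result: PipelineResult, tolerance: int = 10) -> dict:
    """Fraction of true cleavage sites recovered by a retained cluster.

    A (gene, site) with planted reads in at least one tissue counts as
    recovered when any tissue has a retained cluster for that gene whose
    representative site is within +-tolerance.
    """
    truth_sites = result.truth.recoverable_sites()
    recovered = 0
    rows = len(truth_sites)
    reps = {}
    for t, tr in result.tissues.items():
        for c in tr.map_result.clusters:
            if c.retained and c.assigned_gene:
                reps.setdefault(c.assigned_gene, []).append(c.representative_site)
    for _, row in truth_sites.iterrows():
        sites = reps.get(row.gene_id, ())
        if any(abs(s - row.cleavage_site) <= tolerance for s in sites):
            recovered += 1
    return {"n_sites": rows, "n_recovered": recovered,
            "fraction": recovered / rows if rows else float("nan")}


def trap_removal(result: PipelineResult) -> dict:
    """How thoroughly internal-priming artifacts were filtered.

    Counts trap-derived reads that produced a cleavage event and the fraction
    the priming filter removed, plus retained clusters overlapping trap loci.
    """
    n_events = n_removed = 0
    for tr in result.tissues.values():
        for rid, outcome in tr.map_result.event_filter.items():
            if parse_read_id(rid)["kind"] == "trap":
                n_events += 1
                if outcome != "passed":
                    n_removed += 1
    traps = result.truth.traps
    n_trap_clusters = 0
    for tr in result.tissues.values():
        for c in tr.map_result.clusters:
            if not c.retained:
                continue
            hit = traps[(traps.contig == c.contig)
                        & (traps.start - 50 <= c.representative_site)
                        & (traps.end + 50 >= c.representative_site)]
            if len(hit):
                n_trap_clusters += 1
    return {"n_trap_events": n_events, "n_removed": n_removed,
            "fraction_removed": n_removed / n_events if n_events else float("nan"),
            "retained_trap_clusters": n_trap_clusters}


def usage_accuracy(result: PipelineResult, min_reads: int = 50) -> dict:
    """Mean absolute error of estimated vs planted usage fractions.

    Restricted to (gene, tissue) pairs whose retained clusters carry at least
    `min_reads` polyA reads; estimated cluster usage is matched to the nearest
    true site within 10 nt (unmatched clusters score against usage 0).
    """
    errors = []
    for tissue, tr in result.tissues.items():
        by_gene = {}
        for c in tr.map_result.clusters:
            if c.retained and c.assigned_gene:
                by_gene.setdefault(c.assigned_gene, []).append(c)
        for gene, clusters in by_gene.items():
            if sum(c.read_count for c in clusters) < min_reads:
                continue
            true_usage = result.truth.usage_map(gene, tissue)
            if not true_usage:
                continue
            for c in clusters:
                best = min(true_usage, key=lambda s: abs(s - c.representative_site))
                planted = (true_usage[best]
                           if abs(best - c.representative_site) <= 10 else 0.0)
                errors.append(abs(c.usage_fraction - planted))
    return {"n_clusters": len(errors),
            "mean_abs_error": float(np.mean(errors)) if errors else float("nan")}


def switch_accuracy(result: PipelineResult, tolerance: int = 10) -> dict:
    """Agreement of pairwise switch calls with the planted usage mixtures.

    Truth for a (gene, tissue pair): 'same' iff the planted dominant sites
    give UTR lengths within the tolerance, else a switch with the proximal
    tissue determined by the shorter dominant UTR.
    """
    tissues = list(result.config.tissue_names)
    catalogs = result.catalogs()
    n_calls = n_correct = 0
    for i in range(len(tissues)):
        for j in range(i + 1, len(tissues)):
            ta, tb = tissues[i], tissues[j]
            calls = apa.pairwise_switch_table(catalogs[ta], catalogs[tb], ta, tb,
                                              tolerance=tolerance)
            for call in calls:
                gene = result.annotation[call.gene_id]
                da = result.truth.dominant_site(call.gene_id, ta)
                db = result.truth.dominant_site(call.gene_id, tb)
                if gene.strand == "+":
                    ua, ub = da - gene.stop_codon_end, db - gene.stop_codon_end
                else:
                    ua, ub = gene.stop_codon_end - da, gene.stop_codon_end - db
                if abs(ua - ub) <= tolerance:
                    expected = "same"
                elif ua < ub:
                    expected = f"proximal_in:{ta}"
                else:
                    expected = f"proximal_in:{tb}"
                n_calls += 1
                n_correct += call.call == expected
    return {"n_calls": n_calls,
            "accuracy": n_correct / n_calls if n_calls else float("nan")}


def expression_correlation(result: PipelineResult) -> dict:
    """Spearman correlation of FPKM against true abundance, per tissue."""
    out = {}
    for tissue, tr in result.tissues.items():
        truth = result.truth.sites
        ab = (truth[truth.tissue == tissue]
              .drop_duplicates("gene_id").set_index("gene_id").abundance)
        fpkm, true = [], []
        for rec in tr.expression_records:
            fpkm.append(rec.fpkm)
            true.append(float(ab.get(rec.gene_id, 0.0)))
        rho = spearmanr(fpkm, true).statistic
        out[tissue] = float(rho)
    return out
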