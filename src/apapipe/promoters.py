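"""Promoter extraction, positional nucleotide profiles, and 100-nt-bin
hexamer enrichment against random-gene controls.

A promoter is the 600-nt window from -500 to +100 around the annotated TSS in
transcript orientation (position +1 is the TSS base; there is no position 0).
Hexamer enrichment tiles the window into six 100-nt bins, counts overlapping
hexamer windows by the bin of their first base, and compares target against
control frequencies with a two-proportion z-test, Benjamini-Hochberg
corrected; the raw frequency ratio is reported alongside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .sequtil import fetch_oriented

PROMOTER_UP = 500
PROMOTER_DOWN = 100
PROMOTER_LEN = PROMOTER_UP + PROMOTER_DOWN
N_BINS = 6
_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    sequence: str  # exactly 600 nt, transcript orientation

    def __post_init__(self):
        if len(self.sequence) != PROMOTER_LEN:
            raise ValueError("promoter sequence must be exactly 600 nt")


def extract_promoter_regions(gene_ids, annotation, genome: dict,
                             exclude_operons: bool = False):
    """-500..+100 windows around each gene's TSS, transcript orientation.

    Genes whose window would overhang a contig edge are excluded and counted,
    as are operon genes when `exclude_operons` is set. Returns (promoters,
    accounting Counter).
    """
    promoters = []
    accounting = Counter()
    for gid in gene_ids:
        gene = annotation[gid]
        if exclude_operons and gene.in_operon:
            accounting["operon"] += 1
            continue
        tss = gene.tss
        if gene.strand == "+":
            lo, hi = tss - PROMOTER_UP, tss + PROMOTER_DOWN - 1
        else:
            lo, hi = tss - PROMOTER_DOWN + 1, tss + PROMOTER_UP
        seq = fetch_oriented(genome, gene.contig, gene.strand, lo, hi)
        if len(seq) != PROMOTER_LEN:
            accounting["truncated_window"] += 1
            continue
        promoters.append(PromoterRegion(gid, seq))
        accounting["extracted"] += 1
    return promoters, accounting


def positional_nucleotide_profile(promoters):
    """4 x 600 per-position frequency matrix (rows A/C/G/T); None if empty."""
    if not promoters:
        return None
    counts = np.zeros((4, PROMOTER_LEN), dtype=float)
    for p in promoters:
        for j, base in enumerate(p.sequence):
            if base in _ROW:
                counts[_ROW[base], j] += 1
    return counts / counts.sum(axis=0, keepdims=True)


def _bin_hexamer_counts(promoters, n_bins: int):
    """Per-bin Counter of hexamer windows, window assigned to its start's bin."""
    bin_size = PROMOTER_LEN // n_bins
    counters = [Counter() for _ in range(n_bins)]
    totals = [0] * n_bins
    for p in promoters:
        seq = p.sequence
        for start in range(PROMOTER_LEN - 5):
            b = start // bin_size
            counters[b][seq[start:start + 6]] += 1
            totals[b] += 1
    return counters, totals


def hexamer_bin_enrichment(target_promoters, control_promoters,
                           n_bins: int = N_BINS) -> pd.DataFrame:
    """Hexamer x bin enrichment of target over control promoter sets.

    For every hexamer observed in either set and every bin: occurrence
    frequencies, target/control ratio, two-proportion z-test p-value and BH
    q-value across all tests. Sorted by q then p then descending ratio, so
    the first row is the top-ranked enrichment.
    """
    if not target_promoters or not control_promoters:
        raise ValueError("both promoter sets must be non-empty")
    t_counts, t_totals = _bin_hexamer_counts(target_promoters, n_bins)
    c_counts, c_totals = _bin_hexamer_counts(control_promoters, n_bins)
    rows = []
    for b in range(n_bins):
        n_t, n_c = t_totals[b], c_totals[b]
        for hexamer in sorted(set(t_counts[b]) | set(c_counts[b])):
            x_t, x_c = t_counts[b][hexamer], c_counts[b][hexamer]
            f_t, f_c = x_t / n_t, x_c / n_c
            pooled = (x_t + x_c) / (n_t + n_c)
            se = np.sqrt(pooled * (1 - pooled) * (1 / n_t + 1 / n_c))
            if se > 0:
                z = (f_t - f_c) / se
                p = 2 * norm.sf(abs(z))
            else:
                p = 1.0
            ratio = f_t / f_c if f_c > 0 else np.inf
            rows.append((hexamer, b + 1, x_t, x_c, f_t, f_c, ratio, p))
    df = pd.DataFrame(rows, columns=["hexamer", "bin", "target_count",
                                     "control_count", "target_freq",
                                     "control_freq", "enrichment_ratio",
                                     "p_value"])
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(["q_value", "p_value", "enrichment_ratio"],
                        ascending=[True, True, False], kind="mergesort")
    return df.reset_index(drop=True)


def tataa_frequency(promoters) -> float:
    """Fraction of promoters containing TATAA at least once (presence)."""
    if not promoters:
        return 0.0
    return sum("TATAA" in p.sequence for p in promoters) / len(promoters)


def random_control_promoters(annotation, genome: dict, n: int, rng,
                             exclude: set | None = None):
    """A seeded random draw of n gene promoters as a control set."""
    pool = sorted(g for g in annotation if not exclude or g not in exclude)
    if n > len(pool):
        raise ValueError("control pool smaller than requested size")
    chosen = rng.choice(pool, size=n, replace=False)
    promoters, _ = extract_promoter_regions(sorted(chosen), annotation, genome)
    return promoters
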