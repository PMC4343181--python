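"""Polyadenylation-signal (PAS) hexamer classification and cleavage-context
nucleotide profiling.

The canonical PAS is AAUAAA (DNA sense AATAAA), typically ending ~19 nt
upstream of the cleavage site. A candidate hexamer is searched among all
windows whose last base falls in a configurable offset range upstream of the
cleavage site; "permutations" of the canonical element are single-base
substitutions, i.e. Hamming distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .sequtil import fetch_oriented, hamming

CANONICAL_PAS = "AATAAA"
DEFAULT_SEARCH_WINDOW = (-40, -10)  # offsets of the hexamer's last base
CANONICAL_OFFSET = -19
PROFILE_UP = 50   # bases up to and including the cleavage site
PROFILE_DOWN = 20
PAS_CLASSES = ("canonical", "one_permutation", "two_plus_permutations", "none")

_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PasCall:
    gene_id: str
    tissue: str
    cleavage_site: int
    pas_hexamer: str | None
    pas_class: str
    pas_position: int | None  # offset of the hexamer's last base, negative


def classify_pas(isoform, genome: dict, contig: str, strand: str,
                 search_window: tuple = DEFAULT_SEARCH_WINDOW,
                 max_distance: int = 2) -> PasCall:
    """Best PAS hexamer upstream of an isoform's cleavage site.

    Among hexamers whose last base lies at offsets search_window (transcript
    orientation, sense strand), the minimal-Hamming-distance hexamer wins;
    distance ties break toward the offset closest to -19, then the more
    upstream offset. Distance 0/1/2 maps to canonical / one_permutation /
    two_plus_permutations; nothing within max_distance (or insufficient
    upstream sequence) gives class 'none'.
    """
    site = isoform.cleavage_site
    lo_off, hi_off = search_window
    # sense-strand sequence covering every candidate hexamer
    span = hi_off - lo_off + 6
    if strand == "+":
        seq = fetch_oriented(genome, contig, "+", site + lo_off - 5, site + hi_off)
    else:
        seq = fetch_oriented(genome, contig, "-", site - hi_off, site - lo_off + 5)
    best = None  # (distance, |offset+19|, -offset, hexamer, offset)
    if len(seq) == span:
        for i in range(hi_off - lo_off + 1):
            hexamer = seq[i:i + 6]
            off = lo_off + i
            d = hamming(hexamer, CANONICAL_PAS)
            key = (d, abs(off - CANONICAL_OFFSET), -off)
            if best is None or key < best[:3]:
                best = (*key, hexamer, off)
    if best is None or best[0] > max_distance:
        return PasCall(isoform.gene_id, isoform.tissue, site, None, "none", None)
    d, _, _, hexamer, off = best
    klass = PAS_CLASSES[min(d, 2)]
    return PasCall(isoform.gene_id, isoform.tissue, site, hexamer, klass, off)


def classify_catalog(isoforms, annotation, genome: dict, **kwargs):
    """PasCalls for a whole isoform catalog."""
    calls = []
    for iso in isoforms:
        gene = annotation[iso.gene_id]
        calls.append(classify_pas(iso, genome, gene.contig, gene.strand, **kwargs))
    return calls


def pas_class_frequencies(calls) -> dict:
    """Exact proportions of the four PAS classes; empty input -> None."""
    if not calls:
        return None
    counts = Counter(c.pas_class for c in calls)
    n = len(calls)
    return {k: counts.get(k, 0) / n for k in PAS_CLASSES}


def cleavage_context_profile(isoforms, annotation, genome: dict):
    """4 x 70 nucleotide-frequency matrix over positions -50..+20.

    The 70-nt window is the 50 sense-strand bases ending at the cleavage site
    plus the 20 bases downstream. Isoforms whose window is truncated by a
    contig edge are excluded and counted. Returns (matrix rows A/C/G/T,
    included count, excluded count); columns sum to 1 when any isoform is
    included.
    """
    width = PROFILE_UP + PROFILE_DOWN
    counts = np.zeros((4, width), dtype=float)
    included = excluded = 0
    for iso in isoforms:
        gene = annotation[iso.gene_id]
        site = iso.cleavage_site
        if gene.strand == "+":
            seq = fetch_oriented(genome, gene.contig, "+",
                                 site - PROFILE_UP + 1, site + PROFILE_DOWN)
        else:
            seq = fetch_oriented(genome, gene.contig, "-",
                                 site - PROFILE_DOWN, site + PROFILE_UP - 1)
        if len(seq) != width:
            excluded += 1
            continue
        for j, base in enumerate(seq):
            if base in _ROW:
                counts[_ROW[base], j] += 1
        included += 1
    if included:
        counts /= counts.sum(axis=0, keepdims=True)
    return counts, included, excluded
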