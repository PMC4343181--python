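"""PolyA-read extraction, cleavage-site mapping, internal-priming filtering,
clustering, gene assignment and cluster-level filters.

All thresholds follow the strict boundaries of the published filtering rules:
a read is a polyA read iff its terminal A-run is >= 30 nt; a cleavage event
fails the internal-priming filter iff either flanking 30-nt window is >= 65%
A in transcript orientation or the alignment's longest exact-match run is
< 18 nt; per-gene clusters with < 5% usage or a > 40%-A genomic footprint are
discarded and the survivors renormalized.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .io_formats import GeneModel, ReadAlignment
from .sequtil import a_fraction, fetch_oriented, revcomp, terminal_a_run

SEED_LENGTH = 18


@dataclass(frozen=True)
class TrimmedPolyARead:
    read_id: str
    trimmed_sequence: str
    tail_length: int


@dataclass(frozen=True)
class CleavageEvent:
    """The genomic coordinate of a read's last transcribed base (1-based)."""
    read_id: str
    contig: str
    strand: str
    cleavage_position: int
    alignment: ReadAlignment


@dataclass
class PASCluster:
    cluster_id: str
    contig: str
    strand: str
    member_positions: tuple
    representative_site: int
    span_start: int
    span_end: int
    read_count: int
    assigned_gene: str | None = None
    distance_to_gene: int | None = None
    a_fraction_of_footprint: float | None = None
    usage_fraction: float | None = None
    status: str = "retained"
    filter_reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.status == "retained"


# ---------------------------------------------------------------------------
# tail extraction
# ---------------------------------------------------------------------------

def extract_polya_reads(reads, min_tail: int = 30, min_length: int = SEED_LENGTH):
    """Select reads whose maximal terminal A-run is >= min_tail and trim it.

    `reads` yields (read_id, sequence). Returns (trimmed reads, accounting
    Counter over {retained, no_tail, trimmed_too_short, invalid_characters}).
    """
    if min_tail < 1:
        raise ValueError("min_tail must be >= 1")
    out = []
    accounting = Counter()
    for rid, seq in reads:
        if any(c not in "ACGTN" for c in seq):
            accounting["invalid_characters"] += 1
            continue
        run = terminal_a_run(seq)
        if run < min_tail:
            accounting["no_tail"] += 1
            continue
        trimmed = seq[:len(seq) - run]
        if len(trimmed) < min_length:
            accounting["trimmed_too_short"] += 1
            continue
        out.append(TrimmedPolyARead(rid, trimmed, run))
        accounting["retained"] += 1
    return out, accounting


# ---------------------------------------------------------------------------
# built-in aligner: exact seed, full-length extension with <= 1 mismatch
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer index of the forward genome for seed-and-extend lookup.

    Minus-strand hits are found by searching the reverse complement of the
    query, so only the forward strand is indexed.
    """

    def __init__(self, genome: dict, seed_length: int = SEED_LENGTH):
        self.genome = genome
        self.seed_length = seed_length
        self.seeds: dict[str, list] = defaultdict(list)
        k = seed_length
        for contig, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self.seeds[seq[i:i + k]].append((contig, i))
        self.seeds = dict(self.seeds)

    def candidate_positions(self, query: str):
        """Candidate (contig, leftmost0) loci from exact seed hits.

        Two disjoint seeds are probed so a single substitution anywhere in the
        query still leaves one exact seed.
        """
        k = self.seed_length
        L = len(query)
        offsets = [0]
        if L >= 2 * k:
            offsets.append(k)
        elif L > k:
            offsets.append(L - k)
        cands = set()
        for off in offsets:
            for contig, pos in self.seeds.get(query[off:off + k], ()):
                start = pos - off
                if 0 <= start <= len(self.genome[contig]) - L:
                    cands.add((contig, start))
        return cands


def _count_mismatches(query: str, ref: str, limit: int):
    """(n_mismatches, index of the single mismatch) or None when > limit."""
    if query == ref:
        return 0, None
    n = 0
    where = None
    for i, (a, b) in enumerate(zip(query, ref)):
        if a != b:
            n += 1
            if n > limit:
                return None
            where = i
    return n, where


def align_trimmed_read(read: TrimmedPolyARead, index: GenomeIndex,
                       max_mismatches: int = 1):
    """Best unique locus of a trimmed read, or None.

    Returns (ReadAlignment, reason) where reason is None on success, else
    'unaligned' or 'multi_mapped'. A read with >= 2 equally good loci is
    discarded as multi-mapped.
    """
    q = read.trimmed_sequence
    L = len(q)
    if L < index.seed_length:
        return None, "unaligned"
    best = None  # (n_mm, contig, start, strand, mm_index)
    n_best = 0
    for strand, query in (("+", q), ("-", revcomp(q))):
        for contig, start in index.candidate_positions(query):
            ref = index.genome[contig][start:start + L]
            res = _count_mismatches(query, ref, max_mismatches)
            if res is None:
                continue
            n_mm, where = res
            if best is None or n_mm < best[0]:
                best = (n_mm, contig, start, strand, where)
                n_best = 1
            elif n_mm == best[0]:
                if (contig, start, strand) != best[1:4]:
                    n_best += 1
    if best is None:
        return None, "unaligned"
    if n_best > 1:
        return None, "multi_mapped"
    n_mm, contig, start, strand, where = best
    if n_mm == 0:
        lcm = L
    else:
        # mismatch index is in query orientation; for '-' the genomic query was
        # the reverse complement, but run lengths are orientation-free
        lcm = max(where, L - 1 - where)
    return ReadAlignment(
        read_id=read.read_id, contig=contig, strand=strand,
        leftmost_position=start, aligned_span=L,
        longest_consecutive_match=lcm, tail_length=read.tail_length,
    ), None


def align_reads(reads, index: GenomeIndex, max_mismatches: int = 1):
    """Align many trimmed reads; returns (alignments, accounting Counter)."""
    alignments = []
    accounting = Counter()
    for read in reads:
        aln, reason = align_trimmed_read(read, index, max_mismatches)
        if aln is None:
            accounting[reason] += 1
        else:
            alignments.append(aln)
            accounting["aligned"] += 1
    return alignments, accounting


# ---------------------------------------------------------------------------
# cleavage sites and the internal-priming filter
# ---------------------------------------------------------------------------

def compute_cleavage_site(alignment: ReadAlignment) -> CleavageEvent:
    """Genomic 1-based coordinate of the transcript's last templated base."""
    if alignment.strand == "+":
        pos = alignment.leftmost_position + alignment.aligned_span  # 1-based right end
    else:
        pos = alignment.leftmost_position + 1  # 1-based left end = transcript 3'
    return CleavageEvent(alignment.read_id, alignment.contig, alignment.strand,
                         pos, alignment)


def filter_internal_priming(event: CleavageEvent, genome: dict,
                            a_threshold: float = 0.65, window: int = 30,
                            min_consecutive: int = 18):
    """(True, None) if the event survives, else (False, reason).

    Fails when the transcript-orientation A fraction in the `window` nt
    immediately downstream of the cleavage site, or in the `window` nt ending
    at the site, reaches `a_threshold`; or when the alignment's longest
    exact-match run is below `min_consecutive`. Windows truncated at contig
    edges use the available bases as denominator.
    """
    pos = event.cleavage_position
    if event.strand == "+":
        down = fetch_oriented(genome, event.contig, "+", pos + 1, pos + window)
        up = fetch_oriented(genome, event.contig, "+", pos - window + 1, pos)
    else:
        down = fetch_oriented(genome, event.contig, "-", pos - window, pos - 1)
        up = fetch_oriented(genome, event.contig, "-", pos, pos + window - 1)
    if down and a_fraction(down) >= a_threshold:
        return False, "a_rich_downstream"
    if up and a_fraction(up) >= a_threshold:
        return False, "a_rich_upstream"
    if event.alignment.longest_consecutive_match < min_consecutive:
        return False, "short_match"
    return True, None


def apply_priming_filter(events, genome, **kwargs):
    """Partition events into (passed, accounting by failure reason)."""
    passed = []
    accounting = Counter()
    for ev in events:
        ok, reason = filter_internal_priming(ev, genome, **kwargs)
        if ok:
            passed.append(ev)
            accounting["passed"] += 1
        else:
            accounting[f"filtered_{reason}"] += 1
    return passed, accounting


# ---------------------------------------------------------------------------
# clustering, gene assignment, cluster-level filters
# ---------------------------------------------------------------------------

def cluster_cleavage_sites(events, max_gap: int = 25):
    """Single-linkage clustering of cleavage positions per (contig, strand).

    Consecutive sorted positions join one cluster iff their gap is <= max_gap.
    The representative site is the modal member position, ties broken toward
    the 3'-most position in transcript orientation.
    """
    by_group = defaultdict(list)
    for ev in events:
        by_group[(ev.contig, ev.strand)].append(ev.cleavage_position)
    clusters = []
    for (contig, strand), positions in sorted(by_group.items()):
        positions.sort()
        start = 0
        for i in range(1, len(positions) + 1):
            if i == len(positions) or positions[i] - positions[i - 1] > max_gap:
                members = tuple(positions[start:i])
                counts = Counter(members)
                top = max(counts.values())
                modes = [p for p, c in counts.items() if c == top]
                rep = max(modes) if strand == "+" else min(modes)
                clusters.append(PASCluster(
                    cluster_id="", contig=contig, strand=strand,
                    member_positions=members, representative_site=rep,
                    span_start=members[0], span_end=members[-1],
                    read_count=len(members),
                ))
                start = i
    clusters.sort(key=lambda c: (c.contig, c.span_start, c.strand))
    for n, c in enumerate(clusters, start=1):
        c.cluster_id = f"cl{n:06d}"
    return clusters


def _distance_to_gene(cluster: PASCluster, gene: GeneModel):
    """Transcript-orientation distance of the representative site to the
    gene's [stop_codon_end, annotated 3' end] interval; None if the gene has
    no stop codon. Negative direction (upstream of stop) is returned as a
    positive gap, with a flag marking downstream-of-gene placement."""
    site = cluster.representative_site
    stop = gene.stop_codon_end
    if stop is None:
        return None
    if gene.strand == "+":
        lo, hi = stop, gene.gene_end
        if lo <= site <= hi:
            return 0, True
        if site > hi:
            return site - hi, True
        return lo - site, False
    lo, hi = gene.gene_start, stop
    if lo <= site <= hi:
        return 0, True
    if site < lo:
        return lo - site, True
    return site - hi, False


def assign_clusters_to_genes(clusters, annotation, max_distance: int = 1600):
    """Attach each cluster to the closest same-strand gene within range.

    Distance is 0 inside [stop_codon_end, gene 3' end] and the gap to that
    interval otherwise; candidates farther than max_distance stay unassigned.
    Exact ties go to the gene whose 3' terminus lies nearest upstream of the
    site (the gene the cluster is downstream of).
    """
    by_group = defaultdict(list)
    for g in (annotation.values() if isinstance(annotation, dict) else annotation):
        by_group[(g.contig, g.strand)].append(g)
    for c in clusters:
        best = None  # (distance, not_downstream, gene)
        for g in by_group.get((c.contig, c.strand), ()):
            res = _distance_to_gene(c, g)
            if res is None:
                continue
            dist, downstream = res
            if dist > max_distance:
                continue
            key = (dist, not downstream)
            if best is None or key < best[0]:
                best = (key, g)
        if best is not None:
            c.assigned_gene = best[1].gene_id
            c.distance_to_gene = best[0][0]
        else:
            c.assigned_gene = None
            c.distance_to_gene = None
    return clusters


def filter_clusters(clusters, genome: dict, min_usage: float = 0.05,
                    a_footprint_threshold: float = 0.40):
    """Finalize cluster status per gene.

    Per gene: first discard clusters whose genomic footprint (sense strand,
    span inclusive) is > a_footprint_threshold A; then compute each survivor's
    usage fraction over the survivors' total reads and discard those below
    min_usage; finally renormalize retained usage fractions to sum to 1.
    Unassigned clusters are marked filtered(unassigned).
    """
    by_gene = defaultdict(list)
    for c in clusters:
        footprint = fetch_oriented(genome, c.contig, c.strand, c.span_start, c.span_end)
        c.a_fraction_of_footprint = a_fraction(footprint)
        if c.assigned_gene is None:
            c.status, c.filter_reason = "filtered", "unassigned"
            continue
        by_gene[c.assigned_gene].append(c)
    for gene_clusters in by_gene.values():
        survivors = []
        for c in gene_clusters:
            if c.a_fraction_of_footprint > a_footprint_threshold:
                c.status, c.filter_reason = "filtered", "a_rich_footprint"
            else:
                survivors.append(c)
        total = sum(c.read_count for c in survivors)
        if total == 0:
            continue
        kept = []
        for c in survivors:
            c.usage_fraction = c.read_count / total
            if c.usage_fraction < min_usage:
                c.status, c.filter_reason = "filtered", "low_usage"
            else:
                kept.append(c)
        norm = sum(c.usage_fraction for c in kept)
        for c in kept:
            c.usage_fraction = c.usage_fraction / norm
            c.status, c.filter_reason = "retained", None
    return clusters


# ---------------------------------------------------------------------------
# end-to-end mapping for one read set
# ---------------------------------------------------------------------------

@dataclass
class PolyAMapResult:
    clusters: list
    events: list            # cleavage events that passed the priming filter
    accounting: Counter     # every input read lands in exactly one class
    event_filter: dict      # read_id -> filter outcome ('passed' or reason)
    alignments: list = None  # all mapped trimmed-read alignments, pre-filter


def map_polya_reads(reads, genome, annotation, index: GenomeIndex | None = None,
                    min_tail: int = 30, a_threshold: float = 0.65,
                    window: int = 30, min_consecutive: int = 18,
                    max_gap: int = 25, max_distance: int = 1600,
                    min_usage: float = 0.05, a_footprint_threshold: float = 0.40):
    """Run the full polyA-site mapping chain on one tissue's reads.

    `reads` yields (read_id, sequence). Conservation invariant: the
    accounting counter sums to the number of input reads.
    """
    reads = list(reads)
    if index is None:
        index = GenomeIndex(genome)
    trimmed, acc = extract_polya_reads(reads, min_tail=min_tail,
                                       min_length=index.seed_length)
    alignments, align_acc = align_reads(trimmed, index)
    events = [compute_cleavage_site(a) for a in alignments]
    event_filter = {}
    passed = []
    filt_acc = Counter()
    for ev in events:
        ok, reason = filter_internal_priming(
            ev, genome, a_threshold=a_threshold, window=window,
            min_consecutive=min_consecutive)
        if ok:
            passed.append(ev)
            event_filter[ev.read_id] = "passed"
        else:
            event_filter[ev.read_id] = reason
            filt_acc[f"filtered_{reason}"] += 1
    clusters = cluster_cleavage_sites(passed, max_gap=max_gap)
    assign_clusters_to_genes(clusters, annotation, max_distance=max_distance)
    filter_clusters(clusters, genome, min_usage=min_usage,
                    a_footprint_threshold=a_footprint_threshold)
    accounting = Counter()
    accounting["no_tail"] = acc["no_tail"]
    accounting["trimmed_too_short"] = acc["trimmed_too_short"]
    accounting["invalid_characters"] = acc["invalid_characters"]
    accounting["unaligned"] = align_acc["unaligned"]
    accounting["multi_mapped"] = align_acc["multi_mapped"]
    accounting.update(filt_acc)
    accounting["clustered"] = len(passed)
    accounting += Counter()  # drop zero entries
    return PolyAMapResult(clusters=clusters, events=passed,
                          accounting=accounting, event_filter=event_filter,
                          alignments=alignments)
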