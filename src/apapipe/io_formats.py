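"""Readers and writers for the standard formats the pipeline touches.

This module owns the coordinate-convention boundary: everything internal is
1-based inclusive with explicit strand (the GFF3 convention); conversion to
0-based half-open happens only when writing BED.

FASTA/FASTQ go through Biopython, SAM through pysam. GFF3 is read with a
small columnar reader so parse errors can carry line numbers and exon/gene
consistency can be validated as records stream in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HEADER_COMMENT = "# apapipe v0.1.0"


class AnnotationError(ValueError):
    """Malformed or inconsistent gene annotation."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure and 3'UTR anchor.

    ``stop_codon_end`` is the genomic coordinate of the last CDS base in
    transcript orientation (the highest CDS coordinate on '+', the lowest on
    '-'); it anchors all 3'UTR length arithmetic. Genes without a stop_codon
    record carry ``None`` and are unusable for 3'UTR analyses.
    """

    gene_id: str
    contig: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple = ()
    stop_codon_end: int | None = None
    in_operon: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if self.gene_end < self.gene_start:
            raise AnnotationError(f"{self.gene_id}: gene_end < gene_start")
        prev_end = 0
        for s, e in self.exons:
            if e < s:
                raise AnnotationError(f"{self.gene_id}: exon end {e} < start {s}")
            if s <= prev_end:
                raise AnnotationError(f"{self.gene_id}: exons overlap or unsorted")
            if s < self.gene_start or e > self.gene_end:
                raise AnnotationError(f"{self.gene_id}: exon outside gene span")
            prev_end = e
        if self.stop_codon_end is not None and not (
            self.gene_start <= self.stop_codon_end <= self.gene_end
        ):
            raise AnnotationError(f"{self.gene_id}: stop_codon_end outside gene span")

    @property
    def tss(self) -> int:
        """Transcription start: gene_start on '+', gene_end on '-'."""
        return self.gene_start if self.strand == "+" else self.gene_end

    @property
    def three_prime_end(self) -> int:
        """Annotated 3' terminus in transcript orientation."""
        return self.gene_end if self.strand == "+" else self.gene_start

    @property
    def union_exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.union_exons())

    def union_exons(self) -> tuple:
        """Exons merged into disjoint intervals (already disjoint by invariant)."""
        return self.exons if self.exons else ((self.gene_start, self.gene_end),)


@dataclass(frozen=True)
class ReadAlignment:
    """A primary alignment of one (possibly tail-trimmed) read.

    ``leftmost_position`` is 0-based (the SAM in-memory convention);
    ``longest_consecutive_match`` is the longest run of exactly matching bases,
    the quantity the internal-priming filter thresholds at 18 nt.
    """

    read_id: str
    contig: str
    strand: str
    leftmost_position: int
    aligned_span: int
    longest_consecutive_match: int
    tail_length: int = 0

    def __post_init__(self):
        if self.longest_consecutive_match > self.aligned_span:
            raise ValueError("longest_consecutive_match exceeds aligned_span")


_ATTR_RE = re.compile(r"\s*([^=;]+)=([^;]*)")


def _parse_attrs(text: str) -> dict:
    return {m.group(1).strip(): m.group(2) for m in _ATTR_RE.finditer(text)}


def parse_annotation(source) -> dict:
    """Parse GFF3 gene/exon/stop_codon records into {gene_id: GeneModel}.

    `source` is a path or an iterable of lines. Coordinates stay 1-based
    inclusive. Malformed lines raise AnnotationError with the line number.
    """
    close = False
    if isinstance(source, (str, bytes)):
        stream = open(source)
        close = True
    else:
        stream = source
    genes: dict[str, dict] = {}
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"line {lineno}: expected 9 tab-separated fields")
            contig, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if ftype not in ("gene", "exon", "stop_codon"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(f"line {lineno}: non-integer coordinates") from None
            if end < start:
                raise AnnotationError(f"line {lineno}: end < start")
            attrs = _parse_attrs(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise AnnotationError(f"line {lineno}: gene record lacks ID")
                genes[gid] = {
                    "contig": contig, "strand": strand, "start": start, "end": end,
                    "exons": [], "stop": None,
                    "in_operon": attrs.get("operon", "").lower() in ("1", "true", "yes"),
                }
            else:
                gid = attrs.get("Parent") or attrs.get("ID")
                if not gid:
                    raise AnnotationError(f"line {lineno}: {ftype} lacks Parent")
                if gid not in genes:
                    raise AnnotationError(f"line {lineno}: {ftype} references unknown gene {gid!r}")
                rec = genes[gid]
                if ftype == "exon":
                    rec["exons"].append((start, end))
                else:
                    rec["stop"] = end if rec["strand"] == "+" else start
    finally:
        if close:
            stream.close()
    out = {}
    for gid, rec in genes.items():
        out[gid] = GeneModel(
            gene_id=gid, contig=rec["contig"], strand=rec["strand"],
            gene_start=rec["start"], gene_end=rec["end"],
            exons=tuple(sorted(rec["exons"])), stop_codon_end=rec["stop"],
            in_operon=rec["in_operon"],
        )
    return out


def write_annotation(genes, path) -> None:
    """Write GeneModels as GFF3 (gene/exon/stop_codon; 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes.values() if isinstance(genes, dict) else genes,
                        key=lambda g: (g.contig, g.gene_start)):
            attrs = f"ID={g.gene_id}"
            if g.in_operon:
                attrs += ";operon=true"
            fh.write(f"{g.contig}\tapapipe\tgene\t{g.gene_start}\t{g.gene_end}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.contig}\tapapipe\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n")
            if g.stop_codon_end is not None:
                # stop_codon_end is the last CDS base in transcript orientation;
                # emit the 3-nt stop codon interval it terminates.
                if g.strand == "+":
                    s, e = g.stop_codon_end - 2, g.stop_codon_end
                else:
                    s, e = g.stop_codon_end, g.stop_codon_end + 2
                fh.write(f"{g.contig}\tapapipe\tstop_codon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n")


def _md_match_runs(cigartuples, md: str):
    """Yield lengths of exact-match runs implied by CIGAR + MD."""
    tokens = re.findall(r"(\d+)|(\^[ACGTN]+)|([ACGTN])", md)
    ti = 0
    run = 0
    pending = 0  # residue of a numeric MD token spanning cigar ops

    def next_token():
        nonlocal ti
        tok = tokens[ti]
        ti += 1
        return tok

    for op, length in cigartuples:
        if op in (0, 7, 8):  # M, =, X : consume `length` reference bases from MD
            need = length
            while need > 0:
                if pending:
                    take = min(pending, need)
                    run += take
                    pending -= take
                    need -= take
                    continue
                num, dele, mism = next_token()
                if num:
                    pending = int(num)
                elif mism:
                    yield run
                    run = 0
                    need -= 1
                else:  # deletion token inside an M stretch: malformed, but break run
                    yield run
                    run = 0
        elif op == 1:  # insertion: untemplated bases interrupt the exact run
            yield run
            run = 0
        elif op == 2:  # deletion
            if pending == 0 and ti < len(tokens) and tokens[ti][1]:
                next_token()
            yield run
            run = 0
        # S/H/N/P consume no MD
    yield run


def longest_consecutive_match(cigartuples, md: str) -> int:
    return max(_md_match_runs(cigartuples, md))


def parse_alignments(sam_path, tail_registry: dict | None = None) -> list:
    """Read a SAM file into ReadAlignments (external-aligner entry point).

    Unmapped, secondary and supplementary records are dropped. The longest
    exact-match run is derived from CIGAR + MD; a mapped record without MD is
    an error naming the read. Tail lengths trimmed before alignment are
    reattached from `tail_registry` (read_id -> tail nt).
    """
    tail_registry = tail_registry or {}
    out = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.has_tag("MD"):
                raise ValueError(f"record {rec.query_name}: MD tag required to derive match runs")
            lcm = longest_consecutive_match(rec.cigartuples, rec.get_tag("MD"))
            out.append(ReadAlignment(
                read_id=rec.query_name,
                contig=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                leftmost_position=rec.reference_start,
                aligned_span=rec.reference_end - rec.reference_start,
                longest_consecutive_match=lcm,
                tail_length=tail_registry.get(rec.query_name, 0),
            ))
    return out


def write_clusters_bed(clusters, path) -> None:
    """Write cluster representative sites as BED6 (0-based half-open).

    name = gene_id|cluster_id (gene '.' when unassigned), score = read count.
    """
    rows = []
    for c in clusters:
        start0 = c.representative_site - 1
        gene = c.assigned_gene or "."
        rows.append((c.contig, start0, start0 + 1, f"{gene}|{c.cluster_id}", c.read_count, c.strand))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict, path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path):
    """Yield (read_id, sequence) pairs."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(reads, path) -> None:
    """Write (read_id, sequence) pairs with uniform Phred 40 qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
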