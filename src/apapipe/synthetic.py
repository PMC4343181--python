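"""Synthetic genome / annotation / read-set generator with full ground truth.

The generator builds a toy genome carrying every signal the downstream
analyses look for, so each stage of the pipeline can be verified against a
known answer:

* non-overlapping genes (two exons, a stop codon, 1-3 cleavage sites in the
  3'UTR), each cleavage site preceded by a polyadenylation-signal hexamer
  whose last base sits 19 nt upstream of the site;
* per-tissue expression (log-normal abundances, tissue-membership patterns)
  and per-tissue isoform-usage mixtures, including genes whose dominant
  isoform switches between tissues;
* polyA+ reads whose untemplated A tails are >= 30 nt, plus tail-less body
  reads for expression estimation;
* internal-priming traps: genomically templated A-runs planted inside
  transcripts and intergenically, with artifact reads ending at them;
* a promoter hexamer planted into one 100-nt promoter bin of a chosen
  fraction of genes;
* gene-level miRNA-target labels enriched among isoform-switching genes.

Fixed seed => byte-identical FASTA/GFF3/FASTQ/TSV outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GeneModel, write_annotation, write_fasta, write_fastq
from .sequtil import revcomp

CANONICAL_PAS = "AATAAA"  # DNA sense of AAUAAA

# gene-body geometry (transcript offsets from the TSS, 0-based)
_EXON1_LEN = 600
_INTRON_LEN = 100
_CDS2_LEN = 400  # CDS portion of exon 2; stop codon ends at offset 1099
_STOP_OFFSET = _EXON1_LEN + _INTRON_LEN + _CDS2_LEN - 1
_SLOT = 4500
_SLOT_MARGIN = 1200

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic run.

    Defaults give 2 x 200 kb contigs, 60 genes, 3 tissues and 20,000 reads
    per tissue — an end-to-end run of a few minutes on one CPU.
    """

    seed: int = 1
    n_contigs: int = 2
    contig_length: int = 200_000
    n_genes: int = 60
    pas_site_probs: tuple = (0.35, 0.45, 0.20)  # P(1), P(2), P(3) sites per gene
    tissue_names: tuple = ("intestine", "pharynx", "body_muscle")
    expression_log10_mean: float = 1.0
    expression_log10_sigma: float = 0.4
    tissue_all_fraction: float = 0.5   # genes expressed in every tissue
    switch_gene_fraction: float = 0.5  # of multi-site genes: tissue-switching usage
    dominant_usage: float = 0.7        # mixture weight of the dominant site
    tail_length_range: tuple = (30, 60)
    read_length: int = 100
    n_reads_per_tissue: int = 20_000
    polya_read_fraction: float = 0.35  # of non-artifact reads that carry a tail
    error_rate: float = 0.001          # per-base substitution rate outside tails
    tail_error_rate: float = 0.0       # optional robustness knob; tails clean by default
    n_priming_traps: int = 8
    trap_run_length: int = 35
    artifact_reads_per_trap: int = 15
    planted_promoter_motif: str = "TGATAA"
    promoter_motif_bin: int = 5        # 100-nt bin of the -500..+100 window, 1-based
    promoter_motif_fraction: float = 0.4
    pas_canonical_fraction: float = 0.8
    mirna_prediction_sets: tuple = ("three_species", "five_species", "footprint")
    mirna_target_rate_switch: float = 0.5
    mirna_target_rate_background: float = 0.2

    def validate(self) -> None:
        if self.tail_length_range[0] < 30:
            raise ValueError("tail_length_range minimum must be >= 30")
        if not math.isclose(sum(self.pas_site_probs), 1.0, abs_tol=1e-9):
            raise ValueError("pas_site_probs must sum to 1")
        if len(self.tissue_names) < 2:
            raise ValueError("need at least two tissues")
        if not 1 <= self.promoter_motif_bin <= 6:
            raise ValueError("promoter_motif_bin must be in 1..6")
        if len(self.planted_promoter_motif) != 6:
            raise ValueError("planted promoter motif must be a hexamer")


_SITES_SCHEMA = {
    "gene_id": str, "tissue": str, "contig": str, "strand": str,
    "site_index": np.int64, "cleavage_site": np.int64,
    "usage": float, "abundance": float, "expressed": bool, "pas_class": str,
}
_TRAPS_SCHEMA = {
    "trap_id": str, "contig": str, "strand": str,
    "start": np.int64, "end": np.int64, "location": str, "gene_id": str,
}
_TARGETS_SCHEMA = {"gene_id": str, "prediction_set": str, "targeted": bool}
_GENES_SCHEMA = {"gene_id": str, "carries_promoter_motif": bool, "is_switch_gene": bool}


@dataclass(eq=False)
class Truth:
    """Ground-truth tables: one sites row per (gene, tissue, cleavage site)."""

    sites: pd.DataFrame
    traps: pd.DataFrame
    targets: pd.DataFrame
    gene_flags: pd.DataFrame

    def equals(self, other: "Truth") -> bool:
        return all(
            getattr(self, f.name).reset_index(drop=True).equals(
                getattr(other, f.name).reset_index(drop=True))
            for f in fields(self)
        )

    # -- convenience views -------------------------------------------------
    def expressed_genes(self, tissue: str) -> set:
        df = self.sites
        return set(df.loc[(df.tissue == tissue) & df.expressed, "gene_id"])

    def usage_map(self, gene: str, tissue: str) -> dict:
        df = self.sites
        sel = df[(df.gene_id == gene) & (df.tissue == tissue)]
        return dict(zip(sel.cleavage_site, sel.usage))

    def dominant_site(self, gene: str, tissue: str) -> int:
        usage = self.usage_map(gene, tissue)
        return max(usage, key=usage.get)

    def recoverable_sites(self) -> pd.DataFrame:
        """Distinct (gene, site) rows carrying reads in at least one tissue."""
        df = self.sites
        live = df[df.expressed & (df.usage > 0)]
        return live.drop_duplicates(["gene_id", "cleavage_site"])[
            ["gene_id", "contig", "strand", "site_index", "cleavage_site", "pas_class"]
        ]

    def switch_genes(self) -> set:
        gf = self.gene_flags
        return set(gf.loc[gf.is_switch_gene, "gene_id"])

    def motif_carriers(self) -> set:
        gf = self.gene_flags
        return set(gf.loc[gf.carries_promoter_motif, "gene_id"])

    def target_flags(self, prediction_set: str) -> dict:
        df = self.targets[self.targets.prediction_set == prediction_set]
        return dict(zip(df.gene_id, df.targeted))


def _one_permutation(rng, hexamer: str) -> str:
    pos = int(rng.integers(0, 6))
    alt = [b for b in "ACGT" if b != hexamer[pos]]
    return hexamer[:pos] + alt[int(rng.integers(0, 3))] + hexamer[pos + 1:]


class _ContigEditor:
    """Mutable contig with transcript-oriented planting helpers."""

    def __init__(self, seq_array):
        self.arr = seq_array  # numpy array of single characters

    def plant(self, strand: str, anchor: int, offset_from_anchor: int, sense_seq: str):
        """Write `sense_seq` so its FIRST base sits at transcript position
        anchor+offset (anchor and result in 1-based genomic coordinates)."""
        if strand == "+":
            start = anchor + offset_from_anchor  # 1-based
            self.arr[start - 1:start - 1 + len(sense_seq)] = list(sense_seq)
        else:
            start = anchor - offset_from_anchor  # genomic coord of first sense base
            rc = revcomp(sense_seq)
            self.arr[start - len(sense_seq):start] = list(rc)


def generate_genome_and_annotation(config: SimulationConfig):
    """Build (genome, annotation, truth) for the configured study conditions.

    Raises ValueError when the requested gene count does not fit the contigs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    per_contig = (config.contig_length - 2 * _SLOT_MARGIN) // _SLOT
    if config.n_genes > per_contig * config.n_contigs:
        raise ValueError(
            f"{config.n_genes} genes do not fit {config.n_contigs} contigs "
            f"of {config.contig_length} nt ({per_contig} slots per contig)")

    contigs = {}
    editors = {}
    for i in range(config.n_contigs):
        name = f"chr{i + 1}"
        arr = rng.choice(_BASES, size=config.contig_length)
        contigs[name] = name
        editors[name] = _ContigEditor(arr)

    tissues = list(config.tissue_names)
    n_t = len(tissues)
    genes: dict[str, GeneModel] = {}
    site_rows = []
    gene_meta = {}  # gene_id -> dict for flags

    # tissue-membership patterns: all tissues or a random non-empty proper subset
    proper_subsets = []
    for mask in range(1, 2 ** n_t - 1):
        proper_subsets.append([t for j, t in enumerate(tissues) if mask >> j & 1])

    site_counts = rng.choice([1, 2, 3], size=config.n_genes, p=config.pas_site_probs)
    strands = rng.choice(["+", "-"], size=config.n_genes)

    slot_of = []  # (contig, slot_index) per gene
    for g in range(config.n_genes):
        c = g // per_contig
        slot_of.append((f"chr{c + 1}", g % per_contig))

    for g in range(config.n_genes):
        gid = f"gene{g + 1:03d}"
        contig, slot = slot_of[g]
        ed = editors[contig]
        strand = str(strands[g])
        slot_start = _SLOT_MARGIN + slot * _SLOT  # 0-based slot origin

        k = int(site_counts[g])
        utr_lens = [int(rng.integers(80, 151))]
        for _ in range(k - 1):
            utr_lens.append(utr_lens[-1] + int(rng.integers(120, 251)))
        site_offsets = [_STOP_OFFSET + u for u in utr_lens]
        gene_len = site_offsets[-1] + 1  # transcript offsets 0..distal site

        if strand == "+":
            tss = slot_start + 701  # 1-based
            gene_lo, gene_hi = tss, tss + gene_len - 1
        else:
            tss = slot_start + _SLOT - 700
            gene_lo, gene_hi = tss - gene_len + 1, tss

        anchor = tss  # transcript offset 0

        # plant one PAS hexamer per site, ending 19 nt upstream of the site,
        # and pin the cleavage base to a non-A so tail trimming stops exactly
        pas_classes = []
        for off in site_offsets:
            if rng.random() < config.pas_canonical_fraction:
                hexamer, klass = CANONICAL_PAS, "canonical"
            else:
                hexamer, klass = _one_permutation(rng, CANONICAL_PAS), "one_permutation"
            ed.plant(strand, anchor, off - 24, hexamer)  # last base at off-19
            ed.plant(strand, anchor, off, "T")
            pas_classes.append(klass)

        if strand == "+":
            exons = ((gene_lo, gene_lo + _EXON1_LEN - 1),
                     (gene_lo + _EXON1_LEN + _INTRON_LEN, gene_hi))
            stop_end = gene_lo + _STOP_OFFSET
            sites_genomic = [gene_lo + off for off in site_offsets]
        else:
            exons = ((gene_lo, gene_hi - _EXON1_LEN - _INTRON_LEN),
                     (gene_hi - _EXON1_LEN + 1, gene_hi))
            stop_end = gene_hi - _STOP_OFFSET
            sites_genomic = [gene_hi - off for off in site_offsets]

        genes[gid] = GeneModel(
            gene_id=gid, contig=contig, strand=strand,
            gene_start=gene_lo, gene_end=gene_hi,
            exons=exons, stop_codon_end=stop_end,
        )

        # expression pattern and abundances
        if rng.random() < config.tissue_all_fraction:
            members = tissues
        else:
            members = proper_subsets[int(rng.integers(0, len(proper_subsets)))]
        abund = {t: (10.0 ** rng.normal(config.expression_log10_mean,
                                        config.expression_log10_sigma)
                     if t in members else 0.0)
                 for t in tissues}

        # per-tissue usage mixtures; switch genes change their dominant site
        is_switch = False
        if k == 1:
            dominants = {t: 0 for t in tissues}
        else:
            is_switch = bool(rng.random() < config.switch_gene_fraction)
            if is_switch:
                while True:
                    dom = [int(d) for d in rng.integers(0, k, size=n_t)]
                    if len(set(dom)) > 1:
                        break
                dominants = dict(zip(tissues, dom))
            else:
                d = int(rng.integers(0, k))
                dominants = {t: d for t in tissues}

        minor = (1.0 - config.dominant_usage) / (k - 1) if k > 1 else 0.0
        for t in tissues:
            for j, (site, klass) in enumerate(zip(sites_genomic, pas_classes)):
                usage = config.dominant_usage if j == dominants[t] else minor
                if k == 1:
                    usage = 1.0
                site_rows.append((gid, t, contig, strand, j, site, usage,
                                  abund[t], t in members, klass))
        gene_meta[gid] = {"is_switch_gene": is_switch, "sites": sites_genomic,
                          "tss": tss, "strand": strand, "contig": contig}

    # promoter motif: exact planting into round(fraction * n_genes) genes
    n_carriers = int(round(config.promoter_motif_fraction * config.n_genes))
    gene_ids = sorted(genes)
    carriers = set(rng.choice(gene_ids, size=n_carriers, replace=False)) if n_carriers else set()
    b = config.promoter_motif_bin
    for gid in gene_ids:
        if gid not in carriers:
            continue
        meta = gene_meta[gid]
        # promoter window offsets 0..599 (= -500..+100); bin b covers
        # [(b-1)*100, b*100); keep the hexamer fully inside its bin
        o = int(rng.integers((b - 1) * 100, b * 100 - 5))
        # window offset o is transcript position (o - 500) relative to the TSS
        editors[meta["contig"]].plant(meta["strand"], meta["tss"], o - 500,
                                      config.planted_promoter_motif)

    # internal-priming traps: A-runs with non-A flanks, transcript sense
    trap_rows = []
    n_intergenic = config.n_priming_traps - config.n_priming_traps // 2
    n_transcript = config.n_priming_traps - n_intergenic
    run = "C" + "A" * config.trap_run_length + "C"
    inter_slots = rng.choice(config.n_genes, size=n_intergenic, replace=False)
    host_genes = rng.choice(gene_ids, size=n_transcript, replace=False)
    for j in range(config.n_priming_traps):
        tid = f"trap{j + 1:02d}"
        if j < n_intergenic:
            contig, slot = slot_of[int(inter_slots[j])]
            start = _SLOT_MARGIN + slot * _SLOT + 40  # 0-based; clear of promoters/genes
            editors[contig].arr[start:start + len(run)] = list(run)
            lo = start + 2  # 1-based first A
            trap_rows.append((tid, contig, "+", lo, lo + config.trap_run_length - 1,
                              "intergenic", ""))
        else:
            gid = str(host_genes[j - n_intergenic])
            meta = gene_meta[gid]
            ed = editors[meta["contig"]]
            ed.plant(meta["strand"], meta["tss"], 249, run)  # exon1, offsets 250..284+A run
            if meta["strand"] == "+":
                lo = meta["tss"] + 250
                hi = lo + config.trap_run_length - 1
            else:
                hi = meta["tss"] - 250
                lo = hi - config.trap_run_length + 1
            trap_rows.append((tid, meta["contig"], meta["strand"], lo, hi,
                              "transcript", gid))

    # miRNA-target labels, enriched among switch genes
    target_rows = []
    for pset in config.mirna_prediction_sets:
        for gid in gene_ids:
            rate = (config.mirna_target_rate_switch
                    if gene_meta[gid]["is_switch_gene"]
                    else config.mirna_target_rate_background)
            target_rows.append((gid, pset, bool(rng.random() < rate)))

    genome = {name: "".join(ed.arr) for name, ed in editors.items()}
    truth = Truth(
        sites=pd.DataFrame(site_rows, columns=list(_SITES_SCHEMA)).astype(_SITES_SCHEMA),
        traps=pd.DataFrame(trap_rows, columns=list(_TRAPS_SCHEMA)).astype(_TRAPS_SCHEMA),
        targets=pd.DataFrame(target_rows, columns=list(_TARGETS_SCHEMA)).astype(_TARGETS_SCHEMA),
        gene_flags=pd.DataFrame(
            [(gid, gid in carriers, gene_meta[gid]["is_switch_gene"]) for gid in gene_ids],
            columns=list(_GENES_SCHEMA)).astype(_GENES_SCHEMA),
    )
    return genome, genes, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _spliced_isoform(genome: dict, gene: GeneModel, site: int) -> str:
    """Exon-concatenated transcript sequence from the TSS to the cleavage site."""
    parts = []
    if gene.strand == "+":
        for s, e in gene.exons:
            parts.append(genome[gene.contig][s - 1:min(e, site)])
            if e >= site:
                break
        return "".join(parts)
    for s, e in reversed(gene.exons):
        lo = max(s, site)
        parts.append(revcomp(genome[gene.contig][lo - 1:e]))
        if s <= site:
            break
    return "".join(parts)


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[int(rng.integers(0, 3))]
    return "".join(out)


def parse_read_id(read_id: str) -> dict:
    """Decode the provenance a simulated read id carries."""
    parts = read_id.split("|")
    tissue, tag = parts[0], parts[1]
    kind = {"t": "polya", "b": "body", "a": "trap"}[tag[0]]
    info = {"tissue": tissue, "kind": kind}
    if kind == "polya":
        info.update(gene=parts[2], site_index=int(parts[3][1:]),
                    tail_length=int(parts[4][4:]))
    elif kind == "body":
        info["gene"] = parts[2]
    else:
        info["trap_id"] = parts[2]
    return info


def simulate_tissue_reads(genome, annotation, truth: Truth, tissue: str,
                          config: SimulationConfig) -> list:
    """Simulate one tissue's read set as (read_id, sequence) pairs.

    PolyA+ reads terminate at a true cleavage site and carry an untemplated
    pure-A tail; body reads sample the isoform uniformly; artifact reads end
    at a planted A-run so their tails are genomically templated.
    """
    if tissue not in config.tissue_names:
        raise ValueError(f"unknown tissue {tissue!r}")
    t_index = list(config.tissue_names).index(tissue)
    rng = np.random.default_rng([config.seed, 7919, t_index])

    df = truth.sites
    live = df[(df.tissue == tissue) & df.expressed]
    gene_ids = sorted(live.gene_id.unique())
    if not gene_ids:
        return []
    abund = {g: float(live.loc[live.gene_id == g, "abundance"].iloc[0]) for g in gene_ids}
    total = sum(abund.values())
    probs = np.array([abund[g] / total for g in gene_ids])

    usage = {}
    iso_seq = {}
    for g in gene_ids:
        sel = live[live.gene_id == g].sort_values("site_index")
        sites = list(sel.cleavage_site)
        usage[g] = (sites, np.asarray(sel.usage, dtype=float))
        for s in sites:
            iso_seq[(g, s)] = _spliced_isoform(genome, annotation[g], int(s))

    n_trap = config.n_priming_traps * config.artifact_reads_per_trap
    n_rest = config.n_reads_per_tissue - n_trap
    n_tail = int(round(n_rest * config.polya_read_fraction))
    n_body = n_rest - n_tail
    L = config.read_length
    tmin, tmax = config.tail_length_range

    reads = []
    gene_draw = rng.choice(len(gene_ids), size=n_tail + n_body, p=probs)

    for i in range(n_tail):
        g = gene_ids[gene_draw[i]]
        sites, w = usage[g]
        j = int(rng.choice(len(sites), p=w / w.sum()))
        tail = int(rng.integers(tmin, tmax + 1))
        body = iso_seq[(g, sites[j])][-(L - tail):]
        body = _mutate(rng, body, config.error_rate)
        tail_seq = _mutate(rng, "A" * tail, config.tail_error_rate)
        reads.append((f"{tissue}|t{i}|{g}|s{j}|tail{tail}", body + tail_seq))

    for i in range(n_body):
        g = gene_ids[gene_draw[n_tail + i]]
        sites, w = usage[g]
        j = int(rng.choice(len(sites), p=w / w.sum()))
        iso = iso_seq[(g, sites[j])]
        start = int(rng.integers(0, max(1, len(iso) - L + 1)))
        seq = _mutate(rng, iso[start:start + L], config.error_rate)
        reads.append((f"{tissue}|b{i}|{g}", seq))

    i = 0
    for _, trap in truth.traps.iterrows():
        if trap.strand == "+":
            lo, hi = trap.end - L + 1, trap.end
            window = genome[trap.contig][lo - 1:hi]
        else:
            lo, hi = trap.start, trap.start + L - 1
            window = revcomp(genome[trap.contig][lo - 1:hi])
        run = config.trap_run_length
        for _ in range(config.artifact_reads_per_trap):
            seq = _mutate(rng, window[:-run], config.error_rate) + window[-run:]
            reads.append((f"{tissue}|a{i}|{trap.trap_id}", seq))
            i += 1

    order = rng.permutation(len(reads))
    return [reads[k] for k in order]


def simulate_promoter_set(n: int, rng, motif: str | None = None,
                          motif_bin: int = 5, carrier_fraction: float = 0.0):
    """Random 600-nt promoter sequences with an optional planted hexamer.

    The motif is written into the configured 100-nt bin of exactly
    round(carrier_fraction * n) promoters (uniform offset within the bin).
    Returns a list of PromoterRegion-compatible (gene_id, sequence) holders.
    """
    from .promoters import PROMOTER_LEN, PromoterRegion

    n_carriers = int(round(carrier_fraction * n)) if motif else 0
    carriers = set(rng.choice(n, size=n_carriers, replace=False)) if n_carriers else set()
    out = []
    for i in range(n):
        seq = "".join(rng.choice(_BASES, size=PROMOTER_LEN))
        if i in carriers:
            o = int(rng.integers((motif_bin - 1) * 100, motif_bin * 100 - 5))
            seq = seq[:o] + motif + seq[o + len(motif):]
        out.append(PromoterRegion(f"p{i:04d}", seq))
    return out


# ---------------------------------------------------------------------------
# truth table I/O
# ---------------------------------------------------------------------------

_TRUTH_FILES = {
    "sites": ("truth_sites.tsv", _SITES_SCHEMA),
    "traps": ("truth_traps.tsv", _TRAPS_SCHEMA),
    "targets": ("truth_targets.tsv", _TARGETS_SCHEMA),
    "gene_flags": ("truth_genes.tsv", _GENES_SCHEMA),
}


def write_truth_tables(truth: Truth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, (fname, _schema) in _TRUTH_FILES.items():
        getattr(truth, attr).to_csv(outdir / fname, sep="\t", index=False)


def read_truth_tables(outdir) -> Truth:
    outdir = Path(outdir)
    frames = {}
    for attr, (fname, schema) in _TRUTH_FILES.items():
        df = pd.read_csv(outdir / fname, sep="\t", dtype=object,
                         keep_default_na=False)
        for col, typ in schema.items():
            if typ is bool:
                df[col] = df[col] == "True"
            else:
                df[col] = df[col].astype(typ)
        frames[attr] = df
    return Truth(**frames)


def write_simulation(config: SimulationConfig, outdir) -> Truth:
    """Generate and write a full synthetic data set (FASTA/GFF3/FASTQ/TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation, truth = generate_genome_and_annotation(config)
    write_fasta(genome, outdir / "genome.fa")
    write_annotation(annotation, outdir / "annotation.gff3")
    for tissue in config.tissue_names:
        reads = simulate_tissue_reads(genome, annotation, truth, tissue, config)
        write_fastq(reads, outdir / f"reads_{tissue}.fastq")
    write_truth_tables(truth, outdir)
    return truth
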