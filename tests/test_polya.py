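"""PolyA extraction, alignment, priming filter, clustering and cluster filters.

Filter thresholds are asserted at their strict printed boundaries: tails
retained at >= 30 A, events discarded at >= 65% flanking A or < 18 consecutive
matches, clusters discarded below 5% usage or above 40% footprint A.
"""

import itertools
import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apapipe.io_formats import ReadAlignment
from apapipe.polya import (CleavageEvent, GenomeIndex, PASCluster, TrimmedPolyARead,
                           align_trimmed_read, assign_clusters_to_genes,
                           cluster_cleavage_sites, compute_cleavage_site,
                           extract_polya_reads, filter_clusters,
                           filter_internal_priming, map_polya_reads)
from apapipe.io_formats import GeneModel
from apapipe.sequtil import revcomp


def suffix_scan_oracle(seq, min_tail):
    """Independent check: test every suffix for being all-A of length >= min_tail."""
    best = 0
    for k in range(1, len(seq) + 1):
        if set(seq[-k:]) == {"A"}:
            best = k
    return best if best >= min_tail else None


class TestExtractPolyaReads:
    def test_exact_30A_boundary_retained_29_rejected(self):
        body = "CGT" * 13 + "G"  # 40 nt, ends in G
        kept, acc = extract_polya_reads([("ok", body + "A" * 30),
                                         ("short", body + "A" * 29)])
        assert [r.read_id for r in kept] == ["ok"]
        assert kept[0].tail_length == 30
        assert len(kept[0].trimmed_sequence) == 40
        assert acc == Counter(retained=1, no_tail=1)

    def test_all_A_read_dropped_as_unalignable(self):
        kept, acc = extract_polya_reads([("r", "A" * 40)])
        assert kept == [] and acc["trimmed_too_short"] == 1

    def test_non_acgtn_characters_rejected_per_read(self):
        kept, acc = extract_polya_reads([("bad", "ACGU" + "A" * 30)])
        assert kept == [] and acc["invalid_characters"] == 1

    def test_matches_suffix_scan_oracle_on_random_reads(self):
        rng = random.Random(42)
        reads = []
        for i in range(10_000):
            n = rng.randint(10, 90)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            if rng.random() < 0.5:
                seq += "A" * rng.randint(20, 45)
            reads.append((f"r{i}", seq))
        kept, _ = extract_polya_reads(reads, min_tail=30, min_length=0)
        by_id = {r.read_id: r for r in kept}
        for rid, seq in reads:
            tail = suffix_scan_oracle(seq, 30)
            if tail is None:
                assert rid not in by_id
            else:
                assert by_id[rid].tail_length == tail
                assert by_id[rid].trimmed_sequence == seq[:len(seq) - tail]

    @given(st.text(alphabet="ACGT", min_size=0, max_size=60),
           st.integers(min_value=0, max_value=50))
    @settings(max_examples=200, deadline=None)
    def test_property_agrees_with_oracle(self, body, tail_len):
        seq = body + "A" * tail_len
        kept, _ = extract_polya_reads([("r", seq)], min_tail=30, min_length=0)
        oracle = suffix_scan_oracle(seq, 30)
        if oracle is None:
            assert kept == []
        else:
            assert kept[0].tail_length == oracle


def _toy_genome(rng=None, n=4000):
    rng = rng or random.Random(17)
    return {"chr1": "".join(rng.choice("CGT") + rng.choice("ACGT") for _ in range(n // 2))}


class TestAligner:
    def test_exact_read_aligns_full_length(self):
        genome = _toy_genome()
        index = GenomeIndex(genome)
        q = genome["chr1"][500:560]
        aln, reason = align_trimmed_read(TrimmedPolyARead("r", q, 30), index)
        assert reason is None
        assert (aln.contig, aln.strand, aln.leftmost_position) == ("chr1", "+", 500)
        assert aln.longest_consecutive_match == 60
        assert aln.tail_length == 30

    def test_reverse_strand_hit(self):
        genome = _toy_genome()
        index = GenomeIndex(genome)
        q = revcomp(genome["chr1"][800:860])
        aln, reason = align_trimmed_read(TrimmedPolyARead("r", q, 30), index)
        assert reason is None and aln.strand == "-" and aln.leftmost_position == 800

    def test_duplicated_locus_is_multi_mapped(self):
        seg = "ACGTGCATTGCAGGCTACAGGATCCATGACGATCAGGATC"
        filler = _toy_genome(n=600)["chr1"]
        genome = {"chr1": filler + seg + filler[::-1] + seg + filler}
        index = GenomeIndex(genome)
        aln, reason = align_trimmed_read(TrimmedPolyARead("r", seg, 30), index)
        assert aln is None and reason == "multi_mapped"

    def test_single_substitution_gives_flanking_run_lengths(self):
        genome = _toy_genome()
        index = GenomeIndex(genome)
        ref = genome["chr1"][1000:1040]
        i = 11
        q = ref[:i] + ("A" if ref[i] != "A" else "C") + ref[i + 1:]
        aln, reason = align_trimmed_read(TrimmedPolyARead("r", q, 30), index)
        assert reason is None
        assert aln.longest_consecutive_match == max(i, len(q) - 1 - i)

    def test_absent_sequence_is_unaligned(self):
        index = GenomeIndex(_toy_genome())
        aln, reason = align_trimmed_read(TrimmedPolyARead("r", "A" * 10 + "C" * 30, 30), index)
        assert aln is None and reason == "unaligned"


class TestComputeCleavageSite:
    def test_plus_strand_rightmost_base(self):
        aln = ReadAlignment("r", "chr1", "+", 999, 40, 40)
        assert compute_cleavage_site(aln).cleavage_position == 1039

    def test_minus_strand_leftmost_base(self):
        aln = ReadAlignment("r", "chr1", "-", 999, 40, 40)
        assert compute_cleavage_site(aln).cleavage_position == 1000


def _event(genome, pos, strand="+", lcm=40):
    aln = ReadAlignment("r", "chr1", strand, pos - 40, 40, lcm)
    return CleavageEvent("r", "chr1", strand, pos, aln)


class TestInternalPrimingFilter:
    def _genome_with_downstream(self, pos, window_seq):
        base = "C" * (pos) + window_seq
        base += "G" * (pos + 200 - len(base))
        return {"chr1": base}

    def test_downstream_20_of_30_A_fails(self):
        w = "A" * 20 + "G" * 10  # 66.7% A
        genome = self._genome_with_downstream(100, w)
        ok, reason = filter_internal_priming(_event(genome, 100), genome)
        assert (ok, reason) == (False, "a_rich_downstream")

    def test_19_of_30_both_windows_and_18_match_passes(self):
        w = "A" * 19 + "G" * 11  # 63.3% A
        genome = {"chr1": "G" * 70 + w + w + "G" * 60}
        # upstream window = positions 71..100, downstream = 101..130
        ok, reason = filter_internal_priming(_event(genome, 100, lcm=18), genome)
        assert (ok, reason) == (True, None)

    def test_17_consecutive_matches_fails(self):
        genome = {"chr1": "G" * 200}
        ok, reason = filter_internal_priming(_event(genome, 100, lcm=17), genome)
        assert (ok, reason) == (False, "short_match")

    def test_minus_strand_reads_A_on_sense_strand(self):
        # genomic T-run downstream (in transcript orientation) of a '-' event
        genome = {"chr1": "G" * 40 + "T" * 30 + "G" * 130}
        ok, reason = filter_internal_priming(_event(genome, 71, strand="-"), genome)
        assert (ok, reason) == (False, "a_rich_downstream")

    def test_window_truncated_at_contig_edge_uses_available_bases(self):
        genome = {"chr1": "A" * 5 + "G" * 100}
        # downstream of position 101 has only 4 G's? use upstream edge case:
        ok, reason = filter_internal_priming(_event(genome, 8), genome)
        # upstream window 1..8 = AAAAAGGG -> 5/8 = 62.5% < 65% passes
        assert ok


def brute_force_transitive_closure(positions, max_gap):
    """Oracle: repeatedly merge any two groups with members within max_gap.

    Groups hold read indices so duplicate positions keep their multiplicity.
    """
    groups = [[i] for i in range(len(positions))]
    merged = True
    while merged:
        merged = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            if any(abs(positions[a] - positions[b]) <= max_gap
                   for a in groups[i] for b in groups[j]):
                groups[i] += groups[j]
                del groups[j]
                merged = True
                break
    return sorted(sorted(positions[i] for i in g) for g in groups)


def _events_at(positions, strand="+"):
    return [CleavageEvent(f"r{i}", "chr1", strand, p,
                          ReadAlignment(f"r{i}", "chr1", strand, p, 1, 1))
            for i, p in enumerate(positions)]


class TestClustering:
    def test_single_linkage_by_hand(self):
        clusters = cluster_cleavage_sites(_events_at([100, 101, 101, 103, 200]))
        assert [sorted(c.member_positions) for c in clusters] == [[100, 101, 101, 103], [200]]
        assert clusters[0].representative_site == 101  # modal position
        assert clusters[0].read_count == 4

    def test_gap_26_splits_gap_25_joins(self):
        assert len(cluster_cleavage_sites(_events_at([100, 126]))) == 2
        assert len(cluster_cleavage_sites(_events_at([100, 125]))) == 1

    def test_single_event_cluster(self):
        (c,) = cluster_cleavage_sites(_events_at([500]))
        assert (c.representative_site, c.span_start, c.span_end, c.read_count) == (500, 500, 500, 1)

    def test_modal_tie_breaks_to_three_prime_most(self):
        plus = cluster_cleavage_sites(_events_at([100, 100, 105, 105]))
        assert plus[0].representative_site == 105
        minus = cluster_cleavage_sites(_events_at([100, 100, 105, 105], strand="-"))
        assert minus[0].representative_site == 100

    def test_matches_transitive_closure_oracle_on_random_positions(self):
        rng = random.Random(3)
        for trial in range(20):
            positions = [rng.randint(1, 2000) for _ in range(rng.randint(1, 200))]
            clusters = cluster_cleavage_sites(_events_at(positions))
            got = sorted(sorted(c.member_positions) for c in clusters)
            assert got == brute_force_transitive_closure(positions, 25)

    @given(st.lists(st.integers(min_value=1, max_value=5000), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant_and_idempotent(self, positions):
        base = cluster_cleavage_sites(_events_at(positions))
        perm = cluster_cleavage_sites(_events_at(list(reversed(positions))))
        key = lambda cs: [(c.span_start, tuple(sorted(c.member_positions))) for c in cs]
        assert key(base) == key(perm)
        # idempotent: clustering the representatives of singleton re-input
        again = cluster_cleavage_sites(
            _events_at([p for c in base for p in c.member_positions]))
        assert key(again) == key(base)


def _gene(gid, start, end, stop, strand="+", contig="chr1"):
    return GeneModel(gene_id=gid, contig=contig, strand=strand, gene_start=start,
                     gene_end=end, stop_codon_end=stop)


def _cluster_at(pos, strand="+", count=10, cid="c1"):
    return PASCluster(cluster_id=cid, contig="chr1", strand=strand,
                      member_positions=(pos,) * count, representative_site=pos,
                      span_start=pos, span_end=pos, read_count=count)


class TestGeneAssignment:
    def test_1600_boundary(self):
        gene = _gene("g", 1000, 2000, 1800)
        near = _cluster_at(2000 + 1600)
        far = _cluster_at(2000 + 1601, cid="c2")
        assign_clusters_to_genes([near, far], {"g": gene})
        assert near.assigned_gene == "g" and near.distance_to_gene == 1600
        assert far.assigned_gene is None

    def test_opposite_strand_gene_excluded(self):
        gene = _gene("g", 1000, 2000, 1800, strand="-")
        c = _cluster_at(2100, strand="+")
        assign_clusters_to_genes([c], {"g": gene})
        assert c.assigned_gene is None

    def test_equidistant_tie_goes_to_upstream_gene(self):
        up = _gene("up", 1000, 2000, 1800)        # 3' end 2000
        down = _gene("down", 3000, 4000, 3800)    # site 500 upstream of its stop? no:
        c = _cluster_at(2500)  # 500 past up's end, 500 before down's stop interval
        assign_clusters_to_genes([c], {"up": up, "down": down})
        assert c.assigned_gene == "up"

    def test_inside_utr_distance_zero(self):
        gene = _gene("g", 1000, 2000, 1800)
        c = _cluster_at(1900)
        assign_clusters_to_genes([c], {"g": gene})
        assert (c.assigned_gene, c.distance_to_gene) == ("g", 0)


class TestFilterClusters:
    def _genome(self):
        return {"chr1": "CGTG" * 2500}

    def test_usage_below_5pct_filtered_at_exactly_5pct_retained(self):
        genome = self._genome()
        for counts, expect_minor in (((96, 4), "filtered"), ((95, 5), "retained")):
            major = _cluster_at(100, count=counts[0], cid="a")
            minor = _cluster_at(300, count=counts[1], cid="b")
            for c in (major, minor):
                c.assigned_gene = "g"
            filter_clusters([major, minor], genome)
            assert minor.status == expect_minor, counts
            if expect_minor == "filtered":
                assert minor.filter_reason == "low_usage"
                assert major.usage_fraction == 1.0  # renormalized

    def test_footprint_41pct_A_filtered_40pct_retained(self):
        fail_seq = "A" * 41 + "G" * 59
        pass_seq = "A" * 40 + "G" * 60
        genome = {"chr1": fail_seq + pass_seq + "C" * 100}
        c_fail = PASCluster("a", "chr1", "+", (1,), 1, 1, 100, read_count=50,
                            assigned_gene="g")
        c_pass = PASCluster("b", "chr1", "+", (101,), 101, 101, 200, read_count=50,
                            assigned_gene="g")
        filter_clusters([c_fail, c_pass], genome)
        assert c_fail.status == "filtered" and c_fail.filter_reason == "a_rich_footprint"
        assert c_pass.status == "retained"

    def test_retained_usage_sums_to_one(self):
        genome = self._genome()
        clusters = [_cluster_at(100 + 300 * i, count=n, cid=f"c{i}")
                    for i, n in enumerate((50, 30, 15, 3))]
        for c in clusters:
            c.assigned_gene = "g"
        filter_clusters(clusters, genome)
        retained = [c for c in clusters if c.retained]
        assert sum(c.usage_fraction for c in retained) == pytest.approx(1.0, abs=1e-9)


class TestConservation:
    def test_every_read_accounted_once(self, default_run):
        for tr in default_run.tissues.values():
            total = sum(tr.map_result.accounting.values())
            assert total == default_run.config.n_reads_per_tissue
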