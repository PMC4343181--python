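"""Small sequence/coordinate helpers shared across the pipeline.

Internal convention: genomic coordinates are 1-based inclusive, with explicit
strand. "Transcript orientation" means the sense strand read 5'->3': on the
minus strand the genomic window is reverse-complemented before use.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def fetch_oriented(genome: dict, contig: str, strand: str, lo: int, hi: int) -> str:
    """Fetch genomic [lo, hi] (1-based inclusive), oriented to the sense strand.

    Windows overhanging a contig edge are truncated; callers that need to know
    how many bases were available use ``len()`` of the result.
    """
    seq = genome[contig]
    lo = max(lo, 1)
    hi = min(hi, len(seq))
    if hi < lo:
        return ""
    sub = seq[lo - 1:hi]
    return revcomp(sub) if strand == "-" else sub


def a_fraction(seq: str) -> float:
    """Fraction of A in a sense-strand sequence; 0.0 for the empty string."""
    if not seq:
        return 0.0
    return seq.count("A") / len(seq)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def terminal_a_run(seq: str) -> int:
    """Length of the maximal run of A at the 3' end of a read sequence."""
    return len(seq) - len(seq.rstrip("A"))
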