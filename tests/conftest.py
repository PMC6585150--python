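"""Shared fixtures and independent oracles for the test suite."""

from fractions import Fraction
from math import factorial

import pytest

from circdiff.model import CircRecord, GenomicInterval, SampleTable, parse_circ_id


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def ac_point_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Exact rational evaluation of the count-comparison point mass
    (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1))."""
    r = Fraction(n2, n1)
    return (r ** y * Fraction(factorial(x + y), factorial(x) * factorial(y))
            / (1 + r) ** (x + y + 1))


def ac_two_sided_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Exact rational two-sided tail p-value: double the smaller of
    P(Y <= y | x) and P(Y >= y | x), clamped at 1."""
    lower = sum(ac_point_exact(x, k, n1, n2) for k in range(y + 1))
    upper = 1 - sum(ac_point_exact(x, k, n1, n2) for k in range(y))
    return min(Fraction(1), 2 * min(lower, upper))


def classify_by_base(interval, model) -> str:
    """Per-base brute-force region classifier (oracle for classify_region)."""
    bases = set(range(interval.start, interval.end + 1))
    exon_bases: set[int] = set()
    span_bases: set[int] = set()
    for gene in model.genes:
        if gene.chrom != interval.chrom:
            continue
        span_bases.update(range(gene.start, gene.end + 1))
        for s, e in gene.exons:
            exon_bases.update(range(s, e + 1))
    if bases & exon_bases:
        return "exon"
    if bases & span_bases:
        return "intron"
    return "intergenic"


# ---------------------------------------------------------------------------
# Table construction helpers
# ---------------------------------------------------------------------------

def make_table(sample_id: str, counts: dict[str, int], filler_total: int = 0,
               **record_kwargs) -> SampleTable:
    """A SampleTable from a circ_id -> junction_reads mapping; an optional
    filler record absorbs extra library depth so totals are controllable."""
    records = [
        CircRecord(interval=parse_circ_id(cid), junction_reads=reads,
                   **record_kwargs)
        for cid, reads in counts.items()]
    total = sum(counts.values())
    if filler_total > total:
        records.append(CircRecord(
            interval=GenomicInterval("chr99", 1, 2),
            junction_reads=filler_total - total))
    return SampleTable(sample_id, records)


@pytest.fixture
def toy_pair():
    """A small, fully deterministic (B, C) pair with one strong change."""
    b = make_table("tB", {"chr1:100|200": 50, "chr1:300|400": 300,
                          "chr2:10|90": 40}, filler_total=10000)
    c = make_table("tC", {"chr1:100|200": 50, "chr1:300|400": 3,
                          "chr2:500|900": 35}, filler_total=10000)
    return b, c
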