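"""Genomic-region classification and circBase-style reference matching.

A circRNA is classed by the region its back-splice span overlaps:

* ``exon`` — it overlaps at least one exon of any gene;
* ``intron`` — it overlaps at least one gene span but no exon;
* ``intergenic`` — it overlaps no gene span.

The priority exon > intron > intergenic makes the call deterministic, and
the three classes partition every sample.  Matching against a reference
catalogue is by exact interval equality (an optional slack exists for
future tolerance but defaults to 0): a record whose interval is in the
catalogue receives its accession, all others are flagged novel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .model import (GenomicInterval, SampleTable, _normalize_chrom,
                    parse_circ_id, percentage)


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted, merged

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(
                    f"exon ({s}, {e}) outside gene span of {self.gene_id}")


class GeneModel:
    """A collection of genes with exon structure, indexed by chromosome."""

    def __init__(self, genes: list[Gene] | tuple[Gene, ...]) -> None:
        self.genes: tuple[Gene, ...] = tuple(genes)
        self._by_chrom: dict[str, list[Gene]] = {}
        for gene in self.genes:
            self._by_chrom.setdefault(gene.chrom, []).append(gene)

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    @classmethod
    def from_gtf(cls, path) -> "GeneModel":
        """Build from GTF/GFF3 exon features grouped by gene_id."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
            keep_order=True)
        exons_by_gene: dict[str, list[tuple[str, int, int]]] = {}
        for feat in db.features_of_type("exon"):
            gid = (feat.attributes.get("gene_id") or feat.attributes.get("Parent") or [None])[0]
            if gid is None:
                continue
            exons_by_gene.setdefault(gid, []).append(
                (_normalize_chrom(feat.seqid), feat.start, feat.end))
        genes = []
        for gid in sorted(exons_by_gene):
            chroms = {c for c, _, _ in exons_by_gene[gid]}
            if len(chroms) != 1:
                raise ValueError(f"gene {gid!r} has exons on multiple chromosomes")
            exons = _merge_intervals([(s, e) for _, s, e in exons_by_gene[gid]])
            genes.append(Gene(gid, chroms.pop(), exons[0][0], exons[-1][1], exons))
        return cls(genes)

    @classmethod
    def from_tsv(cls, path) -> "GeneModel":
        """Read the simplified gene-model TSV: columns gene_id, chrom,
        gene_start, gene_end, exon_starts, exon_ends (comma-separated,
        1-based inclusive)."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        genes = []
        for row in df.itertuples(index=False):
            starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
            ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
            if len(starts) != len(ends):
                raise ValueError(f"gene {row.gene_id}: exon_starts/exon_ends length mismatch")
            exons = _merge_intervals(list(zip(starts, ends)))
            genes.append(Gene(str(row.gene_id), _normalize_chrom(str(row.chrom)),
                              int(row.gene_start), int(row.gene_end), exons))
        return cls(genes)


def write_gene_model(model: GeneModel, path) -> None:
    rows = [{
        "gene_id": g.gene_id,
        "chrom": g.chrom,
        "gene_start": g.start,
        "gene_end": g.end,
        "exon_starts": ",".join(str(s) for s, _ in g.exons),
        "exon_ends": ",".join(str(e) for _, e in g.exons),
    } for g in model.genes]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "gene_start", "gene_end",
                                "exon_starts", "exon_ends"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap length of two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def classify_region(interval: GenomicInterval, model: GeneModel) -> str:
    """Region class under the priority exon > intron > intergenic.

    A chromosome absent from the model yields ``intergenic``.
    """
    in_span = False
    for gene in model.genes_on(interval.chrom):
        if _overlap(interval.start, interval.end, gene.start, gene.end) == 0:
            continue
        in_span = True
        for es, ee in gene.exons:
            if _overlap(interval.start, interval.end, es, ee) > 0:
                return "exon"
    return "intron" if in_span else "intergenic"


def assign_gene(interval: GenomicInterval, model: GeneModel) -> str | None:
    """Gene attribution for an interval: the gene with the largest exon
    overlap (falling back to gene-span overlap when no exon is touched),
    ties broken lexicographically by gene_id; None when intergenic."""
    best: tuple[int, int, str] | None = None  # (exon_overlap, span_overlap, gene_id)
    for gene in sorted(model.genes_on(interval.chrom), key=lambda g: g.gene_id):
        span = _overlap(interval.start, interval.end, gene.start, gene.end)
        if span == 0:
            continue
        exonic = sum(_overlap(interval.start, interval.end, es, ee)
                     for es, ee in gene.exons)
        key = (exonic, span, gene.gene_id)
        if best is None or (key[0], key[1]) > (best[0], best[1]):
            best = key
    return best[2] if best else None


def annotate_regions(table: SampleTable, model: GeneModel) -> SampleTable:
    """A copy of *table* with circ_type and gene_id set from *model*."""
    records = []
    for rec in table.records:
        ctype = classify_region(rec.interval, model)
        gid = assign_gene(rec.interval, model) if ctype != "intergenic" else None
        records.append(replace(rec, circ_type=ctype, gene_id=gid))
    return table.with_records(records)


# ---------------------------------------------------------------------------
# Reference matching
# ---------------------------------------------------------------------------

class AnnotationReference:
    """Mapping from back-splice interval to a circBase-style accession."""

    def __init__(self, entries: dict[GenomicInterval, str] | None = None) -> None:
        self.entries: dict[GenomicInterval, str] = dict(entries or {})

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, interval: GenomicInterval, slack: int = 0) -> str | None:
        hit = self.entries.get(interval)
        if hit is not None or slack == 0:
            return hit
        for ds in range(-slack, slack + 1):
            for de in range(-slack, slack + 1):
                start = interval.start + ds
                if start <= 0:
                    continue
                end = interval.end + de
                if end < start:
                    continue
                hit = self.entries.get(GenomicInterval(interval.chrom, start, end))
                if hit is not None:
                    return hit
        return None

    @classmethod
    def from_tsv(cls, path) -> "AnnotationReference":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        entries = {}
        for row in df.itertuples(index=False):
            iv = parse_circ_id(str(row.circ_id))
            if iv in entries and entries[iv] != str(row.circbase_id):
                raise ValueError(f"conflicting accessions for {iv.circ_id}")
            entries[iv] = str(row.circbase_id)
        return cls(entries)

    def to_tsv(self, path) -> None:
        rows = sorted((iv.circ_id, acc) for iv, acc in self.entries.items())
        pd.DataFrame(rows, columns=["circ_id", "circbase_id"]).to_csv(
            path, sep="\t", index=False)


def match_reference(table: SampleTable, ref: AnnotationReference,
                    slack: int = 0) -> SampleTable:
    """A copy of *table* in which records whose interval is present in *ref*
    carry the matching accession; all others stay novel (no accession)."""
    records = []
    for rec in table.records:
        acc = ref.lookup(rec.interval, slack=slack)
        records.append(replace(rec, circbase_id=acc) if acc is not None else
                       replace(rec, circbase_id=None))
    return table.with_records(records)


# ---------------------------------------------------------------------------
# Per-sample summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSummary:
    """Per-sample detection summary: junction reads, species count, how many
    species are in the reference catalogue, and the exon/intron/intergenic
    partition, each with its percentage of the species count (two decimals,
    half-up)."""

    sample_id: str
    n_junction_reads: int
    n_species: int
    n_in_reference: int
    n_exon: int
    n_intron: int
    n_intergenic: int

    def __post_init__(self) -> None:
        if self.n_exon + self.n_intron + self.n_intergenic != self.n_species:
            raise ValueError(
                f"region counts {self.n_exon}+{self.n_intron}+{self.n_intergenic} "
                f"do not partition n_species={self.n_species} "
                f"in sample {self.sample_id}")

    @property
    def pct_in_reference(self) -> float:
        return percentage(self.n_in_reference, self.n_species)

    @property
    def pct_exon(self) -> float:
        return percentage(self.n_exon, self.n_species)

    @property
    def pct_intron(self) -> float:
        return percentage(self.n_intron, self.n_species)

    @property
    def pct_intergenic(self) -> float:
        return percentage(self.n_intergenic, self.n_species)


def summarize_sample(table: SampleTable) -> SampleSummary:
    """Summarize one sample.  Every record must carry a region class (run
    :func:`annotate_regions` first, or supply tables with circRNA_type set)."""
    unknown = [r.circ_id for r in table.records if r.circ_type == "unknown"]
    if unknown:
        raise ValueError(
            f"sample {table.sample_id}: {len(unknown)} record(s) lack a region "
            f"class (first: {unknown[0]}); annotate against a gene model first")
    return SampleSummary(
        sample_id=table.sample_id,
        n_junction_reads=table.total_junction_reads,
        n_species=len(table),
        n_in_reference=sum(1 for r in table.records if r.circbase_id is not None),
        n_exon=sum(1 for r in table.records if r.circ_type == "exon"),
        n_intron=sum(1 for r in table.records if r.circ_type == "intron"),
        n_intergenic=sum(1 for r in table.records if r.circ_type == "intergenic"),
    )


def write_summaries(summaries: list[SampleSummary], path) -> None:
    """Write per-sample summaries as a TSV (one row per sample)."""
    rows = [{
        "sample_id": s.sample_id,
        "junction_reads": s.n_junction_reads,
        "species": s.n_species,
        "in_reference": s.n_in_reference,
        "pct_in_reference": f"{s.pct_in_reference:.2f}",
        "exon": s.n_exon,
        "pct_exon": f"{s.pct_exon:.2f}",
        "intron": s.n_intron,
        "pct_intron": f"{s.pct_intron:.2f}",
        "intergenic": s.n_intergenic,
        "pct_intergenic": f"{s.pct_intergenic:.2f}",
    } for s in summaries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
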