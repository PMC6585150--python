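"""Domain types and I/O for circRNA detection tables.

A circRNA is identified by its back-splice junction, written as
``chrN:start|end`` where *start* and *end* are the 1-based inclusive
donor/acceptor boundary coordinates.  Detection tables are tab-separated,
one row per circRNA detected in one sample, carrying the junction-read
count (the expression "semaphore"), the flanking non-junction read count,
an alignment-signal tag, the genomic region class and optional gene /
circBase annotations.
"""

from __future__ import annotations

import decimal
import re
from dataclasses import dataclass, field

import pandas as pd

CIRC_TYPES = ("exon", "intron", "intergenic", "unknown")

#: Canonical detection-table header.  The first two columns are mandatory.
TABLE_COLUMNS = (
    "circRNA_ID",
    "junction_reads",
    "non_junction_reads",
    "SM_MS_SMS",
    "junction_reads_ratio",
    "circRNA_type",
    "gene_id",
    "circBase_ID",
)


class CircIdParseError(ValueError):
    """Raised for a malformed ``chrN:start|end`` identifier."""


def round_half_up(value: float | decimal.Decimal, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(value) if isinstance(value, float) else value)
                 .quantize(q, rounding=decimal.ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """``100 * count / total`` rounded half-up; 0.0 when ``total`` is 0."""
    if total == 0:
        return 0.0
    return round_half_up(decimal.Decimal(100 * count) / decimal.Decimal(total), ndigits)


# ---------------------------------------------------------------------------
# GenomicInterval and identifier parsing
# ---------------------------------------------------------------------------

def _normalize_chrom(chrom: str) -> str:
    """Normalize to a lowercase ``chr`` prefix so annotation joins are
    deterministic; the remainder (``19``, ``X`` ...) is kept verbatim."""
    token = re.sub(r"\s+", "", chrom)
    if not token:
        raise CircIdParseError("empty chromosome name")
    if token[:3].lower() == "chr":
        token = token[3:]
    if not token:
        raise CircIdParseError(f"chromosome name is a bare prefix: {chrom!r}")
    return "chr" + token


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval: the span between back-splice donor and
    acceptor sites."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start <= 0:
            raise ValueError(f"start must be positive, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.circ_id


_CIRC_ID_RE = re.compile(r"^\s*(?P<chrom>[^:|]+?)\s*:\s*(?P<start>\S+)\s*\|\s*(?P<end>\S+)\s*$")


def parse_circ_id(text: str) -> GenomicInterval:
    """Parse ``chrN:start|end`` (case-insensitive ``chr`` prefix optional,
    stray whitespace tolerated) into a :class:`GenomicInterval`.

    Raises :class:`CircIdParseError` naming the offending token.
    """
    m = _CIRC_ID_RE.match(text)
    if m is None:
        raise CircIdParseError(f"malformed circRNA identifier: {text!r}")
    coords = []
    for name in ("start", "end"):
        token = m.group(name)
        if not token.isdigit():
            raise CircIdParseError(f"non-numeric coordinate {token!r} in {text!r}")
        coords.append(int(token))
    start, end = coords
    chrom = _normalize_chrom(m.group("chrom"))
    if start > end:
        raise CircIdParseError(f"start {start} > end {end} in {text!r}")
    if start <= 0:
        raise CircIdParseError(f"non-positive coordinate {start} in {text!r}")
    return GenomicInterval(chrom, start, end)


# ---------------------------------------------------------------------------
# CircRecord
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircRecord:
    """One circRNA detected in one sample.

    ``junction_reads_ratio`` defaults to the CIRI-style reliability measure
    ``2j / (2j + nj)`` computed from the two counts; a value supplied by the
    input is preserved and only checked for [0, 1] membership.
    ``alignment_signal`` (the SM/MS/SMS tag) is stored verbatim and never
    interpreted.
    """

    interval: GenomicInterval
    junction_reads: int
    non_junction_reads: int = 0
    junction_reads_ratio: float | None = None
    alignment_signal: str = ""
    circ_type: str = "unknown"
    gene_id: str | None = None
    circbase_id: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.junction_reads < 0:
            raise ValueError(f"negative junction_reads for {self.circ_id}")
        if self.non_junction_reads < 0:
            raise ValueError(f"negative non_junction_reads for {self.circ_id}")
        if self.circ_type not in CIRC_TYPES:
            raise ValueError(f"unknown circ_type {self.circ_type!r} for {self.circ_id}")
        if self.junction_reads_ratio is None:
            denom = 2 * self.junction_reads + self.non_junction_reads
            if denom > 0:
                ratio = 2 * self.junction_reads / denom
                object.__setattr__(self, "junction_reads_ratio", ratio)
        elif not 0.0 <= self.junction_reads_ratio <= 1.0:
            raise ValueError(
                f"junction_reads_ratio {self.junction_reads_ratio} outside [0, 1] "
                f"for {self.circ_id}")

    @property
    def circ_id(self) -> str:
        return self.interval.circ_id

    @property
    def novel(self) -> bool:
        """True when the circRNA carries no circBase accession."""
        return self.circbase_id is None


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------

class SampleTable:
    """All circRNAs detected in one sample.

    ``total_junction_reads`` is the library size N of the two-library test;
    it defaults to the in-table sum of junction reads but can be overridden
    when the sequencing run reports a larger per-sample junction total.
    """

    def __init__(
        self,
        sample_id: str,
        records: list[CircRecord] | tuple[CircRecord, ...] = (),
        sample_type: str = "unknown",
        total_junction_reads: int | None = None,
    ) -> None:
        self.sample_id = sample_id
        self.sample_type = sample_type
        self.records: list[CircRecord] = list(records)
        seen: dict[str, int] = {}
        for rec in self.records:
            seen[rec.circ_id] = seen.get(rec.circ_id, 0) + 1
        dups = sorted(cid for cid, n in seen.items() if n > 1)
        if dups:
            raise ValueError(
                f"duplicate circ_id(s) in sample {sample_id}: {', '.join(dups)}")
        in_table = sum(rec.junction_reads for rec in self.records)
        if total_junction_reads is None:
            self.total_junction_reads = in_table
        else:
            peak = max((r.junction_reads for r in self.records), default=0)
            if total_junction_reads < peak:
                raise ValueError(
                    f"total_junction_reads {total_junction_reads} below the "
                    f"largest per-record count {peak} in sample {sample_id}")
            self.total_junction_reads = int(total_junction_reads)
        self._index = {rec.circ_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, circ_id: str) -> bool:
        return circ_id in self._index

    def get(self, circ_id: str) -> CircRecord | None:
        return self._index.get(circ_id)

    def circ_ids(self) -> list[str]:
        return [rec.circ_id for rec in self.records]

    def with_records(self, records: list[CircRecord]) -> "SampleTable":
        """A copy of this table carrying *records* (totals recomputed unless
        the original total was an override larger than the record sum)."""
        in_table = sum(r.junction_reads for r in records)
        override = self.total_junction_reads if self.total_junction_reads > in_table else None
        return SampleTable(self.sample_id, records, self.sample_type, override)


# ---------------------------------------------------------------------------
# Detection-table I/O
# ---------------------------------------------------------------------------

def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def read_sample_table(path, sample_id: str, sample_type: str = "unknown",
                      total_junction_reads: int | None = None) -> SampleTable:
    """Read a tab-separated detection table (``#`` lines are comments).

    Mandatory columns: ``circRNA_ID`` and ``junction_reads``.  Missing
    optional columns are filled with ``unknown``/absent; columns outside the
    canonical schema are preserved per record in ``extras``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False, na_values=[""])
    missing = [c for c in ("circRNA_ID", "junction_reads") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    extra_cols = [c for c in df.columns if c not in TABLE_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        interval = parse_circ_id(row["circRNA_ID"])
        jr = int(row["junction_reads"])
        njr = int(row["non_junction_reads"]) if _opt_str(row.get("non_junction_reads")) else 0
        ratio_text = _opt_str(row.get("junction_reads_ratio"))
        ratio = float(ratio_text) if ratio_text is not None else None
        circ_type = _opt_str(row.get("circRNA_type")) or "unknown"
        records.append(CircRecord(
            interval=interval,
            junction_reads=jr,
            non_junction_reads=njr,
            junction_reads_ratio=ratio,
            alignment_signal=_opt_str(row.get("SM_MS_SMS")) or "",
            circ_type=circ_type,
            gene_id=_opt_str(row.get("gene_id")),
            circbase_id=_opt_str(row.get("circBase_ID")),
            extras={c: row[c] for c in extra_cols},
        ))
    return SampleTable(sample_id, records, sample_type, total_junction_reads)


def write_sample_table(table: SampleTable, path, header_comment: str | None = None) -> None:
    """Write *table* in the canonical TSV detection-table format."""
    extra_cols: list[str] = []
    for rec in table.records:
        for c in rec.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for rec in table.records:
        row = {
            "circRNA_ID": rec.circ_id,
            "junction_reads": rec.junction_reads,
            "non_junction_reads": rec.non_junction_reads,
            "SM_MS_SMS": rec.alignment_signal,
            "junction_reads_ratio": (
                "" if rec.junction_reads_ratio is None
                else repr(rec.junction_reads_ratio)),
            "circRNA_type": rec.circ_type,
            "gene_id": rec.gene_id or "",
            "circBase_ID": rec.circbase_id or "",
        }
        row.update({c: rec.extras.get(c, "") for c in extra_cols})
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS) + extra_cols)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_bed(table: SampleTable, path) -> None:
    """BED6 export: 0-based half-open coordinates, name = circ_id, score =
    junction reads capped at the BED bound of 1000, strand ``.`` (strand is
    not part of the detection-table schema)."""
    with open(path, "w") as fh:
        for rec in table.records:
            iv = rec.interval
            score = min(rec.junction_reads, 1000)
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{rec.circ_id}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# Study collection statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyCollection:
    """Per-study sample and circRNA counts for a pooled collection."""

    studies: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for name, n_samples, n_circ in self.studies:
            if n_samples < 0 or n_circ < 0:
                raise ValueError(f"negative count for study {name!r}")

    @property
    def total_samples(self) -> int:
        return sum(n for _, n, _ in self.studies)

    @property
    def total_circrnas(self) -> int:
        return sum(n for _, _, n in self.studies)


def collection_total(collection: StudyCollection) -> int:
    """Total circRNAs pooled over all studies."""
    if not collection.studies:
        raise ValueError("empty study collection")
    return collection.total_circrnas


def read_study_table(path) -> StudyCollection:
    """Read a study-statistics TSV with columns study, samples, circrnas."""
    df = pd.read_csv(path, sep="\t", comment="#")
    triples = tuple(
        (str(r.study), int(r.samples), int(r.circrnas))
        for r in df.itertuples(index=False))
    return StudyCollection(triples)
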