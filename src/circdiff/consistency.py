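"""Cross-group consistency of significant differential-expression calls.

A circRNA that is significantly changed in the same direction across
several independent tumor/normal comparison groups is a stronger disease
candidate than one seen once.  This module aggregates per-group results
into one record per circRNA, counts the comparison groups supporting its
dominant direction ("found x/y" of y groups examined), drops circRNAs with
conflicting directions, and splits the reported candidates into
catalogue-annotated versus novel (no circBase-style accession).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .diffexp import DiffExpResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsistencyRecord:
    """Cross-group aggregation for one circRNA."""

    circ_id: str
    circbase_id: str | None
    gene_id: str | None
    per_group: tuple[tuple[str, bool, str], ...]  # (group_id, significant, direction)
    n_groups_total: int
    n_consistent: int
    consensus_direction: str
    conflicted: bool

    def __post_init__(self) -> None:
        if not 0 <= self.n_consistent <= self.n_groups_total:
            raise ValueError(
                f"{self.circ_id}: n_consistent {self.n_consistent} outside "
                f"[0, {self.n_groups_total}]")

    @property
    def found_label(self) -> str:
        return f"{self.n_consistent}/{self.n_groups_total}"

    @property
    def novel(self) -> bool:
        return self.circbase_id is None


@dataclass(frozen=True)
class ConsistencyReport:
    """Records with n_consistent >= min_groups, sorted by (n_consistent
    descending, circ_id); conflicted circRNAs are excluded (kept separately
    for audit)."""

    records: tuple[ConsistencyRecord, ...]
    excluded_conflicted: tuple[ConsistencyRecord, ...]
    min_groups: int
    n_groups_total: int

    @property
    def histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for rec in self.records:
            hist[rec.n_consistent] = hist.get(rec.n_consistent, 0) + 1
        return hist

    @property
    def n_annotated(self) -> int:
        return sum(1 for r in self.records if not r.novel)

    @property
    def n_novel(self) -> int:
        return sum(1 for r in self.records if r.novel)


def aggregate(group_results: dict[str, list[DiffExpResult]],
              min_groups: int = 2) -> ConsistencyReport:
    """Aggregate per-group results into a consistency report.

    Every circRNA significant in at least one group gets a record; only
    records whose dominant-direction support reaches *min_groups* are
    reported.  A circRNA significant Up in some groups and Down in others is
    conflicted: its consensus is the majority direction (a tie counts as
    conflicted too) and it is excluded from the report and logged.
    """
    if not group_results:
        raise ValueError("at least one comparison group is required")
    n_groups_total = len(group_results)
    per_circ: dict[str, dict[str, DiffExpResult]] = {}
    for gid in sorted(group_results):
        seen: set[str] = set()
        for res in group_results[gid]:
            if res.circ_id in seen:
                raise ValueError(f"duplicate circ_id {res.circ_id} in group {gid}")
            seen.add(res.circ_id)
            if res.significant:
                per_circ.setdefault(res.circ_id, {})[gid] = res

    kept: list[ConsistencyRecord] = []
    conflicted: list[ConsistencyRecord] = []
    for cid in sorted(per_circ):
        hits = per_circ[cid]
        n_up = sum(1 for r in hits.values() if r.direction == "Up")
        n_down = len(hits) - n_up
        is_conflicted = n_up >= 1 and n_down >= 1
        if n_up > n_down:
            consensus, n_consistent = "Up", n_up
        elif n_down > n_up:
            consensus, n_consistent = "Down", n_down
        else:  # tie: direction is arbitrary, record stays conflicted
            consensus, n_consistent = "Down", n_down
        any_hit = next(iter(hits.values()))
        rec = ConsistencyRecord(
            circ_id=cid,
            circbase_id=any_hit.circbase_id,
            gene_id=any_hit.gene_id,
            per_group=tuple((g, True, hits[g].direction) for g in sorted(hits)),
            n_groups_total=n_groups_total,
            n_consistent=n_consistent,
            consensus_direction=consensus,
            conflicted=is_conflicted,
        )
        if is_conflicted:
            conflicted.append(rec)
            logger.info("excluding conflicted circRNA %s (Up in %d, Down in %d groups)",
                        cid, n_up, n_down)
        elif rec.n_consistent >= min_groups:
            kept.append(rec)
    kept.sort(key=lambda r: (-r.n_consistent, r.circ_id))
    return ConsistencyReport(
        records=tuple(kept),
        excluded_conflicted=tuple(conflicted),
        min_groups=min_groups,
        n_groups_total=n_groups_total,
    )


def split_annotated(report: ConsistencyReport,
                    ) -> tuple[list[ConsistencyRecord], list[ConsistencyRecord]]:
    """Partition reported records into (annotated, novel), report order kept."""
    annotated = [r for r in report.records if not r.novel]
    novel = [r for r in report.records if r.novel]
    return annotated, novel


def report_to_frame(report: ConsistencyReport) -> pd.DataFrame:
    rows = [{
        "CircRNA_ID": r.circ_id,
        "CircBase_ID": r.circbase_id or "",
        "Gene_ID": r.gene_id or "",
        "Up/down regulation": r.consensus_direction,
        "Found (x/y)": r.found_label,
        "conflicted": r.conflicted,
    } for r in report.records]
    return pd.DataFrame(rows, columns=["CircRNA_ID", "CircBase_ID", "Gene_ID",
                                       "Up/down regulation", "Found (x/y)",
                                       "conflicted"])


def write_report(report: ConsistencyReport, path) -> None:
    report_to_frame(report).to_csv(path, sep="\t", index=False)


def write_histogram(report: ConsistencyReport, path) -> None:
    hist = report.histogram
    pd.DataFrame(sorted(hist.items(), reverse=True),
                 columns=["n_consistent", "count"]).to_csv(path, sep="\t", index=False)
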