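"""Synthetic paired tumor/normal circRNA detection data with known truth.

The generator emulates the study design the pipeline targets: several
patients, each contributing a normal (B) and a tumor (C) library of
back-splice junction counts over a shared circRNA universe.  Baseline
abundances are heavy-tailed (log-normal relative rates), counts are
negative-binomial around rate x library size, a planted subset of circRNAs
is truly differentially expressed (a sub-subset with a shared identity and
direction in every patient), and low-abundance circRNAs can drop out of a
sample's detection table.  CircRNAs are placed on a small synthetic genome
so that their true region class agrees with the annotation classifier, and
a fraction of the universe is present in a synthetic reference catalogue.

Defaults mirror the scale of the motivating HCC study: five patient pairs,
per-sample junction-read totals of 5 000-35 000, roughly 91%/8%/1%
exon/intron/intergenic species and ~70% catalogue-annotated species.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .annotation import AnnotationReference, Gene, GeneModel
from .consistency import ConsistencyReport
from .diffexp import ComparisonGroup
from .model import CircRecord, GenomicInterval, SampleTable, write_sample_table

_REGION_PROBS = {"exon": 0.91, "intron": 0.08, "intergenic": 0.01}
_SIGNALS = ("SM", "MS", "SMS")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the generator.

    ``dispersion`` is the negative-binomial overdispersion phi in
    var = m + phi m^2 (0 = Poisson); the default 0.01 adds mild
    technical-level extra-Poisson noise.  ``detection_dropout`` is the
    probability that a circRNA with expected count < 1 is missing from a
    sample's detection table.  ``shared_de_min_expected_reads`` > 0 floors
    the baseline rate of shared-DE circRNAs so each is expected at that
    read depth even in the smallest library (a strong-effect scenario).
    """

    n_circ: int = 3000
    n_groups: int = 5
    frac_de: float = 0.05
    log2fc_range: tuple[float, float] = (1.0, 3.0)
    frac_shared_de: float = 0.25
    library_size_range: tuple[int, int] = (5000, 35000)
    detection_dropout: float = 0.3
    dispersion: float = 0.01
    frac_annotated: float = 0.7
    shared_de_min_expected_reads: float = 0.0
    rate_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_circ < 1 or self.n_groups < 1:
            raise ValueError("n_circ and n_groups must be >= 1")
        for name in ("frac_de", "frac_shared_de", "detection_dropout", "frac_annotated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.log2fc_range[0] <= self.log2fc_range[1]:
            raise ValueError(f"log2fc_range out of order: {self.log2fc_range}")
        if self.log2fc_range[0] < 0:
            raise ValueError("log2fc_range holds absolute fold changes (>= 0)")
        if not 0 < self.library_size_range[0] <= self.library_size_range[1]:
            raise ValueError(f"library_size_range invalid: {self.library_size_range}")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("log2fc_range", "library_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["log2fc_range"] = list(self.log2fc_range)
        raw["library_size_range"] = list(self.library_size_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass(frozen=True)
class CircTruth:
    """Ground truth for one circRNA of the universe."""

    circ_id: str
    baseline_rate: float
    region_type: str
    gene_id: str | None
    annotated: bool
    shared_de: bool
    lfc_by_group: dict[str, float] = field(default_factory=dict)

    def lfc(self, group_id: str) -> float:
        return self.lfc_by_group.get(group_id, 0.0)

    @property
    def is_de(self) -> bool:
        return any(v != 0.0 for v in self.lfc_by_group.values())

    @property
    def shared_direction(self) -> str | None:
        if not self.shared_de:
            return None
        sign = next(iter(self.lfc_by_group.values()))
        return "Up" if sign > 0 else "Down"


@dataclass(frozen=True)
class GroundTruth:
    circs: dict[str, CircTruth]
    group_ids: tuple[str, ...]

    @property
    def shared_de_ids(self) -> list[str]:
        return sorted(c.circ_id for c in self.circs.values() if c.shared_de)


# ---------------------------------------------------------------------------
# Synthetic genome and interval placement
# ---------------------------------------------------------------------------

_CHROM_LEN = 100_000
_GENE_SPACING = 3000
_GENE_FIRST = 501
_EXON_LEN = 200
_EXON_OFFSETS = (0, 600, 1200, 1800)


def build_gene_model(n_chroms: int = 3) -> GeneModel:
    """A deterministic toy genome: ``n_chroms`` chromosomes of 100 kb, genes
    tiled every 3 kb, four 200-bp exons per gene with 400-bp introns."""
    genes = []
    idx = 0
    for c in range(1, n_chroms + 1):
        chrom = f"chr{c}"
        start = _GENE_FIRST
        while start + _EXON_OFFSETS[-1] + _EXON_LEN - 1 <= _CHROM_LEN - 500:
            idx += 1
            exons = tuple((start + off, start + off + _EXON_LEN - 1)
                          for off in _EXON_OFFSETS)
            genes.append(Gene(f"GENE{idx:04d}", chrom, exons[0][0], exons[-1][1], exons))
            start += _GENE_SPACING
    return GeneModel(genes)


def _intergenic_gaps(model: GeneModel, n_chroms: int) -> list[tuple[str, int, int]]:
    gaps = []
    for c in range(1, n_chroms + 1):
        chrom = f"chr{c}"
        pos = 1
        for gene in sorted(model.genes_on(chrom), key=lambda g: g.start):
            if gene.start - 1 >= pos + 20:
                gaps.append((chrom, pos, gene.start - 1))
            pos = gene.end + 1
        if _CHROM_LEN >= pos + 20:
            gaps.append((chrom, pos, _CHROM_LEN))
    return gaps


def _place_interval(rng: np.random.Generator, region: str, model: GeneModel,
                    gaps: list[tuple[str, int, int]]) -> tuple[GenomicInterval, str | None]:
    """One interval whose true region class is *region*; returns the placed
    gene_id (None for intergenic)."""
    if region == "intergenic":
        chrom, lo, hi = gaps[rng.integers(len(gaps))]
        a, b = sorted(rng.integers(lo, hi + 1, size=2))
        return GenomicInterval(chrom, int(a), int(b)), None
    gene = model.genes[rng.integers(len(model.genes))]
    if region == "exon":
        i, j = sorted(rng.integers(len(gene.exons), size=2))
        a = int(rng.integers(gene.exons[i][0], gene.exons[i][1] + 1))
        b = int(rng.integers(gene.exons[j][0], gene.exons[j][1] + 1))
        if a > b:
            a, b = b, a
        return GenomicInterval(gene.chrom, a, b), gene.gene_id
    # intron: strictly between two consecutive exons of one gene
    k = int(rng.integers(len(gene.exons) - 1))
    lo, hi = gene.exons[k][1] + 1, gene.exons[k + 1][0] - 1
    a, b = sorted(rng.integers(lo, hi + 1, size=2))
    return GenomicInterval(gene.chrom, int(a), int(b)), gene.gene_id


# ---------------------------------------------------------------------------
# Count sampling
# ---------------------------------------------------------------------------

def _draw_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial counts with var = m + phi m^2 (Poisson at phi=0)."""
    if phi <= 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _normalized_rates(rng: np.random.Generator, config: SimulationConfig,
                      shared_mask: np.ndarray) -> np.ndarray:
    rates = rng.lognormal(mean=0.0, sigma=config.rate_sigma, size=config.n_circ)
    rates /= rates.sum()
    floor_reads = config.shared_de_min_expected_reads
    if floor_reads > 0 and shared_mask.any():
        floor_rate = floor_reads / config.library_size_range[0]
        for _ in range(50):
            deficit = shared_mask & (rates < floor_rate)
            if not deficit.any():
                break
            rates[deficit] = floor_rate
            rates /= rates.sum()
        else:
            raise ValueError(
                "shared_de_min_expected_reads is unsatisfiable for this "
                "n_circ / library_size_range combination")
    return rates


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig,
             ) -> tuple[list[ComparisonGroup], GeneModel, AnnotationReference, GroundTruth]:
    """Generate paired detection tables plus gene model, reference catalogue
    and ground truth, fully reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_circ
    group_ids = tuple(f"{g}B_vs_{g}C" for g in range(1, config.n_groups + 1))

    # --- universe: regions, placement, annotation ---
    model = build_gene_model()
    gaps = _intergenic_gaps(model, 3)
    regions = rng.choice(list(_REGION_PROBS), size=n, p=list(_REGION_PROBS.values()))
    intervals: list[GenomicInterval] = []
    gene_ids: list[str | None] = []
    used: set[GenomicInterval] = set()
    for region in regions:
        for _ in range(1000):
            iv, gid = _place_interval(rng, region, model, gaps)
            if iv not in used:
                break
        else:  # pragma: no cover - would need a saturated genome
            raise ValueError("could not place a unique interval; reduce n_circ")
        used.add(iv)
        intervals.append(iv)
        gene_ids.append(gid)

    annotated_mask = np.zeros(n, dtype=bool)
    n_ann = int(round(config.frac_annotated * n))
    annotated_mask[rng.choice(n, size=n_ann, replace=False)] = True
    accession = {
        i: f"hsa_circ_{k + 1:07d}"
        for k, i in enumerate(np.flatnonzero(annotated_mask))}
    reference = AnnotationReference(
        {intervals[i]: accession[i] for i in accession})

    # --- planted differential expression ---
    n_de = int(round(config.frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    n_shared = int(round(config.frac_shared_de * n_de))
    shared_idx = de_idx[:n_shared]
    single_idx = de_idx[n_shared:]
    shared_mask = np.zeros(n, dtype=bool)
    shared_mask[shared_idx] = True

    lfc = np.zeros((config.n_groups, n))
    lo, hi = config.log2fc_range
    shared_lfc = rng.uniform(lo, hi, size=n_shared) * rng.choice([-1.0, 1.0], size=n_shared)
    lfc[:, shared_idx] = shared_lfc  # same effect in every group
    for i in single_idx:
        g = int(rng.integers(config.n_groups))
        lfc[g, i] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])

    rates = _normalized_rates(rng, config, shared_mask)

    # --- per-group sampling ---
    groups: list[ComparisonGroup] = []
    lib_lo, lib_hi = config.library_size_range
    for g, gid in enumerate(group_ids):
        sizes = {}
        for side in ("B", "C"):
            sizes[side] = int(rng.integers(lib_lo, lib_hi + 1))
        c_rates = rates * np.exp2(lfc[g])
        c_rates = c_rates / c_rates.sum()
        tables = {}
        for side, side_rates, stype in (("B", rates, "normal"), ("C", c_rates, "tumor")):
            mean = side_rates * sizes[side]
            counts = _draw_counts(rng, mean, config.dispersion)
            low = mean < 1.0
            dropped = low & (rng.random(n) < config.detection_dropout)
            counts = np.where(dropped, 0, counts)
            records = []
            for i in np.flatnonzero(counts > 0):
                jr = int(counts[i])
                njr = int(rng.poisson(2 * jr))
                records.append(CircRecord(
                    interval=intervals[i],
                    junction_reads=jr,
                    non_junction_reads=njr,
                    alignment_signal=str(rng.choice(_SIGNALS)),
                    circ_type=str(regions[i]),
                    gene_id=gene_ids[i],
                    circbase_id=accession.get(i),
                ))
            if not records:
                raise ValueError(
                    f"configuration produced an empty sample {g + 1}{side}; "
                    "increase n_circ or library sizes")
            tables[side] = SampleTable(
                f"{g + 1}{side}", records, sample_type=stype)
        groups.append(ComparisonGroup(gid, tables["B"], tables["C"]))

    truth = GroundTruth(
        circs={
            intervals[i].circ_id: CircTruth(
                circ_id=intervals[i].circ_id,
                baseline_rate=float(rates[i]),
                region_type=str(regions[i]),
                gene_id=gene_ids[i],
                annotated=bool(annotated_mask[i]),
                shared_de=bool(shared_mask[i]),
                lfc_by_group={gid: float(lfc[g, i])
                              for g, gid in enumerate(group_ids)
                              if lfc[g, i] != 0.0},
            )
            for i in range(n)},
        group_ids=group_ids,
    )
    return groups, model, reference, truth


# ---------------------------------------------------------------------------
# Dataset serialization
# ---------------------------------------------------------------------------

def write_dataset(outdir, groups, model: GeneModel, reference: AnnotationReference,
                  truth: GroundTruth, config: SimulationConfig) -> None:
    """Write the generated dataset in the same TSV formats the readers
    consume: one detection table per sample, the gene model, the reference
    catalogue, the ground truth and the configuration."""
    from pathlib import Path

    from .annotation import write_gene_model

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"generator=circdiff.simulate seed={config.seed}"
    for grp in groups:
        for table in (grp.b, grp.c):
            write_sample_table(table, outdir / f"{table.sample_id}.tsv",
                               header_comment=header)
    write_gene_model(model, outdir / "gene_model.tsv")
    reference.to_tsv(outdir / "reference.tsv")
    config.to_yaml(outdir / "config.yaml")
    rows = [{
        "circ_id": t.circ_id,
        "baseline_rate": repr(t.baseline_rate),
        "region_type": t.region_type,
        "gene_id": t.gene_id or "",
        "annotated": int(t.annotated),
        "shared_de": int(t.shared_de),
        "lfc": ";".join(f"{g}:{v!r}" for g, v in sorted(t.lfc_by_group.items())),
    } for _, t in sorted(truth.circs.items())]
    pd.DataFrame(rows, columns=["circ_id", "baseline_rate", "region_type",
                                "gene_id", "annotated", "shared_de", "lfc"]
                 ).to_csv(outdir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Evaluation against truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalMetrics:
    """Recovery of planted shared-DE circRNAs from a consistency report.

    ``by_level`` maps a consistency level k to (precision, recall) of
    shared-DE recovery among report records with n_consistent >= k;
    ``direction_accuracy`` is the fraction of recovered shared-DE circRNAs
    whose consensus direction matches the planted one (nan when none were
    recovered)."""

    by_level: dict[int, tuple[float, float]]
    direction_accuracy: float
    n_true_shared: int

    def precision(self, level: int) -> float:
        return self.by_level[level][0]

    def recall(self, level: int) -> float:
        return self.by_level[level][1]


def truth_eval(report: ConsistencyReport, truth: GroundTruth) -> EvalMetrics:
    """Score a consistency report against the generator's ground truth."""
    unknown = [r.circ_id for r in report.records if r.circ_id not in truth.circs]
    if unknown:
        raise ValueError(
            f"report and truth universes differ; unknown circ_id(s): "
            f"{', '.join(unknown[:5])}")
    shared = set(truth.shared_de_ids)
    by_level: dict[int, tuple[float, float]] = {}
    n_groups = len(truth.group_ids)
    for level in range(report.min_groups, n_groups + 1):
        pred = {r.circ_id for r in report.records if r.n_consistent >= level}
        tp = len(pred & shared)
        precision = tp / len(pred) if pred else float("nan")
        recall = tp / len(shared) if shared else float("nan")
        by_level[level] = (precision, recall)
    recovered = [r for r in report.records if r.circ_id in shared]
    if recovered:
        correct = sum(
            1 for r in recovered
            if r.consensus_direction == truth.circs[r.circ_id].shared_direction)
        direction_accuracy = correct / len(recovered)
    else:
        direction_accuracy = float("nan")
    return EvalMetrics(by_level=by_level, direction_accuracy=direction_accuracy,
                       n_true_shared=len(shared))
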