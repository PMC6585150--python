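"""Two-library differential expression of circRNA junction counts.

The statistic is the Audic–Claverie count-comparison probability: given a
circRNA observed x times among N1 junction reads in library B, the
predictive probability of observing it y times among N2 reads in library C
under a common underlying rate is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is the negative-binomial pmf with size x+1 and success probability
1/(1 + N2/N1).  The default p-value doubles the smaller predictive tail
(two-sided); the raw point mass is retained as ``mode="point"``.

Expression is normalized to TPM = junction reads per million total junction
reads; an undetected circRNA gets the floor value 0.001 so log2 ratios are
always defined.  Per comparison group (a B/C sample pair), p-values over
the union of detected circRNAs are Benjamini–Hochberg adjusted, and a
circRNA is called significant when FDR < 0.001 and |log2 ratio| >= 1 (both
thresholds configurable).

Because the Audic–Claverie tail conditions on one of the two counts, the
raw two-sided value is not symmetric in the sample labels.  The pairwise
comparison therefore evaluates it in a canonical orientation — conditioning
on the smaller count (ties broken by the smaller library) — so that
exchanging B and C leaves every p-value unchanged and only flips signs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .model import SampleTable, percentage

logger = logging.getLogger(__name__)

DEFAULT_FDR_MAX = 0.001
DEFAULT_MIN_ABS_LOG2 = 1.0
TPM_FLOOR = 0.001
P_MODES = ("two_sided", "point")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def tpm(reads: int, total: int) -> float:
    """Junction reads per million total junction reads; the undetected case
    (reads = 0) returns the floor 0.001."""
    if total <= 0:
        raise ValueError(f"library size must be positive, got {total}")
    if reads < 0:
        raise ValueError(f"negative read count {reads}")
    if reads == 0:
        return TPM_FLOOR
    return reads / total * 1e6


def log2_ratio(b_tpm: float, c_tpm: float) -> float:
    """log2(C over B); both inputs must be positive (the TPM floor
    guarantees this for pipeline-produced values)."""
    if b_tpm <= 0 or c_tpm <= 0:
        raise ValueError(f"non-positive TPM ({b_tpm}, {c_tpm}); floor was skipped upstream")
    return math.log2(c_tpm / b_tpm)


# ---------------------------------------------------------------------------
# Audic–Claverie statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ACInputs:
    """Counts and library sizes of one circRNA in a (B, C) pair: x among N1
    reads in B, y among N2 reads in C."""

    x: int
    y: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError(f"library sizes must be positive, got ({self.n1}, {self.n2})")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"negative counts ({self.x}, {self.y})")
        if self.x > self.n1 or self.y > self.n2:
            raise ValueError(
                f"count exceeds its library size: x={self.x} (N1={self.n1}), "
                f"y={self.y} (N2={self.n2})")


def _log_point_prob(x, y, log_r: float, log_1pr: float):
    """log p(y|x) for arrays/scalars x, y with r = N2/N1 fixed."""
    return (y * log_r + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
            - (x + y + 1) * log_1pr)


def ac_point_probability(inp: ACInputs) -> float:
    """The predictive point mass p(y|x), evaluated in log space (log-gamma)
    so counts up to at least 10**6 do not overflow."""
    log_r = math.log(inp.n2) - math.log(inp.n1)
    log_1pr = math.log1p(inp.n2 / inp.n1)
    return float(math.exp(_log_point_prob(inp.x, inp.y, log_r, log_1pr)))


def _tails(x: int, y: int, n1: int, n2: int) -> tuple[float, float]:
    """(P(Y <= y | x), P(Y >= y | x)) by summation of the point mass.

    The tail on the thin side of the predictive mean is summed directly in
    scaled log space (so it never underflows through a 1 - cdf complement);
    the other tail is recovered from its complement, where cancellation is
    harmless because that tail is large.
    """
    r = n2 / n1
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(r)
    mean = (x + 1) * r  # predictive mean of Y given x
    if y <= mean:
        # lower tail is the small side: finite sum over y' = 0..y
        k = np.arange(y + 1)
        logpmf = _log_point_prob(x, k, log_r, log_1pr)
        m = logpmf.max()
        terms = np.exp(logpmf - m)
        lower = float(math.exp(m) * terms.sum())
        point = float(math.exp(m) * terms[-1])
        upper = 1.0 - lower + point
    else:
        # upper tail is the small side: sum from y until the geometric
        # decay (term ratio -> r/(1+r) < 1) makes the remainder negligible
        log_start = float(_log_point_prob(x, y, log_r, log_1pr))
        term, total = 1.0, 0.0
        k = y
        while True:
            total += term
            k += 1
            term *= r * (x + k) / (k * (1.0 + r))
            if term < total * 1e-18 and k > y + 4:
                break
        upper = math.exp(log_start) * total
        point = math.exp(log_start)
        lower = 1.0 - upper + point
    return min(max(lower, 0.0), 1.0), min(max(upper, 0.0), 1.0)


def ac_p_value(inp: ACInputs, mode: str = "two_sided") -> float:
    """Audic–Claverie p-value.

    ``point`` returns the raw point mass p(y|x); ``two_sided`` (default)
    doubles the smaller of the two predictive tails and clamps to [0, 1].
    """
    if mode not in P_MODES:
        raise ValueError(f"unknown p-value mode {mode!r}; expected one of {P_MODES}")
    if mode == "point":
        return ac_point_probability(inp)
    lower, upper = _tails(inp.x, inp.y, inp.n1, inp.n2)
    return min(1.0, 2.0 * min(lower, upper))


def _canonical_p_value(xb: int, yc: int, n1: int, n2: int, mode: str) -> float:
    """Two-sided p in the label-free orientation: condition on the smaller
    count (ties: the smaller library), so swapping B and C is inert."""
    if mode == "point":
        return ac_p_value(ACInputs(xb, yc, n1, n2), mode="point")
    if (xb, n1) <= (yc, n2):
        return ac_p_value(ACInputs(xb, yc, n1, n2))
    return ac_p_value(ACInputs(yc, xb, n2, n1))


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        bad = p[(p < 0) | (p > 1) | np.isnan(p)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    return multipletests(p, method="fdr_bh")[1].tolist()


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonGroup:
    """A (B, C) pair of samples compared circRNA-by-circRNA — e.g. adjacent
    normal (B) and tumor (C) tissue from one patient."""

    group_id: str
    b: SampleTable
    c: SampleTable


@dataclass(frozen=True)
class DiffExpResult:
    """One circRNA's comparison row in a (B, C) group."""

    circ_id: str
    circbase_id: str | None
    gene_id: str | None
    b_expression: int
    c_expression: int
    b_tpm: float
    c_tpm: float
    log2_ratio: float
    direction: str  # "Up" | "Down"
    p_value: float
    fdr: float
    significant: bool


@dataclass(frozen=True)
class ComparisonSummary:
    """Counts of differing and significant circRNAs in one comparison."""

    group_id: str
    n_diff: int
    n_sig: int

    def __post_init__(self) -> None:
        if self.n_sig > self.n_diff:
            raise ValueError(f"n_sig {self.n_sig} > n_diff {self.n_diff}")

    @property
    def percentile(self) -> float:
        return percentage(self.n_sig, self.n_diff)


def compare_group(
    group: ComparisonGroup,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
    p_mode: str = "two_sided",
) -> tuple[list[DiffExpResult], ComparisonSummary]:
    """Compare the two samples of *group* over the union of their circRNAs.

    A circRNA absent from one side enters with count 0 and the TPM floor.
    Direction is Up when C exceeds B; a circRNA with equal TPMs is reported
    Down by convention but can never be significant (|log2 ratio| = 0).
    ``n_diff`` counts union members whose TPMs differ.
    """
    b, c = group.b, group.c
    if len(b) == 0 or len(c) == 0:
        raise ValueError(f"group {group.group_id}: both samples must be non-empty")
    n1, n2 = b.total_junction_reads, c.total_junction_reads
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"group {group.group_id}: zero total junction reads")

    union = sorted(set(b.circ_ids()) | set(c.circ_ids()))
    raw_p = []
    rows = []
    for cid in union:
        rb, rc = b.get(cid), c.get(cid)
        xb = rb.junction_reads if rb is not None else 0
        yc = rc.junction_reads if rc is not None else 0
        btpm = tpm(xb, n1)
        ctpm = tpm(yc, n2)
        lr = log2_ratio(btpm, ctpm)
        meta = rb if rb is not None else rc
        raw_p.append(_canonical_p_value(xb, yc, n1, n2, p_mode))
        rows.append((cid, meta.circbase_id, meta.gene_id, xb, yc, btpm, ctpm, lr))

    fdrs = bh_fdr(raw_p)
    results = []
    n_diff = 0
    n_sig = 0
    for (cid, acc, gid, xb, yc, btpm, ctpm, lr), p, q in zip(rows, raw_p, fdrs):
        direction = "Up" if ctpm > btpm else "Down"
        sig = q < fdr_max and abs(lr) >= min_abs_log2
        if btpm != ctpm:
            n_diff += 1
        if sig:
            n_sig += 1
        results.append(DiffExpResult(
            circ_id=cid, circbase_id=acc, gene_id=gid,
            b_expression=xb, c_expression=yc, b_tpm=btpm, c_tpm=ctpm,
            log2_ratio=lr, direction=direction, p_value=p, fdr=q,
            significant=sig))
    summary = ComparisonSummary(group.group_id, n_diff=n_diff, n_sig=n_sig)
    logger.info(
        "group %s: N1=%d N2=%d union=%d n_diff=%d n_sig=%d p_mode=%s "
        "fdr_max=%g min_abs_log2=%g",
        group.group_id, n1, n2, len(union), n_diff, n_sig, p_mode,
        fdr_max, min_abs_log2)
    return results, summary


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "Group ID", "CircRNA_ID", "CircBase_ID", "Gene ID",
    "B-Expression", "C-Expression", "B-TPM", "C-TPM",
    "Log2 Ratio", "Up-Down-Regulation", "P-value", "FDR",
)


def results_to_frame(group_id: str, results: list[DiffExpResult]) -> pd.DataFrame:
    rows = [{
        "Group ID": group_id,
        "CircRNA_ID": r.circ_id,
        "CircBase_ID": r.circbase_id or "",
        "Gene ID": r.gene_id or "",
        "B-Expression": r.b_expression,
        "C-Expression": r.c_expression,
        "B-TPM": repr(r.b_tpm),
        "C-TPM": repr(r.c_tpm),
        "Log2 Ratio": repr(r.log2_ratio),
        "Up-Down-Regulation": r.direction,
        "P-value": repr(r.p_value),
        "FDR": repr(r.fdr),
    } for r in results]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(group_id: str, results: list[DiffExpResult], path) -> None:
    results_to_frame(group_id, results).to_csv(path, sep="\t", index=False)


def read_results(path, fdr_max: float = DEFAULT_FDR_MAX,
                 min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
                 ) -> tuple[str, list[DiffExpResult]]:
    """Read a results TSV back; the significance flag is re-derived from the
    stored FDR and Log2 Ratio columns at the given thresholds."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: empty results table")
    group_ids = df["Group ID"].unique()
    if len(group_ids) != 1:
        raise ValueError(f"{path}: expected one Group ID, found {list(group_ids)}")
    results = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        lr = float(d["Log2 Ratio"])
        q = float(d["FDR"])
        results.append(DiffExpResult(
            circ_id=d["CircRNA_ID"],
            circbase_id=d["CircBase_ID"] or None,
            gene_id=d["Gene ID"] or None,
            b_expression=int(d["B-Expression"]),
            c_expression=int(d["C-Expression"]),
            b_tpm=float(d["B-TPM"]),
            c_tpm=float(d["C-TPM"]),
            log2_ratio=lr,
            direction=d["Up-Down-Regulation"],
            p_value=float(d["P-value"]),
            fdr=q,
            significant=q < fdr_max and abs(lr) >= min_abs_log2,
        ))
    return str(group_ids[0]), results


def scatter_data(results: list[DiffExpResult]) -> pd.DataFrame:
    """Per-circRNA (b_expression, c_expression, category) for a log-log
    expression scatter: up_significant (red), down_significant (green),
    not_significant (blue)."""
    rows = []
    for r in results:
        if r.significant:
            cat = "up_significant" if r.direction == "Up" else "down_significant"
        else:
            cat = "not_significant"
        rows.append({"circ_id": r.circ_id, "b_expression": r.b_expression,
                     "c_expression": r.c_expression, "category": cat})
    return pd.DataFrame(rows, columns=["circ_id", "b_expression",
                                       "c_expression", "category"])
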