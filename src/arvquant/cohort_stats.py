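"""Cohort-level statistics for per-patient / per-CTC transcript quantifications.

Covers the descriptive and inferential summaries used in liquid-biopsy
splice-variant studies:

* positivity calling and prevalence (positives / total, integer percent);
* per-transcript median / mean / range over *all* subjects, zeros included
  (a non-detected transcript contributes 0 copies, not a missing value);
* two-tailed Fisher exact test for group enrichment, by exact hypergeometric
  enumeration with the point-probability rule (every table with the observed
  margins whose probability does not exceed the observed table's is summed);
* Mann-Whitney U for group expression comparisons on log2-transformed
  counts, exact by enumeration for small samples and normal-approximated
  (tie- and continuity-corrected) otherwise;
* EpCAM-positive vs EpCAM-negative CTC-fraction comparison;
* a subjects x transcripts matrix export for heatmap display with an
  explicit not-detected sentinel.

The Fisher and Mann-Whitney routines are deliberately self-contained exact
implementations; library equivalents serve as independent cross-checks in
the test suite, never as the computation itself.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRANSCRIPTS = ("AR-FL", "AR-V7", "AR-v567es")

#: Sentinel written to heatmap exports for a not-detected (missing) value;
#: distinct from a true measured zero.
NOT_DETECTED = "ND"


class StatsError(ValueError):
    pass


@dataclass
class PatientRecord:
    """Copies/sample for the three transcripts in one subject (or one CTC)."""

    subject_id: str
    disease_group: str = "mCRPC"
    unit: str = "bulk_CTC"
    epcam_status: str = "NA"
    copies: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, v in self.copies.items():
            if v is not None and v < 0:
                raise StatsError(f"{self.subject_id}: negative copies for {tid}")


@dataclass
class TranscriptSummary:
    transcript_id: str
    n_positive: int
    n_total: int
    prevalence_percent: int  # Table-style integer percent
    prevalence_exact: float
    median: float
    mean: float
    range: tuple[float, float]


@dataclass
class CohortSummary:
    per_transcript: dict[str, TranscriptSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.per_transcript.values():
            rows.append(
                {
                    "transcript_id": s.transcript_id,
                    "n_positive": s.n_positive,
                    "n_total": s.n_total,
                    "prevalence_percent": s.prevalence_percent,
                    "median": s.median,
                    "mean": s.mean,
                    "min": s.range[0],
                    "max": s.range[1],
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows are groups, columns are positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatsError("contingency counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise StatsError("empty contingency table")


def call_positive(
    record: PatientRecord, transcript: str, threshold_copies: float = 0.0
) -> bool:
    """Positivity call: detected signal strictly above the copies threshold.

    The default threshold of 0 treats any detected signal as positive.  A
    missing measurement is *not detected* and logged, not an error.
    """
    if threshold_copies < 0:
        raise StatsError("threshold_copies must be >= 0")
    value = record.copies.get(transcript)
    if value is None:
        logger.info(
            "subject %s: %s not measured; treated as not detected",
            record.subject_id,
            transcript,
        )
        return False
    return value > threshold_copies


def summarize_cohort(
    records: Sequence[PatientRecord],
    threshold_copies: float = 0.0,
    transcripts: Sequence[str] = TRANSCRIPTS,
) -> CohortSummary:
    """Per-transcript prevalence and expression summary over the whole cohort.

    Median, mean and range are computed over *all* records, with
    not-detected entries contributing 0 copies.  Prevalence is reported
    both exactly and as the conventional rounded integer percent.
    """
    if not records:
        raise StatsError("empty cohort")
    out: dict[str, TranscriptSummary] = {}
    for tid in transcripts:
        values = np.array(
            [r.copies.get(tid) or 0.0 for r in records], dtype=float
        )
        n_pos = sum(call_positive(r, tid, threshold_copies) for r in records)
        n_tot = len(records)
        prev = 100.0 * n_pos / n_tot
        out[tid] = TranscriptSummary(
            transcript_id=tid,
            n_positive=n_pos,
            n_total=n_tot,
            prevalence_percent=int(round(prev)),
            prevalence_exact=prev,
            median=float(np.median(values)),
            mean=float(values.mean()),
            range=(float(values.min()), float(values.max())),
        )
    return CohortSummary(per_transcript=out)


# ---------------------------------------------------------------------------
# Fisher exact test (two-tailed, point-probability rule, exact arithmetic)
# ---------------------------------------------------------------------------

def fisher_exact_two_tailed(table: ContingencyTable) -> float:
    """Two-tailed Fisher exact p for a 2x2 table.

    With margins fixed, the table is determined by its top-left cell k,
    distributed hypergeometrically.  The two-sided p sums the point
    probabilities of every achievable table whose probability is less than
    or equal to the observed table's (the convention of mainstream
    statistics tools).  Probabilities are compared as exact integers
    (binomial-coefficient numerators over a common denominator), so tied
    tables are included without any floating-point tolerance.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    # numerator of P(k) with common denominator C(n_total, col1)
    def num(k: int) -> int:
        return comb(row1, k) * comb(n_total - row1, col1 - k)

    obs = num(a)
    tail = sum(nk for k in range(lo, hi + 1) if (nk := num(k)) <= obs)
    return tail / comb(n_total, col1)


def fisher_from_counts(
    pos1: int, total1: int, pos2: int, total2: int
) -> tuple[ContingencyTable, float]:
    """Convenience wrapper: build the 2x2 from positives/totals and test."""
    tbl = ContingencyTable(pos1, total1 - pos1, pos2, total2 - pos2)
    return tbl, fisher_exact_two_tailed(tbl)


# ---------------------------------------------------------------------------
# Mann-Whitney U (midranks; exact enumeration for small n)
# ---------------------------------------------------------------------------

EXACT_CROSSOVER = 12  # exact enumeration when n_x + n_y <= this


def _midranks(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    order = np.argsort(arr, kind="mergesort")
    ranks = np.empty(arr.size, dtype=float)
    i = 0
    while i < arr.size:
        j = i
        while j + 1 < arr.size and arr[order[j + 1]] == arr[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank ties.

    Returns ``(U, p)`` where U is the statistic of the first sample.  The
    exact branch enumerates every assignment of the pooled midranks to the
    two groups (feasible for n_x + n_y <= 12) and sums the probability of
    U values at least as far from the null mean n_x*n_y/2 as observed.
    Larger samples use the normal approximation with tie correction and a
    0.5 continuity correction.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise StatsError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    pooled = x + y
    ranks = _midranks(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mu = nx * ny / 2.0

    if nx + ny <= EXACT_CROSSOVER:
        # exact permutation distribution of U over rank assignments
        n = nx + ny
        dev_obs = abs(u_x - mu)
        hits = 0
        total = 0
        rank_sum_offset = nx * (nx + 1) / 2.0
        for idx in itertools.combinations(range(n), nx):
            u = ranks[list(idx)].sum() - rank_sum_offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_x, hits / total

    # normal approximation with tie and continuity correction
    n = nx + ny
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return u_x, 1.0
    z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = math.erfc(z / math.sqrt(2.0))
    return u_x, min(p, 1.0)


def log2_transform(
    raw_counts: Sequence[float] | np.ndarray, offset: float = 1.0
) -> np.ndarray:
    """log2(count + offset); the default offset of 1 maps zeros to zero."""
    arr = np.asarray(raw_counts, dtype=float)
    if np.any(arr < 0):
        raise StatsError("counts must be nonnegative")
    return np.log2(arr + offset)


# ---------------------------------------------------------------------------
# EpCAM-fraction comparison and heatmap export
# ---------------------------------------------------------------------------

def compare_epcam_fractions(
    records: Sequence[PatientRecord],
    threshold_copies: float = 0.0,
    transcripts: Sequence[str] = TRANSCRIPTS,
) -> pd.DataFrame:
    """Prevalence of each transcript in EpCAM-positive vs EpCAM-negative
    CTC fractions, with a two-tailed Fisher exact p per transcript.

    Records must carry ``epcam_status`` in {"pos", "neg"}; an empty fraction
    is an error because the comparison is undefined.
    """
    pos_recs = [r for r in records if r.epcam_status == "pos"]
    neg_recs = [r for r in records if r.epcam_status == "neg"]
    if not pos_recs or not neg_recs:
        raise StatsError("both EpCAM fractions must contain records")
    rows = []
    for tid in transcripts:
        n_pos_frac = sum(call_positive(r, tid, threshold_copies) for r in pos_recs)
        n_neg_frac = sum(call_positive(r, tid, threshold_copies) for r in neg_recs)
        _, p = fisher_from_counts(
            n_pos_frac, len(pos_recs), n_neg_frac, len(neg_recs)
        )
        rows.append(
            {
                "transcript_id": tid,
                "epcam_pos_positive": n_pos_frac,
                "epcam_pos_total": len(pos_recs),
                "epcam_pos_prevalence_percent": round(100.0 * n_pos_frac / len(pos_recs)),
                "epcam_neg_positive": n_neg_frac,
                "epcam_neg_total": len(neg_recs),
                "epcam_neg_prevalence_percent": round(100.0 * n_neg_frac / len(neg_recs)),
                "fisher_p": p,
            }
        )
    return pd.DataFrame(rows)


def heatmap_matrix(
    records: Sequence[PatientRecord],
    transcripts: Sequence[str] = TRANSCRIPTS,
) -> pd.DataFrame:
    """Subjects x transcripts copies matrix for heatmap display.

    Rows are ordered by subject id; a missing measurement becomes NaN
    internally and the :data:`NOT_DETECTED` sentinel on text export,
    distinct from a measured 0.
    """
    if not records:
        raise StatsError("empty cohort")
    data = {}
    for r in sorted(records, key=lambda r: r.subject_id):
        key = r.subject_id
        data[key] = [
            math.nan if r.copies.get(t) is None else float(r.copies[t])
            for t in transcripts
        ]
    return pd.DataFrame.from_dict(data, orient="index", columns=list(transcripts))


def write_heatmap_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep=NOT_DETECTED, index_label="subject_id")


def read_heatmap_matrix(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", index_col="subject_id", na_values=[NOT_DETECTED]
    )


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Build records from a long-format table with columns
    subject_id, disease_group, unit, epcam_status, transcript, copies."""
    required = {"subject_id", "transcript", "copies"}
    if not required.issubset(df.columns):
        raise StatsError(f"cohort table must have columns {sorted(required)}")
    records: dict[tuple, PatientRecord] = {}
    for _, row in df.iterrows():
        key = (
            row["subject_id"],
            row.get("unit", "bulk_CTC"),
            row.get("epcam_status", "NA"),
        )
        if key not in records:
            records[key] = PatientRecord(
                subject_id=str(row["subject_id"]),
                disease_group=str(row.get("disease_group", "mCRPC")),
                unit=str(row.get("unit", "bulk_CTC")),
                epcam_status=str(row.get("epcam_status", "NA")),
            )
        copies = row["copies"]
        records[key].copies[str(row["transcript"])] = (
            None if pd.isna(copies) else float(copies)
        )
    return list(records.values())


def load_cohort_csv(path) -> list[PatientRecord]:
    return records_from_frame(pd.read_csv(path))


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for tid, v in r.copies.items():
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "disease_group": r.disease_group,
                    "unit": r.unit,
                    "epcam_status": r.epcam_status,
                    "transcript": tid,
                    "copies": v,
                }
            )
    return pd.DataFrame(rows)
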