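"""Count spliced alignments that bridge a transcript's discriminating junction.

A split alignment supports a junction signature when one of its ``N``
(reference-skip) operations covers *exactly* the signature's intronic
interval ``[donor_end + 1, acceptor_start - 1]`` and the aligned segments
immediately flanking that skip anchor at least ``min_overhang`` bases on
each side.  Exact matching mirrors the specificity argument of
junction-anchored assays: a read that skips a different interval is
evidence for a different splice event, not weaker evidence for this one.

Transcript positivity is presence/absence: a sample is called positive for
a transcript when at least ``positivity_threshold`` spanning reads are
observed (default 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .transcript_model import (
    JunctionSignature,
    SignatureCollisionError,
    TranscriptModel,
    validate_signatures,
)

logger = logging.getLogger(__name__)

#: CIGAR operations that consume reference bases.
REF_CONSUMING = set("MDN=X")
#: CIGAR operations that count as aligned sequence match for anchoring.
ALIGNED_OPS = set("M=X")
_VALID_OPS = set("MIDNSH=XP")

# pysam integer cigar op codes -> characters
_PYSAM_OPS = "MIDNSHP=XB"


class SamParseError(ValueError):
    """Malformed SAM record (bad CIGAR or coordinate)."""


@dataclass(frozen=True)
class SplicedRead:
    """One mapped alignment with a decoded CIGAR.

    ``pos`` is the 1-based leftmost mapped reference coordinate (SAM
    convention); ``cigar`` is an ordered list of ``(length, op)`` tuples.
    """

    read_id: str
    chrom: str
    pos: int
    cigar: tuple[tuple[int, str], ...]
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SamParseError(f"{self.read_id}: position {self.pos} < 1")
        if not self.cigar:
            raise SamParseError(f"{self.read_id}: empty CIGAR")
        for length, op in self.cigar:
            if length <= 0:
                raise SamParseError(f"{self.read_id}: non-positive CIGAR length")
            if op not in _VALID_OPS:
                raise SamParseError(f"{self.read_id}: unknown CIGAR op {op!r}")
        if not any(op in REF_CONSUMING for _, op in self.cigar):
            raise SamParseError(f"{self.read_id}: no reference-consuming CIGAR op")


@dataclass(frozen=True)
class JunctionCount:
    """Spanning-read count and positivity call for one transcript."""

    transcript_id: str
    spanning_reads: int
    total_reads_screened: int
    positive: bool


def parse_cigar(cigar: str) -> tuple[tuple[int, str], ...]:
    """Decode a CIGAR string into (length, op) tuples."""
    if cigar == "*" or not cigar:
        raise SamParseError("missing CIGAR")
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in _VALID_OPS and num:
            ops.append((int(num), ch))
            num = ""
        else:
            raise SamParseError(f"malformed CIGAR {cigar!r}")
    if num:
        raise SamParseError(f"malformed CIGAR {cigar!r}")
    return tuple(ops)


def parse_sam(
    source: str | Path,
    *,
    include_secondary: bool = False,
    include_supplementary: bool = False,
) -> list[SplicedRead]:
    """Read mapped records from a SAM file into :class:`SplicedRead` objects.

    Unmapped records are always dropped; secondary and supplementary
    alignments are dropped under the defaults.  Decoding is delegated to
    pysam, so BAM input works transparently where htslib supports it.
    """
    reads: list[SplicedRead] = []
    save = pysam.set_verbosity(0)  # silence missing-index warning on SAM text
    try:
        with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
            for i, rec in enumerate(fh, start=1):
                if rec.is_unmapped:
                    continue
                if rec.is_secondary and not include_secondary:
                    continue
                if rec.is_supplementary and not include_supplementary:
                    continue
                if rec.cigartuples is None:
                    raise SamParseError(f"record {i} ({rec.query_name}): missing CIGAR")
                cigar = tuple(
                    (length, _PYSAM_OPS[op]) for op, length in rec.cigartuples
                )
                reads.append(
                    SplicedRead(
                        read_id=rec.query_name or f"record{i}",
                        chrom=rec.reference_name,
                        pos=rec.reference_start + 1,
                        cigar=cigar,
                        mapq=rec.mapping_quality,
                    )
                )
    finally:
        pysam.set_verbosity(save)
    return reads


def read_spans_junction(
    read: SplicedRead, sig: JunctionSignature, min_overhang: int = 6
) -> bool:
    """True iff the read's splice skip bridges exactly this signature's junction.

    The test walks the CIGAR along the reference.  For every ``N`` op it
    checks (a) the skipped interval equals ``[donor_end+1, acceptor_start-1]``
    and (b) the contiguous aligned (``M``/``=``/``X``) reference coverage
    immediately flanking the skip is at least ``min_overhang`` bases on both
    sides.  Anchors are measured in reference bases: a deletion breaks the
    run (its reference bases are not aligned) while an insertion, which
    consumes no reference, does not.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if read.chrom != sig.chrom:
        return False
    skip_start = sig.donor_end + 1
    skip_end = sig.acceptor_start - 1
    ref = read.pos  # reference coordinate of next consumed base
    cigar = read.cigar
    for idx, (length, op) in enumerate(cigar):
        if op == "N":
            if ref == skip_start and ref + length - 1 == skip_end:
                left = _aligned_run(cigar, idx, direction=-1)
                right = _aligned_run(cigar, idx, direction=+1)
                if left >= min_overhang and right >= min_overhang:
                    return True
        if op in REF_CONSUMING:
            ref += length
    return False


def _aligned_run(cigar: Sequence[tuple[int, str]], n_idx: int, direction: int) -> int:
    """Contiguous aligned reference coverage adjacent to the N at ``n_idx``.

    Ops that consume no reference (I, P) are transparent; any other
    non-aligned op terminates the run.
    """
    total = 0
    i = n_idx + direction
    while 0 <= i < len(cigar):
        length, op = cigar[i]
        if op in ALIGNED_OPS:
            total += length
        elif op not in {"I", "P"}:
            break
        i += direction
    return total


def count_junction_reads(
    reads: Iterable[SplicedRead],
    model: TranscriptModel,
    *,
    min_overhang: int = 6,
    positivity_threshold: int = 1,
) -> list[JunctionCount]:
    """Count junction-spanning reads for every signature in the model.

    Refuses to run on a model with colliding signatures (ambiguous
    assignment).  Each read is assigned to at most one signature; with
    unique junctions and exact matching a single skip can match only one,
    and a multi-skip read is credited to the first signature it supports
    in model order.
    """
    report = validate_signatures(model)
    if not report.ok:
        raise SignatureCollisionError(
            f"cannot count with ambiguous signatures: {report.collisions}"
        )
    reads = list(reads)
    total = len(reads)
    counts = {sig.transcript_id: 0 for sig in model.signatures}
    for read in reads:
        for sig in model.signatures:
            if read_spans_junction(read, sig, min_overhang):
                counts[sig.transcript_id] += 1
                break
    return [
        JunctionCount(
            transcript_id=tid,
            spanning_reads=n,
            total_reads_screened=total,
            positive=n >= positivity_threshold,
        )
        for tid, n in counts.items()
    ]


def write_counts_table(counts: Sequence[JunctionCount], path: str | Path) -> None:
    """Write counts as a tab-separated table."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tspanning_reads\ttotal_reads_screened\tpositive\n")
        for c in counts:
            fh.write(
                f"{c.transcript_id}\t{c.spanning_reads}\t"
                f"{c.total_reads_screened}\t{str(c.positive).lower()}\n"
            )


def counts_to_json(counts: Sequence[JunctionCount]) -> str:
    return json.dumps(
        {
            c.transcript_id: {
                "spanning_reads": c.spanning_reads,
                "total_reads_screened": c.total_reads_screened,
                "positive": c.positive,
            }
            for c in counts
        },
        indent=2,
        sort_keys=True,
    )
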