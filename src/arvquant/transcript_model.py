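"""Exon models and discriminating splice-junction signatures for AR transcripts.

The full-length androgen receptor (AR-FL) and its two clinically relevant
splice variants are distinguished by a single exon--exon junction each:

* **AR-FL** -- exon 7 spliced to exon 8 (present only in the full-length
  message);
* **AR-V7** -- exon 3 spliced to cryptic exon 3 (CE3), which truncates the
  ligand-binding domain;
* **AR-v567es** -- exon 4 spliced directly to exon 8, skipping exons 5-7.

A junction signature is the ordered pair ``(donor_end, acceptor_start)`` of
genomic coordinates: the last base of the donor exon and the first base of
the acceptor exon, both 1-based inclusive.  A spliced alignment supports a
transcript when its skipped segment bridges exactly that pair.  Signatures
must therefore be unique within a model; two identical pairs would make
read assignment ambiguous (the situation that arises between AR-V7 and
AR-V9, which share their terminal cryptic-exon sequence).

The shipped default model lives on a single synthetic contig with toy
coordinates so that the whole pipeline runs without reference downloads;
real (e.g. hg38) coordinates are supplied through :func:`load_model`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

#: Name of the synthetic contig used by the default toy model.
TOY_CONTIG = "AR_toy"
#: Length of the synthetic contig (bases).
TOY_CONTIG_LENGTH = 2000

_MODEL_COLUMNS = (
    "transcript_id",
    "donor_exon",
    "acceptor_exon",
    "donor_end",
    "acceptor_start",
    "chrom",
    "strand",
)


class ModelError(ValueError):
    """Raised for malformed or self-inconsistent transcript models."""


class SignatureCollisionError(ModelError):
    """Two junction signatures share the same (donor_end, acceptor_start)."""


@dataclass(frozen=True)
class Exon:
    """One exon, 1-based inclusive genomic coordinates."""

    exon_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelError(f"exon {self.exon_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ModelError(f"exon {self.exon_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class JunctionSignature:
    """The donor/acceptor coordinate pair that uniquely identifies one transcript.

    ``donor_end`` is the last base of the upstream exon and ``acceptor_start``
    the first base of the downstream exon (1-based, plus-strand orientation).
    The skipped intronic interval is ``[donor_end + 1, acceptor_start - 1]``.
    """

    transcript_id: str
    donor_exon: str
    acceptor_exon: str
    donor_end: int
    acceptor_start: int
    chrom: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ModelError(
                f"{self.transcript_id}: donor_end {self.donor_end} must precede "
                f"acceptor_start {self.acceptor_start}"
            )

    @property
    def junction(self) -> tuple[int, int]:
        return (self.donor_end, self.acceptor_start)

    @property
    def intron_length(self) -> int:
        """Length of the skipped reference interval."""
        return self.acceptor_start - self.donor_end - 1


@dataclass
class TranscriptModel:
    """Container pairing an exon catalogue with its junction signatures."""

    exons: list[Exon] = field(default_factory=list)
    signatures: list[JunctionSignature] = field(default_factory=list)

    def __post_init__(self) -> None:
        exon_ids = {e.exon_id for e in self.exons}
        for sig in self.signatures:
            for eid in (sig.donor_exon, sig.acceptor_exon):
                if exon_ids and eid not in exon_ids:
                    raise ModelError(
                        f"signature {sig.transcript_id} references unknown exon {eid!r}"
                    )

    def exon(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.exon_id == exon_id:
                return e
        raise KeyError(exon_id)

    def signature(self, transcript_id: str) -> JunctionSignature:
        for s in self.signatures:
            if s.transcript_id == transcript_id:
                return s
        raise KeyError(transcript_id)

    @property
    def transcript_ids(self) -> list[str]:
        return [s.transcript_id for s in self.signatures]


def build_toy_ar_model() -> TranscriptModel:
    """Build the default AR model on a synthetic contig.

    Nine exons (E1-E8 plus cryptic exon CE3) of 100 bp each, separated by
    100-bp introns on the plus strand of ``AR_toy``, and the three
    discriminating signatures:

    ========== ============ ============== =================
    transcript donor exon   acceptor exon  junction
    ========== ============ ============== =================
    AR-FL      E7           E8             (1600, 1701)
    AR-V7      E3           CE3            (600, 701)
    AR-v567es  E4           E8             (1000, 1701)
    ========== ============ ============== =================

    The coordinates are synthetic by design; supply real genome coordinates
    through :func:`load_model` for use on actual alignments.
    """
    order = ["E1", "E2", "E3", "CE3", "E4", "E5", "E6", "E7", "E8"]
    exons = []
    for i, eid in enumerate(order):
        start = 101 + 200 * i
        exons.append(Exon(eid, TOY_CONTIG, start, start + 99, "+"))
    by_id = {e.exon_id: e for e in exons}
    signatures = [
        JunctionSignature("AR-FL", "E7", "E8", by_id["E7"].end, by_id["E8"].start, TOY_CONTIG),
        JunctionSignature("AR-V7", "E3", "CE3", by_id["E3"].end, by_id["CE3"].start, TOY_CONTIG),
        JunctionSignature(
            "AR-v567es", "E4", "E8", by_id["E4"].end, by_id["E8"].start, TOY_CONTIG
        ),
    ]
    model = TranscriptModel(exons=exons, signatures=signatures)
    report = validate_signatures(model)
    assert not report.collisions  # toy model is collision-free by construction
    return model


@dataclass
class ValidationReport:
    """Result of signature-uniqueness validation.

    ``collisions`` lists groups of transcript ids that share an identical
    ``(donor_end, acceptor_start)`` junction and therefore cannot be told
    apart by junction-spanning reads.
    """

    collisions: list[tuple[tuple[int, int], list[str]]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.collisions


def validate_signatures(model: TranscriptModel) -> ValidationReport:
    """Report any pair of signatures with identical junction coordinates."""
    seen: dict[tuple[str, int, int], list[str]] = {}
    for sig in model.signatures:
        seen.setdefault((sig.chrom, *sig.junction), []).append(sig.transcript_id)
    collisions = [
        ((key[1], key[2]), ids) for key, ids in seen.items() if len(ids) > 1
    ]
    return ValidationReport(collisions=collisions)


def load_model(path: str | Path) -> TranscriptModel:
    """Load a transcript model from a tab-separated junction-definition file.

    Expected columns (one header line):
    ``transcript_id  donor_exon  acceptor_exon  donor_end  acceptor_start
    chrom  strand``.  Minus-strand rows are normalised at load time so that
    ``donor_end < acceptor_start`` internally.  Exon records are synthesised
    from the junction coordinates (a junction file does not carry full exon
    extents; only the boundary bases matter for counting).

    Raises :class:`ModelError` naming the offending line for malformed rows
    and :class:`SignatureCollisionError` for duplicate junctions.
    """
    path = Path(path)
    signatures: list[JunctionSignature] = []
    exons: dict[str, Exon] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            logger.warning("empty junction-definition file %s: zero signatures", path)
            return TranscriptModel()
        cols = header.rstrip("\n").split("\t")
        if tuple(cols) != _MODEL_COLUMNS:
            raise ModelError(
                f"{path}:1: expected header {list(_MODEL_COLUMNS)}, got {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_MODEL_COLUMNS):
                raise ModelError(
                    f"{path}:{lineno}: expected {len(_MODEL_COLUMNS)} fields, "
                    f"got {len(parts)}"
                )
            tid, donor, acceptor, d_end, a_start, chrom, strand = parts
            try:
                d_end_i, a_start_i = int(d_end), int(a_start)
            except ValueError as exc:
                raise ModelError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand == "-":
                # normalise to the canonical plus-strand orientation
                d_end_i, a_start_i = min(d_end_i, a_start_i), max(d_end_i, a_start_i)
                donor, acceptor = acceptor, donor
            try:
                sig = JunctionSignature(tid, donor, acceptor, d_end_i, a_start_i, chrom)
            except ModelError as exc:
                raise ModelError(f"{path}:{lineno}: {exc}") from exc
            signatures.append(sig)
            for eid, s, e in ((donor, d_end_i, d_end_i), (acceptor, a_start_i, a_start_i)):
                if eid not in exons:
                    exons[eid] = Exon(eid, chrom, s, e)
    model = TranscriptModel(exons=list(exons.values()), signatures=signatures)
    report = validate_signatures(model)
    if not report.ok:
        raise SignatureCollisionError(
            f"{path}: duplicate junction coordinates: {report.collisions}"
        )
    return model


def save_model(model: TranscriptModel, path: str | Path) -> None:
    """Write signatures as a junction-definition file (round-trips with load_model)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_MODEL_COLUMNS) + "\n")
        for s in model.signatures:
            fh.write(
                "\t".join(
                    [
                        s.transcript_id,
                        s.donor_exon,
                        s.acceptor_exon,
                        str(s.donor_end),
                        str(s.acceptor_start),
                        s.chrom,
                        s.strand,
                    ]
                )
                + "\n"
            )


def iter_signatures(model: TranscriptModel) -> Iterable[JunctionSignature]:
    return iter(model.signatures)
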