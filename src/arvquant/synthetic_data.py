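"""Synthetic generators for droplets, spliced reads, and patient cohorts.

Everything downstream of wet-lab and alignment is testable against these
generators because each one emits its ground truth alongside the data:

* :func:`simulate_droplets` -- Poisson template loading at a true
  concentration with bimodal Gaussian amplitudes and optional "rain"
  (intermediate-amplitude droplets);
* :func:`simulate_spliced_reads` -- SAM text over the toy AR contig whose
  junction reads have the exact ``aM kN bM`` structure the counter looks
  for, plus unspliced background reads;
* :func:`simulate_random_reads` -- adversarial reads with randomly
  perturbed skips and anchors, for oracle-equivalence testing;
* :func:`simulate_cohort` -- per-subject transcript copies with
  configurable prevalence and log-normal expression in positives.

All generators draw from a single numpy Generator seeded explicitly, so a
fixed seed reproduces output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_stats import TRANSCRIPTS, PatientRecord
from .transcript_model import TOY_CONTIG, TOY_CONTIG_LENGTH, TranscriptModel


class SimConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Droplets
# ---------------------------------------------------------------------------

@dataclass
class DropletSimConfig:
    """Droplet generation parameters.

    ``lambda_true`` is the mean template copies per droplet; amplitudes are
    Normal(mu_pos, sigma) for template-bearing droplets and
    Normal(mu_neg, sigma) otherwise.  ``rain_fraction`` of the
    *template-bearing* droplets get an amplitude drawn uniformly between
    the two modes instead, emulating partially amplified "rain" droplets
    that challenge thresholding.  (Rain physically originates from delayed
    or partial amplification of template-containing droplets; drawing it
    from the positive class keeps the generator's truth labels meaningful.)
    """

    lambda_true: float = 0.3
    n_droplets: int = 15_000
    mu_neg: float = 1000.0
    mu_pos: float = 8000.0
    sigma: float = 300.0
    rain_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_true < 0:
            raise SimConfigError("lambda_true must be >= 0")
        if self.n_droplets < 1:
            raise SimConfigError("n_droplets must be >= 1")
        if not self.mu_neg < self.mu_pos:
            raise SimConfigError("mu_neg must be < mu_pos")
        if not 0 <= self.rain_fraction < 0.2:
            raise SimConfigError("rain_fraction must be in [0, 0.2)")


def simulate_droplets(
    config: DropletSimConfig, well_id: str = "A01", channel: str = "target"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one well of droplets.

    Returns ``(table, truth)``: a droplet table with columns
    ``well_id, channel, amplitude`` and a boolean array marking the
    droplets that truly contain template (count >= 1).
    """
    rng = np.random.default_rng(config.seed)
    counts = rng.poisson(config.lambda_true, size=config.n_droplets)
    truth = counts >= 1
    mu = np.where(truth, config.mu_pos, config.mu_neg)
    amplitudes = rng.normal(mu, config.sigma)
    if config.rain_fraction > 0:
        is_rain = truth & (rng.random(config.n_droplets) < config.rain_fraction)
        amplitudes[is_rain] = rng.uniform(
            config.mu_neg, config.mu_pos, size=int(is_rain.sum())
        )
    table = pd.DataFrame(
        {
            "well_id": well_id,
            "channel": channel,
            "amplitude": amplitudes,
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# Spliced reads (SAM text)
# ---------------------------------------------------------------------------

_BASE_PATTERN = "ACGT"


def _filler_seq(length: int) -> str:
    reps = (_BASE_PATTERN * (length // 4 + 1))[:length]
    return reps


def _sam_header(model: TranscriptModel) -> str:
    chroms = {e.chrom for e in model.exons} | {s.chrom for s in model.signatures}
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chroms):
        length = TOY_CONTIG_LENGTH if chrom == TOY_CONTIG else 1_000_000
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    return "\n".join(lines) + "\n"


def _sam_record(read_id: str, chrom: str, pos: int, cigar_str: str, seq_len: int) -> str:
    seq = _filler_seq(seq_len)
    qual = "I" * seq_len
    return (
        f"{read_id}\t0\t{chrom}\t{pos}\t60\t{cigar_str}\t*\t0\t0\t{seq}\t{qual}\n"
    )


def simulate_spliced_reads(
    model: TranscriptModel,
    mixture: dict[str, int],
    *,
    read_len: int = 50,
    anchor_range: tuple[int, int] = (6, 25),
    n_background: int = 0,
    seed: int = 0,
) -> tuple[str, dict[str, int]]:
    """Generate SAM text with junction-spanning reads per the mixture.

    For each requested read of transcript *t* the record has CIGAR
    ``aM kN bM`` where ``a, b`` are drawn uniformly from ``anchor_range``
    and ``k`` is the intron length of *t*'s signature, placed so the skip
    covers exactly the signature's intronic interval.  ``n_background``
    unspliced ``read_len M`` reads are added at random positions.  Read
    bases are a fixed filler pattern; junction counting never inspects them.

    Returns ``(sam_text, truth_counts)``.
    """
    if read_len < 2:
        raise SimConfigError("read_len must be >= 2")
    lo, hi = anchor_range
    if lo < 1 or hi < lo:
        raise SimConfigError("anchor_range must satisfy 1 <= lo <= hi")
    for tid in mixture:
        model.signature(tid)  # KeyError on unknown transcript
    rng = np.random.default_rng(seed)
    out = [_sam_header(model)]
    truth = {sig.transcript_id: 0 for sig in model.signatures}
    serial = 0
    for tid, n_reads in mixture.items():
        sig = model.signature(tid)
        k = sig.intron_length
        for _ in range(n_reads):
            a = int(rng.integers(lo, hi + 1))
            b = int(rng.integers(lo, hi + 1))
            pos = sig.donor_end - a + 1
            cigar = f"{a}M{k}N{b}M"
            serial += 1
            out.append(_sam_record(f"jr{serial}_{tid}", sig.chrom, pos, cigar, a + b))
        truth[tid] = truth.get(tid, 0) + n_reads
    for _ in range(n_background):
        pos = int(rng.integers(1, TOY_CONTIG_LENGTH - read_len + 2))
        serial += 1
        out.append(
            _sam_record(f"bg{serial}", TOY_CONTIG, pos, f"{read_len}M", read_len)
        )
    return "".join(out), truth


def simulate_random_reads(
    model: TranscriptModel, n_reads: int, *, seed: int = 0
) -> str:
    """Adversarial random reads for stress-testing the junction counter.

    Each read is anchored near a randomly chosen signature with randomly
    perturbed skip start/length (so some match a junction exactly, many
    miss by a few bases), random anchor lengths above and below typical
    overhang thresholds, optional soft-clips, and occasional extra
    insertions/deletions next to the skip.  A quarter of reads are plain
    unspliced matches.  Returns SAM text.
    """
    rng = np.random.default_rng(seed)
    out = [_sam_header(model)]
    sigs = list(model.signatures)
    for i in range(n_reads):
        kind = rng.random()
        if kind < 0.25 or not sigs:
            pos = int(rng.integers(1, TOY_CONTIG_LENGTH - 50))
            out.append(_sam_record(f"rnd{i}", TOY_CONTIG, pos, "50M", 50))
            continue
        sig = sigs[int(rng.integers(len(sigs)))]
        a = int(rng.integers(1, 15))
        b = int(rng.integers(1, 15))
        skip_shift = int(rng.integers(-2, 3))  # 0 => exact junction
        k = sig.intron_length + int(rng.integers(-2, 3))
        k = max(1, k)
        pos = sig.donor_end - a + 1 + skip_shift
        pos = max(1, pos)
        parts = []
        seq_len = a + b
        if rng.random() < 0.2:
            clip = int(rng.integers(1, 5))
            parts.append(f"{clip}S")
            seq_len += clip
        parts.append(f"{a}M")
        if rng.random() < 0.15:
            ins = int(rng.integers(1, 4))
            parts.append(f"{ins}I")
            seq_len += ins
        parts.append(f"{k}N")
        if rng.random() < 0.15:
            dele = int(rng.integers(1, 4))
            parts.append(f"{dele}D")
        parts.append(f"{b}M")
        out.append(_sam_record(f"rnd{i}", sig.chrom, pos, "".join(parts), seq_len))
    return "".join(out)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Cohort generation parameters.

    ``prevalence`` maps transcript -> probability a subject expresses it;
    ``lognormal_params`` maps transcript -> (mu, sigma) of the natural-log
    expression distribution for positive subjects.  Defaults emulate a
    metastatic castration-resistant prostate cancer CTC cohort: prevalences
    0.90 / 0.66 / 0.52 for AR-FL / AR-V7 / AR-v567es and log-normal
    expression centred near the published medians (about 10, 2 and 0.3
    copies/sample) with a heavy right tail.
    """

    n_subjects: int = 29
    prevalence: dict[str, float] = field(
        default_factory=lambda: {"AR-FL": 0.90, "AR-V7": 0.66, "AR-v567es": 0.52}
    )
    lognormal_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "AR-FL": (math.log(10.0), 1.5),
            "AR-V7": (math.log(2.0), 1.5),
            "AR-v567es": (math.log(0.3), 1.5),
        }
    )
    disease_group: str = "mCRPC"
    unit: str = "bulk_CTC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SimConfigError("n_subjects must be >= 1")
        for tid, p in self.prevalence.items():
            if not 0 <= p <= 1:
                raise SimConfigError(f"prevalence for {tid} outside [0, 1]")


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[list[PatientRecord], dict[str, float]]:
    """Simulate per-subject transcript copies.

    Each subject is positive for each transcript independently with its
    prevalence probability; positive copies are log-normal, negatives are
    exactly 0.  Returns ``(records, truth_prevalence)`` where the truth is
    the realised (not nominal) positive fraction per transcript.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    realised = {tid: 0 for tid in config.prevalence}
    for i in range(config.n_subjects):
        copies: dict[str, float | None] = {}
        for tid, pi in config.prevalence.items():
            if rng.random() < pi:
                mu, sigma = config.lognormal_params.get(tid, (0.0, 1.0))
                copies[tid] = float(rng.lognormal(mu, sigma))
                realised[tid] += 1
            else:
                copies[tid] = 0.0
        records.append(
            PatientRecord(
                subject_id=f"P{i + 1:03d}",
                disease_group=config.disease_group,
                unit=config.unit,
                copies=copies,
            )
        )
    truth = {tid: n / config.n_subjects for tid, n in realised.items()}
    return records, truth


# ---------------------------------------------------------------------------
# Reference-style fixed cohorts (synthetic stand-ins)
# ---------------------------------------------------------------------------

def synthetic_mcrpc_reference_cohort() -> list[PatientRecord]:
    """Synthetic 29-subject mCRPC cohort matching published summary marginals.

    This is a *synthetic stand-in*: the per-patient source data behind the
    published cohort summary are not redistributed here, so this constructor
    builds one explicit 29-subject cohort whose per-transcript marginals --
    positives out of 29, median, mean, and range of copies/sample -- equal
    the published Table-1 values (26/29, 19/29, 15/29 positive; medians
    8.5 / 1.3 / 0.14; means 28.74 / 5.24 / 1.49; maxima 280 / 70 / 8.4).
    Individual values are NOT real measurements; only the marginals are
    meaningful.
    """
    spec = {
        "AR-FL": (26, 8.5, 28.74, 280.0),
        "AR-V7": (19, 1.3, 5.24, 70.0),
        "AR-v567es": (15, 0.14, 1.49, 8.4),
    }
    n = 29
    columns = {
        tid: _marginal_matched_values(n, n_pos, median, mean, vmax)
        for tid, (n_pos, median, mean, vmax) in spec.items()
    }
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                subject_id=f"S{i + 1:03d}",
                disease_group="mCRPC",
                unit="bulk_CTC",
                copies={tid: columns[tid][i] for tid in spec},
            )
        )
    return records


def _marginal_matched_values(
    n: int, n_pos: int, median: float, mean: float, vmax: float
) -> list[float]:
    """One sorted value vector with exactly the requested marginals.

    Works for odd n with n_pos <= n and median attainable given the zero
    count; raises if the marginals are mutually inconsistent.
    """
    if n % 2 != 1:
        raise SimConfigError("marginal matching implemented for odd n")
    n_zero = n - n_pos
    mid = n // 2
    if n_zero > mid:
        raise SimConfigError("too many zeros for a positive median")
    k_low = mid - n_zero  # positives strictly below the median slot
    k_high = n - mid - 2  # positives between median and the maximum
    total = mean * n
    low_val = median / 2.0 if k_low else 0.0
    remaining = total - (low_val * k_low + median + vmax)
    if k_high:
        high_val = remaining / k_high
        if not median <= high_val <= vmax:
            raise SimConfigError("marginals are mutually inconsistent")
    else:
        high_val = None
        if abs(remaining) > 1e-9:
            raise SimConfigError("marginals are mutually inconsistent")
    values = (
        [0.0] * n_zero
        + [low_val] * k_low
        + [median]
        + ([high_val] * k_high if high_val is not None else [])
        + [vmax]
    )
    assert len(values) == n
    return values


def synthetic_epcam_fraction_cohort() -> list[PatientRecord]:
    """Synthetic EpCAM-fraction records matching published positivity patterns.

    Ten subjects with matched EpCAM-positive and EpCAM-negative CTC pools;
    positivity patterns per transcript equal the published counts (AR-FL
    8/10 vs 10/10, AR-V7 6/10 vs 9/10, AR-v567es 2/10 vs 6/10 in the
    positive vs negative fraction).  Copies values for positives are
    nominal placeholders; only the positivity pattern is meaningful.
    """
    patterns = {
        "pos": {"AR-FL": 8, "AR-V7": 6, "AR-v567es": 2},
        "neg": {"AR-FL": 10, "AR-V7": 9, "AR-v567es": 6},
    }
    records = []
    for status, per_transcript in patterns.items():
        for i in range(10):
            copies = {
                tid: (5.0 if i < n_pos else 0.0)
                for tid, n_pos in per_transcript.items()
            }
            records.append(
                PatientRecord(
                    subject_id=f"E{i + 1:02d}",
                    disease_group="mCRPC",
                    unit="CTC_pool",
                    epcam_status=status,
                    copies=copies,
                )
            )
    return records
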