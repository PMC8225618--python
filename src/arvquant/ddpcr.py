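"""Droplet digital PCR absolute quantification and assay QC.

A ddPCR reaction is partitioned into tens of thousands of droplets of
nominally identical volume.  Template molecules distribute over droplets
approximately as a Poisson process, so the fraction of *negative* droplets
estimates the zero-class probability and the mean copies per droplet is

    lambda_hat = -ln(1 - n_pos / n_total) = -ln(n_neg / n_total)

which converts to an absolute concentration

    conc [copies/uL] = lambda_hat * 1000 / droplet_volume_nl.

The default droplet volume is 0.85 nL (Bio-Rad QX200 nominal partition
volume); every threshold and volume here is configurable.

Assay repeatability (intra-assay) and reproducibility (inter-assay) are
summarised by the coefficient of variation CV% = 100 * SD / mean of the
replicate concentrations, with the sample (n-1) standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

#: QX200 nominal droplet volume, nanolitres.
DEFAULT_DROPLET_VOLUME_NL = 0.85
#: Wells with fewer accepted droplets than this are flagged LOW_DROPLETS.
DEFAULT_MIN_DROPLETS = 10_000
#: Positive droplets tolerated in a no-template control well.
DEFAULT_NTC_TOLERANCE = 2


class QuantError(ValueError):
    """Domain error in droplet quantification inputs."""


@dataclass(frozen=True)
class DropletRecord:
    well_id: str
    channel: str
    amplitude: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.amplitude):
            raise QuantError(f"{self.well_id}: non-finite amplitude")


@dataclass
class WellQuantification:
    """Absolute quantification for one well/target."""

    well_id: str
    target: str
    n_total: int
    n_pos: int
    lambda_hat: float
    conc_per_ul: float
    copies_per_reaction: float
    copies_per_sample: float
    flags: set[str] = field(default_factory=set)


@dataclass
class ReplicateSet:
    """Replicate concentrations with their repeatability summary."""

    label: Literal["intra", "inter"]
    values: tuple[float, ...]
    mean: float
    sd: float
    cv_percent: float
    flags: set[str] = field(default_factory=set)


def otsu_threshold(amplitudes: np.ndarray) -> float:
    """Two-class amplitude threshold: midpoint of the cluster centres of the
    1-D two-class partition minimising within-class variance.

    Equivalent to exhaustive 1-D k-means over the sorted sample: every split
    point is evaluated with prefix sums and the best split's class means are
    averaged.  Degenerate (constant) input returns that constant, so every
    droplet classifies as negative (amplitude must *exceed* the threshold).
    """
    x = np.sort(np.asarray(amplitudes, dtype=float))
    n = x.size
    if n == 0:
        raise QuantError("cannot threshold zero droplets")
    if x[0] == x[-1]:
        return float(x[0])
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)  # size of the lower class
    lower_mean = csum[:-1] / k
    upper_mean = (csum[-1] - csum[:-1]) / (n - k)
    # within-class sum of squares for each split
    wss = (
        csq[:-1]
        - k * lower_mean**2
        + (csq[-1] - csq[:-1])
        - (n - k) * upper_mean**2
    )
    best = int(np.argmin(wss))
    return float((lower_mean[best] + upper_mean[best]) / 2.0)


def classify_droplets(
    amplitudes: Iterable[float] | np.ndarray,
    threshold: float | Literal["auto"] = "auto",
) -> tuple[int, int, int]:
    """Split droplets into positive/negative by amplitude.

    Returns ``(n_pos, n_neg, n_total)``; a droplet is positive when its
    amplitude is strictly above the threshold.  ``"auto"`` derives the
    threshold with :func:`otsu_threshold`.
    """
    x = np.asarray(list(amplitudes) if not isinstance(amplitudes, np.ndarray) else amplitudes, dtype=float)
    if x.size == 0:
        raise QuantError("cannot classify zero droplets")
    thr = otsu_threshold(x) if threshold == "auto" else float(threshold)
    n_pos = int(np.count_nonzero(x > thr))
    return n_pos, x.size - n_pos, x.size


def poisson_concentration(
    n_pos: int,
    n_total: int,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> tuple[float, float, set[str]]:
    """Poisson estimate of copies per droplet and concentration per microlitre.

    Returns ``(lambda_hat, conc_per_ul, flags)``.  A saturated well (all
    droplets positive) has no finite estimate: both values are ``inf`` and
    the ``SATURATED`` flag is set.
    """
    if not 0 <= n_pos <= n_total:
        raise QuantError(f"n_pos={n_pos} outside [0, n_total={n_total}]")
    if n_total < 1:
        raise QuantError("n_total must be >= 1")
    if droplet_volume_nl <= 0:
        raise QuantError("droplet volume must be positive")
    flags: set[str] = set()
    if n_pos == n_total:
        flags.add("SATURATED")
        return math.inf, math.inf, flags
    lam = -math.log1p(-n_pos / n_total)
    conc = lam * 1000.0 / droplet_volume_nl
    return lam, conc, flags


def copies_per_sample(
    conc_per_ul: float,
    reaction_volume_ul: float = 22.0,
    sample_fraction_loaded: float = 1.0,
) -> tuple[float, float]:
    """Scale a concentration to copies per reaction and per original sample.

    ``sample_fraction_loaded`` is the fraction of the extracted sample that
    went into the reaction; dividing by it back-calculates the total sample
    content.  The 22-uL default matches a one-step RT-ddPCR reaction loaded
    with 11 uL of sample RNA.
    """
    if reaction_volume_ul <= 0:
        raise QuantError("reaction volume must be positive")
    if not 0 < sample_fraction_loaded <= 1:
        raise QuantError("sample_fraction_loaded must be in (0, 1]")
    per_reaction = conc_per_ul * reaction_volume_ul
    return per_reaction, per_reaction / sample_fraction_loaded


def quantify_well(
    amplitudes: Iterable[float] | np.ndarray,
    *,
    well_id: str = "well",
    target: str = "target",
    threshold: float | Literal["auto"] = "auto",
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    reaction_volume_ul: float = 22.0,
    sample_fraction_loaded: float = 1.0,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    normalization_divisor: float | None = None,
) -> WellQuantification:
    """Classify, estimate and scale one well end to end.

    ``normalization_divisor`` optionally divides copies/sample by an
    experiment-specific denominator (number of CTCs in a pool, nanograms of
    input RNA, or a reference-target ratio); the default applies none.
    """
    n_pos, _, n_total = classify_droplets(amplitudes, threshold)
    lam, conc, flags = poisson_concentration(n_pos, n_total, droplet_volume_nl)
    if n_total < min_droplets:
        flags.add("LOW_DROPLETS")
    if math.isinf(conc):
        per_rxn = per_sample = math.inf
    else:
        per_rxn, per_sample = copies_per_sample(
            conc, reaction_volume_ul, sample_fraction_loaded
        )
        if normalization_divisor is not None:
            if normalization_divisor <= 0:
                raise QuantError("normalization divisor must be positive")
            per_sample /= normalization_divisor
    return WellQuantification(
        well_id=well_id,
        target=target,
        n_total=n_total,
        n_pos=n_pos,
        lambda_hat=lam,
        conc_per_ul=conc,
        copies_per_reaction=per_rxn,
        copies_per_sample=per_sample,
        flags=flags,
    )


def quantify_plate(
    droplets: pd.DataFrame,
    layout: Mapping[str, Mapping[str, str]],
    *,
    threshold: float | Literal["auto"] = "auto",
    **well_kwargs,
) -> list[WellQuantification]:
    """Quantify every well of a droplet table.

    ``droplets`` needs columns ``well_id, channel, amplitude`` (QuantaSoft-
    style CSV export).  ``layout`` maps well id -> ``{"target": ..., "role":
    "sample"|"ntc"|"positive_control"}``; wells absent from the layout are
    quantified as samples with their well id as target.
    """
    required = {"well_id", "channel", "amplitude"}
    if not required.issubset(droplets.columns):
        raise QuantError(f"droplet table must have columns {sorted(required)}")
    out = []
    for well_id, grp in droplets.groupby("well_id", sort=True):
        meta = layout.get(well_id, {})
        out.append(
            quantify_well(
                grp["amplitude"].to_numpy(),
                well_id=str(well_id),
                target=meta.get("target", str(well_id)),
                threshold=threshold,
                **well_kwargs,
            )
        )
    return out


@dataclass
class PlateQCReport:
    """Outcome of plate-control checks."""

    passed: bool
    ntc_failures: list[str] = field(default_factory=list)
    control_failures: list[str] = field(default_factory=list)
    unreliable_wells: list[str] = field(default_factory=list)


def apply_plate_controls(
    wells: Sequence[WellQuantification],
    control_map: Mapping[str, str],
    *,
    ntc_tolerance: int = DEFAULT_NTC_TOLERANCE,
    required_positive_controls: Sequence[str] = (),
) -> PlateQCReport:
    """Check plate controls and flag sample wells on failed plates.

    ``control_map`` maps well id -> role, role in {"ntc",
    "positive_control"}.  An NTC well with more than ``ntc_tolerance``
    positive droplets fails the plate; a positive-control well with zero
    positive droplets is a control failure.  Sample wells on a failed plate
    are marked ``UNRELIABLE`` but still reported.

    ``required_positive_controls`` lists targets that must each have a
    positive-control well present; a missing one is a configuration error.
    """
    by_id = {w.well_id: w for w in wells}
    for well_id in control_map:
        if well_id not in by_id:
            raise QuantError(f"control well {well_id!r} missing from plate")
    pc_targets = {
        by_id[w].target for w, role in control_map.items() if role == "positive_control"
    }
    for target in required_positive_controls:
        if target not in pc_targets:
            raise QuantError(f"missing positive control for target {target!r}")

    ntc_failures, control_failures = [], []
    for well_id, role in control_map.items():
        w = by_id[well_id]
        if role == "ntc" and w.n_pos > ntc_tolerance:
            w.flags.add("NTC_FAIL")
            ntc_failures.append(well_id)
        elif role == "positive_control" and w.n_pos == 0:
            w.flags.add("CONTROL_FAIL")
            control_failures.append(well_id)
    passed = not ntc_failures and not control_failures
    unreliable = []
    if not passed:
        for w in wells:
            if w.well_id not in control_map:
                w.flags.add("UNRELIABLE")
                unreliable.append(w.well_id)
    return PlateQCReport(
        passed=passed,
        ntc_failures=ntc_failures,
        control_failures=control_failures,
        unreliable_wells=unreliable,
    )


def replicate_cv(
    values: Sequence[float], label: Literal["intra", "inter"] = "intra"
) -> ReplicateSet:
    """Coefficient of variation (SD/mean, sample SD) over replicate wells.

    A zero mean leaves the CV undefined (NaN) and sets the ``CV_UNDEFINED``
    flag rather than raising.
    """
    vals = tuple(float(v) for v in values)
    if len(vals) < 2:
        raise QuantError("replicate CV needs at least 2 values")
    arr = np.asarray(vals)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    flags: set[str] = set()
    if mean == 0:
        cv = math.nan
        flags.add("CV_UNDEFINED")
    else:
        cv = 100.0 * sd / mean
    return ReplicateSet(label=label, values=vals, mean=mean, sd=sd, cv_percent=cv, flags=flags)


def wells_to_frame(wells: Sequence[WellQuantification]) -> pd.DataFrame:
    """Tabulate well quantifications (one row per well)."""
    return pd.DataFrame(
        {
            "well_id": [w.well_id for w in wells],
            "target": [w.target for w in wells],
            "n_total": [w.n_total for w in wells],
            "n_pos": [w.n_pos for w in wells],
            "lambda_hat": [w.lambda_hat for w in wells],
            "conc_per_ul": [w.conc_per_ul for w in wells],
            "copies_per_reaction": [w.copies_per_reaction for w in wells],
            "copies_per_sample": [w.copies_per_sample for w in wells],
            "flags": [";".join(sorted(w.flags)) for w in wells],
        }
    )
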