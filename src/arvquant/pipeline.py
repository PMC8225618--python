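"""Stage orchestration: config-driven runs, a manifest, and a text report.

A run is described by one YAML/JSON config with optional stages executed in
order: ``simulate`` (droplets / reads / cohort), ``quantify`` (droplet
table -> per-well quantification), ``count`` (SAM -> junction counts), and
``cohort`` (cohort table -> summary statistics).  Every run writes a
manifest recording the config snapshot, input digests, seeds and output
paths, which fully determines a deterministic rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    CohortSummary,
    compare_epcam_fractions,
    load_cohort_csv,
    summarize_cohort,
)
from .ddpcr import apply_plate_controls, quantify_plate, wells_to_frame
from .junction_counting import count_junction_reads, parse_sam, write_counts_table
from .synthetic_data import (
    CohortSimConfig,
    DropletSimConfig,
    simulate_cohort,
    simulate_droplets,
    simulate_spliced_reads,
)
from .cohort_stats import records_to_frame
from .transcript_model import build_toy_ar_model, load_model

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunManifest:
    config: dict[str, Any]
    seed: int | None
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "input_digests": self.input_digests,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineConfigError(f"{path}: config must be a mapping")
    return cfg


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> RunManifest:
    """Execute the configured stages and write outputs plus a manifest.

    Raises :class:`PipelineConfigError` for missing inputs or schema
    mismatches before any stage runs partially.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    manifest = RunManifest(config=config, seed=seed, version=__version__)

    model = (
        load_model(config["junctions"]) if "junctions" in config else build_toy_ar_model()
    )

    sim_cfg = config.get("simulate", {})
    if "droplets" in sim_cfg:
        dcfg = DropletSimConfig(**{**sim_cfg["droplets"], "seed": sim_cfg["droplets"].get("seed", seed or 0)})
        table, _ = simulate_droplets(dcfg)
        path = outdir / "droplets.csv"
        table.to_csv(path, index=False)
        manifest.outputs.append(str(path))
        config.setdefault("quantify", {}).setdefault("droplets", str(path))
    if "reads" in sim_cfg:
        rcfg = dict(sim_cfg["reads"])
        rcfg.setdefault("seed", seed or 0)
        mixture = rcfg.pop("mixture")
        sam_text, _ = simulate_spliced_reads(model, mixture, **rcfg)
        path = outdir / "reads.sam"
        path.write_text(sam_text)
        manifest.outputs.append(str(path))
        config.setdefault("count", {}).setdefault("sam", str(path))
    if "cohort" in sim_cfg:
        ccfg = CohortSimConfig(**{**sim_cfg["cohort"], "seed": sim_cfg["cohort"].get("seed", seed or 0)})
        records, _ = simulate_cohort(ccfg)
        path = outdir / "cohort.csv"
        records_to_frame(records).to_csv(path, index=False)
        manifest.outputs.append(str(path))
        config.setdefault("cohort", {}).setdefault("input", str(path))

    results: dict[str, Any] = {}

    if "quantify" in config:
        qcfg = config["quantify"]
        droplet_path = Path(qcfg.get("droplets", ""))
        if not droplet_path.is_file():
            raise PipelineConfigError(
                f"quantify stage: droplet file {droplet_path} not found"
            )
        manifest.input_digests[str(droplet_path)] = _sha256(droplet_path)
        droplets = pd.read_csv(droplet_path)
        layout = qcfg.get("layout", {})
        wells = quantify_plate(
            droplets, layout, threshold=qcfg.get("threshold", "auto")
        )
        control_map = {
            w: meta["role"]
            for w, meta in layout.items()
            if meta.get("role") in {"ntc", "positive_control"}
        }
        qc = apply_plate_controls(wells, control_map) if control_map else None
        frame = wells_to_frame(wells)
        path = outdir / "wells.tsv"
        frame.to_csv(path, sep="\t", index=False)
        manifest.outputs.append(str(path))
        results["wells"] = frame
        results["qc"] = qc

    if "count" in config:
        ccfg = config["count"]
        sam_path = Path(ccfg.get("sam", ""))
        if not sam_path.is_file():
            raise PipelineConfigError(f"count stage: SAM file {sam_path} not found")
        manifest.input_digests[str(sam_path)] = _sha256(sam_path)
        reads = parse_sam(sam_path)
        counts = count_junction_reads(
            reads,
            model,
            min_overhang=ccfg.get("min_overhang", 6),
            positivity_threshold=ccfg.get("positivity_threshold", 1),
        )
        path = outdir / "junction_counts.tsv"
        write_counts_table(counts, path)
        manifest.outputs.append(str(path))
        results["counts"] = counts

    if "cohort" in config:
        hcfg = config["cohort"]
        cohort_path = Path(hcfg.get("input", ""))
        if not cohort_path.is_file():
            raise PipelineConfigError(
                f"cohort stage: input file {cohort_path} not found"
            )
        manifest.input_digests[str(cohort_path)] = _sha256(cohort_path)
        records = load_cohort_csv(cohort_path)
        summary = summarize_cohort(records, hcfg.get("threshold", 0.0))
        path = outdir / "cohort_summary.tsv"
        summary.to_frame().to_csv(path, sep="\t", index=False)
        manifest.outputs.append(str(path))
        results["summary"] = summary
        if hcfg.get("compare_epcam"):
            ep = compare_epcam_fractions(records, hcfg.get("threshold", 0.0))
            path = outdir / "epcam_comparison.tsv"
            ep.to_csv(path, sep="\t", index=False)
            manifest.outputs.append(str(path))
            results["epcam"] = ep

    report_path = outdir / "report.txt"
    report_path.write_text(render_report(results))
    manifest.outputs.append(str(report_path))
    manifest.write(outdir / "manifest.json")
    return manifest


def render_report(results: dict[str, Any]) -> str:
    """Deterministic plain-text summary of a run's outputs.

    Numbers are printed exactly as they appear in the tabular outputs so
    the report can be cross-checked mechanically against them.
    """
    lines = ["# arvquant run report", ""]
    if "wells" in results:
        lines.append("## ddPCR well quantification")
        lines.append(results["wells"].to_string(index=False))
        qc = results.get("qc")
        if qc is not None:
            lines.append("")
            lines.append(f"Plate QC: {'PASS' if qc.passed else 'FAIL'}")
            if qc.ntc_failures:
                lines.append(f"NTC_FAIL wells: {', '.join(qc.ntc_failures)}")
            if qc.control_failures:
                lines.append(
                    f"Positive-control failures: {', '.join(qc.control_failures)}"
                )
        lines.append("")
    if "counts" in results:
        lines.append("## Junction-spanning read counts")
        for c in results["counts"]:
            lines.append(
                f"{c.transcript_id}\t{c.spanning_reads}\t"
                f"{'positive' if c.positive else 'negative'}"
            )
        lines.append("")
    if "summary" in results:
        summary: CohortSummary = results["summary"]
        lines.append("## Cohort summary (copies/sample)")
        lines.append(summary.to_frame().to_string(index=False))
        lines.append("")
    if "epcam" in results:
        lines.append("## EpCAM-fraction comparison")
        lines.append(results["epcam"].to_string(index=False))
        lines.append("")
    return "\n".join(lines)
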