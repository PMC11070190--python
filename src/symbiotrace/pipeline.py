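"""Config-driven orchestration: simulate -> segment -> quantify -> transfer.

A run writes a self-contained directory: per-ROI quantification table
(quants.csv), activity classification (activity.json), transfer estimate
(transfer.json), a YAML manifest with the config hash and per-output
checksums, and a plain-text log. Reruns with the same config and seed are
bit-identical for every deterministic stage; one global seed fans out to
per-stage seeds through named seed sequences.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .isotope_quant import (
    ROIQuant,
    activity_summary,
    calibrate_natural_abundance,
    classify_enrichment,
    quantify_rois,
)
from .segmentation import (
    SegmentationError,
    SegmentationParams,
    extract_rois,
    segment_cell,
    segment_compartments,
)
from .sims_io import write_roi_table
from .synthetic_data import SimConfig, simulate_control_population, simulate_population
from .transfer_model import CellRecord, bootstrap_transfer, excess_enrichment

logger = logging.getLogger("symbiotrace")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    n_cells: int = 100
    n_controls: int = 30
    volume_ratio: float = 0.06
    n_bootstrap: int = 1000
    seed: int = 0
    simulate_only: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            for key in ("grid_size", "host_axes"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(**sim)
        if "seg" in d and isinstance(d["seg"], dict):
            d["seg"] = SegmentationParams(**d["seg"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def analyze_population(
    population,
    controls,
    seg: SegmentationParams,
) -> dict:
    """Segment and quantify labeled and control populations.

    Returns rois/quants per population plus 15N and 13C calibrations from
    the control ROIs. Cells whose segmentation fails are skipped with a log
    entry; quantification itself is deterministic.
    """

    def run(cells):
        all_rois, all_quants = [], []
        for image, truth in cells:
            try:
                cm = segment_cell(image, seg)
                mask = segment_compartments(image, cm, seg)
            except SegmentationError as exc:
                logger.warning("segmentation failed for %s: %s", truth.cell_id, exc)
                continue
            rois = extract_rois(mask, image.pixel_size, cell_id=truth.cell_id)
            quants = quantify_rois(image, rois)
            all_rois.extend(rois)
            all_quants.extend(quants)
        return all_rois, all_quants

    rois, quants = run(population)
    ctrl_rois, ctrl_quants = run(controls)
    cal15 = calibrate_natural_abundance(ctrl_quants, "15N")
    cal13 = calibrate_natural_abundance(ctrl_quants, "13C")
    for q in quants:
        q.enriched_15N = classify_enrichment(q, cal15)
        q.enriched_13C = classify_enrichment(q, cal13)
    return {
        "rois": rois,
        "quants": quants,
        "control_rois": ctrl_rois,
        "control_quants": ctrl_quants,
        "cal15": cal15,
        "cal13": cal13,
    }


def cell_records_from_quants(quants: list[ROIQuant], cal15) -> list[CellRecord]:
    """Paired per-cell excess enrichments from classified ROI quants.

    Counts are pooled per cell and compartment; only cells with both a
    diazoplast and a host(N) measurement (the paired subset) are returned.
    """
    from .isotope_quant import _pool_cell_quant

    by_cell: dict[str, dict[str, list[ROIQuant]]] = {}
    for q in quants:
        by_cell.setdefault(q.cell_id, {}).setdefault(q.compartment, []).append(q)
    records = []
    for cell_id, comps in sorted(by_cell.items()):
        d = _pool_cell_quant(comps.get("diazoplast", []), "15N")
        h = _pool_cell_quant(comps.get("host_N", []), "15N")
        if d is None or h is None:
            continue
        if math.isnan(d.atom15N_pct) or math.isnan(h.atom15N_pct):
            continue
        records.append(
            CellRecord(
                cell_id,
                excess_enrichment(d.atom15N_pct, cal15),
                excess_enrichment(h.atom15N_pct, cal15),
            )
        )
    return records


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages and write the run directory.

    Outputs: quants.csv (per-ROI table, labeled population), controls.csv,
    activity.json, transfer.json, manifest.yaml, run.log. Returns the
    in-memory results keyed by stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S")
    )
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
    }
    t0 = time.time()
    results: dict = {}
    try:
        sim = dataclasses.replace(config.sim, seed=_stage_seed(config.seed, "simulate"))
        population = simulate_population(sim, config.n_cells)
        ctrl_sim = dataclasses.replace(
            config.sim, seed=_stage_seed(config.seed, "controls")
        )
        controls = simulate_control_population(ctrl_sim, config.n_controls)
        results["population"] = population
        results["controls"] = controls
        manifest["stages"]["simulate"] = {
            "n_cells": config.n_cells,
            "n_controls": config.n_controls,
            "true_active": sum(t.active for _, t in population),
        }
        logger.info("simulated %d cells, %d controls", config.n_cells, config.n_controls)
        if config.simulate_only:
            return _finish(manifest, outdir, t0, results)

        analysis = analyze_population(population, controls, config.seg)
        results["analysis"] = analysis
        write_roi_table(analysis["rois"], analysis["quants"], outdir / "quants.csv")
        write_roi_table(
            analysis["control_rois"],
            analysis["control_quants"],
            outdir / "controls.csv",
        )
        manifest["stages"]["quantify"] = {
            "n_rois": len(analysis["rois"]),
            "cal15_mean_pct": analysis["cal15"].mean_pct,
            "cal15_threshold_pct": analysis["cal15"].threshold_pct,
            "cal13_mean_pct": analysis["cal13"].mean_pct,
            "cal13_threshold_pct": analysis["cal13"].threshold_pct,
        }

        summary = activity_summary(
            analysis["quants"], analysis["cal15"], analysis["cal13"]
        )
        results["activity"] = summary
        (outdir / "activity.json").write_text(
            json.dumps(
                {
                    "n_cells": summary.n_cells,
                    "n_with_diazoplast": summary.n_with_diazoplast,
                    "frac_active_15N": summary.frac_active_15N,
                    "ci_active_15N": summary.ci_active_15N,
                    "frac_fixing_13C": summary.frac_fixing_13C,
                    "ci_fixing_13C": summary.ci_fixing_13C,
                    "co_table": summary.co_table.to_dict(),
                },
                indent=2,
                default=str,
            )
        )

        records = cell_records_from_quants(analysis["quants"], analysis["cal15"])
        active_records = [r for r in records if r.x_d > 3 * analysis["cal15"].sd_pct / 100]
        estimate = bootstrap_transfer(
            active_records or records,
            volume_ratio=config.volume_ratio,
            n_bootstrap=config.n_bootstrap,
            seed=_stage_seed(config.seed, "bootstrap"),
        )
        results["transfer"] = estimate
        (outdir / "transfer.json").write_text(json.dumps(estimate.as_dict(), indent=2))
        manifest["stages"]["transfer"] = {"n_paired_cells": estimate.n_cells}
        return _finish(manifest, outdir, t0, results)
    except Exception as exc:
        manifest["error"] = str(exc)
        _finish(manifest, outdir, t0, results)
        raise PipelineError(f"pipeline failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def _finish(manifest: dict, outdir: Path, t0: float, results: dict) -> dict:
    for f in sorted(outdir.iterdir()):
        if f.name in {"manifest.yaml", "run.log"} or f.is_dir():
            continue
        manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    results["manifest"] = manifest
    return results


def make_report(outdir: str | Path) -> str:
    """Human-readable summary of a completed (or partial) run directory.

    Missing stage outputs are listed as absent rather than raising.
    """
    outdir = Path(outdir)
    lines = [f"symbiotrace run report: {outdir}"]
    manifest_path = outdir / "manifest.yaml"
    if manifest_path.exists():
        manifest = yaml.safe_load(manifest_path.read_text())
        lines.append(f"config hash {manifest.get('config_hash')} seed {manifest.get('seed')}")
        q = manifest.get("stages", {}).get("quantify")
        if q:
            lines.append(
                "calibration: 15N mean "
                f"{q['cal15_mean_pct']:.4f}% (threshold {q['cal15_threshold_pct']:.4f}%), "
                f"13C mean {q['cal13_mean_pct']:.4f}% (threshold {q['cal13_threshold_pct']:.4f}%)"
            )
    else:
        lines.append("manifest.yaml: absent")
    act = outdir / "activity.json"
    if act.exists():
        a = json.loads(act.read_text())
        lines.append(
            f"activity: {100 * a['frac_active_15N']:.1f}% of {a['n_with_diazoplast']} "
            f"cells 15N-active (95% CI {100 * float(a['ci_active_15N'][0]):.1f}-"
            f"{100 * float(a['ci_active_15N'][1]):.1f}%), "
            f"{100 * a['frac_fixing_13C']:.1f}% 13C-fixing"
        )
    else:
        lines.append("activity.json: absent")
    tr = outdir / "transfer.json"
    if tr.exists():
        t = json.loads(tr.read_text())
        lines.append(
            f"transfer: slope {t['slope']:.3f} (R2 {t['r2']:.3f}), volume ratio "
            f"{t['volume_ratio']:.3f} -> transferred fraction {t['transfer_frac']:.3f} "
            f"(95% CI {t['ci_low']:.3f}-{t['ci_high']:.3f}, n={t['n_cells']})"
        )
    else:
        lines.append("transfer.json: absent")
    return "\n".join(lines)
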