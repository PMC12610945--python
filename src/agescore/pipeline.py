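"""Orchestration: simulate → quantify → test → score.

Runs the whole chain on an in-memory :class:`~agescore.synthetic.StudyBundle`
or on a study directory written by :func:`~agescore.synthetic.write_study`,
and produces the per-well measurement table, the binarized marker calls and
the scorecard.  Reruns with the same configuration and seed are
bit-identical for every table written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import assayquant, imagequant, markerstats, scoring, synthetic
from .imagequant import FocusDetectionParams
from .panel import Panel, default_panel, load_panel
from .scene import read_scene
from .synthetic import (
    MarkerEffectSpec,
    SceneEntry,
    StudyBundle,
    StudyDesign,
    WoundEntry,
    generate_study,
    reference_effect_preset,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "RunResult",
    "quantify_study",
    "analyze_markers",
    "score_calls",
    "run_study",
    "run_pipeline",
    "load_study",
]

log = logging.getLogger("agescore")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; the seed lives in ``design.seed``."""

    design: StudyDesign = field(default_factory=StudyDesign)
    effects: list[MarkerEffectSpec] = field(default_factory=reference_effect_preset)
    panel: Panel = field(default_factory=default_panel)
    focus_params: FocusDetectionParams = field(default_factory=FocusDetectionParams)
    cytoplasm_width_px: int = 6
    out_dir: Path | None = None


@dataclass
class RunResult:
    wells: pd.DataFrame
    calls: pd.DataFrame
    results: dict[str, scoring.AgeScoreResult]
    trajectory: list[int]  # full score: control, then each timepoint


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("quantify")
def quantify_study(
    bundle: StudyBundle,
    panel: Panel | None = None,
    focus_params: FocusDetectionParams = FocusDetectionParams(),
    cytoplasm_width_px: int = 6,
) -> pd.DataFrame:
    """Per-well marker values for every panel marker present in a bundle.

    Image markers: nuclei are segmented per scene, the marker's readout is
    measured per cell and averaged per well (≥ 20 cells expected).  qPCR
    markers: ΔΔCt fold change per sample against the control-arm baseline
    of the same timepoint.  ELISA: mean of technical duplicates.
    Telomere: T/S ratio from the standard series (mean of triplicates,
    CV-based QC flag carried along).
    """
    panel = panel or default_panel()
    design = bundle.design
    cell_rows: list[pd.DataFrame] = []
    for entry in bundle.scenes:
        try:
            marker = panel.marker(entry.marker_name)
        except KeyError:
            continue
        channel_name = marker.channel or marker.name
        labels = imagequant.segment_nuclei(entry.scene.channel("dapi"))
        readout = {marker.name: (marker.readout, channel_name
                                 if marker.readout != "nucleus_area" else None)}
        cells = imagequant.quantify_cells(
            entry.scene.channels, labels, readout,
            focus_params=focus_params, cytoplasm_width_px=cytoplasm_width_px,
        )
        if cells.empty:
            continue
        long = cells[["cell_id", marker.name]].rename(columns={marker.name: "value"})
        long["marker"] = marker.name
        long["well_id"] = entry.well_id
        long["condition"] = entry.condition
        long["timepoint_days"] = entry.timepoint_days
        cell_rows.append(long)

    frames: list[pd.DataFrame] = []
    if cell_rows:
        cells_long = pd.concat(cell_rows, ignore_index=True)
        frames.append(
            markerstats.aggregate_per_well(
                cells_long, min_cells=design.cells_per_well
            )
        )

    if bundle.qpcr is not None:
        folds = assayquant.ddct_relative_expression(
            bundle.qpcr,
            reference_gene="GAPDH",
            control_condition=design.control_condition,
            group_within=["timepoint_days"],
        )
        qf = folds.rename(columns={"gene": "marker", "fold_change": "value"})
        qf["well_id"] = qf["sample_id"]
        frames.append(qf[["well_id", "condition", "timepoint_days", "marker", "value"]])

    if bundle.elisa is not None:
        el = assayquant.average_technical_replicates(
            bundle.elisa,
            ["sample_id", "condition", "timepoint_days", "well_id", "analyte"],
        ).rename(columns={"analyte": "marker"})
        frames.append(el[["well_id", "condition", "timepoint_days", "marker", "value"]])

    if bundle.telomere_runs is not None and bundle.telomere_standard is not None:
        tlr = assayquant.telomere_ts_ratio(bundle.telomere_runs, bundle.telomere_standard)
        meta = bundle.telomere_runs[
            ["sample_id", "condition", "timepoint_days", "well_id"]
        ].drop_duplicates()
        tlr = tlr.merge(meta, on="sample_id")
        tlr["marker"] = "telomere"
        tlr = tlr.rename(columns={"tlr": "value"})
        frames.append(
            tlr[["well_id", "condition", "timepoint_days", "marker", "value", "qc_pass"]]
        )

    if not frames:
        raise ValueError("bundle contains nothing the panel can quantify")
    wells = pd.concat(frames, ignore_index=True)
    wells = wells.sort_values(
        ["marker", "timepoint_days", "condition", "well_id"]
    ).reset_index(drop=True)
    return wells


@_stage("stats")
def analyze_markers(
    wells: pd.DataFrame,
    design: StudyDesign,
    panel: Panel | None = None,
    treated_condition: str | None = None,
) -> tuple[pd.DataFrame, list[markerstats.MarkerCall]]:
    """Test every panel marker per timepoint and binarize the results."""
    panel = panel or default_panel()
    calls: list[markerstats.MarkerCall] = []
    for marker in panel:
        sub = wells[wells["marker"] == marker.name]
        if sub.empty:
            raise ValueError(f"no measurements for panel marker {marker.name!r}")
        comparison = markerstats.compare_conditions(
            sub,
            test=marker.test,
            control_condition=design.control_condition,
            treated_condition=treated_condition,
        )
        calls.extend(
            markerstats.binarize_marker(
                comparison, marker.name, marker.expected_direction, alpha=panel.alpha
            )
        )
    calls_df = pd.DataFrame(
        [
            {"marker": c.marker_name, "timepoint_days": c.timepoint_days,
             "p_value": c.p_value, "direction": c.observed_direction,
             "rating": c.rating, "note": c.note,
             "category": panel.marker(c.marker_name).category}
            for c in calls
        ]
    ).sort_values(["timepoint_days", "marker"]).reset_index(drop=True)
    return calls_df, calls


@_stage("score")
def score_calls(
    calls: list[markerstats.MarkerCall],
    design: StudyDesign,
    panel: Panel | None = None,
) -> tuple[dict[str, scoring.AgeScoreResult], list[int]]:
    """AgeScores per timepoint plus the control-arm baseline column.

    The control column is the arm compared against itself: every marker
    rates 0 by construction, so its score is the all-zero baseline.
    """
    panel = panel or default_panel()
    results = {}
    baseline = scoring.AgeScoreResult(
        timepoint_days=None,
        primary_score=0,
        antagonistic_score=0,
        full_score=0,
        breakdown=tuple((m.name, m.category, 0) for m in panel),
        label=design.control_condition,
    )
    results[design.control_condition] = baseline
    per_tp = scoring.compute_agescore(calls, panel)
    for res in per_tp:
        results[f"day{res.timepoint_days}"] = res
    trajectory = [0] + [r.full_score for r in per_tp]
    return results, trajectory


def run_study(
    design: StudyDesign | None = None,
    effects: list[MarkerEffectSpec] | None = None,
    panel: Panel | None = None,
    focus_params: FocusDetectionParams = FocusDetectionParams(),
    cytoplasm_width_px: int = 6,
) -> RunResult:
    """In-memory end-to-end run: simulate, quantify, test, score."""
    design = design or StudyDesign()
    effects = effects if effects is not None else reference_effect_preset()
    panel = panel or default_panel()
    log.info("simulating study (seed=%d)", design.seed)
    bundle = generate_study(design, effects)
    log.info("quantifying %d scenes + assay tables", len(bundle.scenes))
    wells = quantify_study(bundle, panel, focus_params, cytoplasm_width_px)
    calls_df, calls = analyze_markers(wells, design, panel)
    results, trajectory = score_calls(calls, design, panel)
    return RunResult(wells=wells, calls=calls_df, results=results, trajectory=trajectory)


def run_pipeline(config: PipelineConfig) -> Path:
    """Full run that writes its outputs to ``config.out_dir``.

    Writes ``measurements.csv``, ``calls.csv``, ``scorecard.csv``,
    ``scorecard.md``, a ``manifest.yaml`` recording parameters and seed,
    and ``pipeline.log``.
    """
    if config.out_dir is None:
        raise PipelineError("stage 'setup' failed: no output directory configured")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        result = run_study(
            config.design, config.effects, config.panel,
            config.focus_params, config.cytoplasm_width_px,
        )
        result.wells.to_csv(out / "measurements.csv", index=False)
        result.calls.to_csv(out / "calls.csv", index=False)
        scoring.write_scorecard(result.results, out / "scorecard")
        manifest = {
            "seed": config.design.seed,
            "design": {
                "conditions": list(config.design.conditions),
                "timepoints_days": list(config.design.timepoints_days),
                "wells_per_arm": config.design.wells_per_arm,
                "cells_per_well": config.design.cells_per_well,
            },
            "panel": config.panel.name,
            "alpha": config.panel.alpha,
            "focus_intensity_window": list(config.focus_params.intensity_window),
            "focus_min_size_px": config.focus_params.min_size_px,
            "cytoplasm_width_px": config.cytoplasm_width_px,
            "full_score_trajectory": result.trajectory,
            "outputs": ["measurements.csv", "calls.csv", "scorecard.csv", "scorecard.md"],
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
        log.info("run complete; trajectory %s", result.trajectory)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def load_study(study_dir: str | Path) -> StudyBundle:
    """Read a study directory written by :func:`~agescore.synthetic.write_study`."""
    study_dir = Path(study_dir)
    manifest_path = study_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.yaml under {study_dir}")
    manifest = yaml.safe_load(manifest_path.read_text())
    d = manifest["design"]
    design = StudyDesign(
        conditions=tuple(d["conditions"]),
        timepoints_days=tuple(d["timepoints_days"]),
        wells_per_arm=d["wells_per_arm"],
        cells_per_well=d["cells_per_well"],
        seed=d["seed"],
    )
    effects = [MarkerEffectSpec(**e) for e in manifest.get("effects", [])]
    scenes: list[SceneEntry] = []
    wounds: list[WoundEntry] = []
    tables: dict[str, pd.DataFrame | None] = {
        "qpcr": None, "elisa": None, "telomere_runs": None, "telomere_standard": None
    }
    for entry in manifest.get("artifacts", []):
        kind = entry.get("kind")
        if kind == "scene":
            scene = read_scene(study_dir / entry["path"])
            scenes.append(
                SceneEntry(
                    marker_name=entry["marker"], condition=entry["condition"],
                    timepoint_days=entry["timepoint_days"], well_id=entry["well_id"],
                    seed=entry.get("seed", 0), scene=scene, ground_truth=None,
                )
            )
        elif kind == "table":
            name = Path(entry["path"]).stem
            tables[name] = pd.read_csv(study_dir / entry["path"])
        elif kind == "wound_pair":
            stack = tifffile.imread(study_dir / entry["path"]).astype(bool)
            wounds.append(
                WoundEntry(
                    marker_name=entry["marker"], condition=entry["condition"],
                    timepoint_days=entry["timepoint_days"], well_id=entry["well_id"],
                    gap_mask_first=stack[0], gap_mask_last=stack[1],
                    planted_closure_percent=np.nan,
                )
            )
    return StudyBundle(
        design=design, effects=effects, scenes=scenes,
        qpcr=tables["qpcr"], elisa=tables["elisa"],
        telomere_runs=tables["telomere_runs"],
        telomere_standard=tables["telomere_standard"],
        wounds=wounds, manifest=manifest,
    )
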