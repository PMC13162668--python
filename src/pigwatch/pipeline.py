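"""End-to-end orchestration: detections + pen geometry + schedule +
microclimate → activity, budgets, comfort and evaluation reports.

Two entry points: :func:`run` executes the on-disk pipeline described by a
:class:`RunConfig` (each stage's artifact is written so the CLI subcommands
can be re-run standalone on a previous stage's output), and
:func:`run_scenario` runs the whole chain in memory on a synthetic scenario,
returning the measurements the tests and the acceptance analysis use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import behavior as bh
from . import budget as bd
from . import detections as io
from . import evaluation as ev
from . import microclimate as mc
from . import synthetic as syn
from .config import DEFAULT_THRESHOLDS, ComfortThresholds, load_thresholds

__all__ = ["RunConfig", "run", "run_scenario", "read_label_directory"]

log = logging.getLogger("pigwatch")


@dataclass
class RunConfig:
    """Paths and thresholds for one on-disk pipeline run."""

    labels_dir: Path
    zones_csv: Path
    out_dir: Path
    truth_dir: Path | None = None
    microclimate_csv: Path | None = None
    physiology_csv: Path | None = None
    manual_budget_json: Path | None = None  # behavior → observed hours
    feeding_windows: tuple[tuple[float, float], ...] = (
        (7 * 3600.0, 9 * 3600.0),
        (15 * 3600.0, 17 * 3600.0),
    )
    confidence_threshold: float = 0.70
    occupancy_threshold: float = 0.5
    occupancy_rule: Literal["zone", "box"] = "zone"
    iou_threshold: float = 0.5
    day_start_s: float = 6 * 3600.0
    fps: float = 1.0
    n_pigs: int | None = 3
    width: int = 640
    height: int = 360
    phase: str = "growth"
    thresholds: ComfortThresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    thresholds_yaml: Path | None = None

    def __post_init__(self) -> None:
        for name in ("confidence_threshold", "occupancy_threshold", "iou_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0,1]")
        if self.thresholds_yaml is not None:
            self.thresholds = load_thresholds(self.thresholds_yaml)

    @property
    def meta(self) -> io.VideoMeta:
        return io.VideoMeta(self.width, self.height, native_fps=self.fps)

    @property
    def schedule(self) -> bh.FeedingSchedule:
        return bh.FeedingSchedule(windows=tuple(tuple(w) for w in self.feeding_windows))


def read_label_directory(
    directory: str | Path,
    meta: io.VideoMeta,
    class_names=io.TWO_CLASS_NAMES,
) -> list[io.FrameDetections]:
    """Read every ``<frame_index>.txt`` in a directory, ordered by index."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"label directory not found: {directory}")
    paths = sorted(directory.glob("*.txt"), key=lambda p: int(p.stem))
    return [io.parse_label_file(p, meta, class_names) for p in paths]


def run(config: RunConfig) -> dict:
    """Execute every configured stage; returns the report bundle as a dict
    and writes CSV/JSON artifacts plus a plain-text summary under
    ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.meta
    bundle: dict = {}

    frames = read_label_directory(config.labels_dir, meta)
    log.info("read %d label frames from %s", len(frames), config.labels_dir)
    filtered = [
        io.FrameDetections(
            f.frame_index,
            f.timestamp,
            io.filter_confidence(f.detections, config.confidence_threshold),
        )
        for f in frames
    ]
    zones = bh.zones_from_frame(io.read_zones_csv(config.zones_csv))
    activities, totals = bh.infer_video(
        filtered,
        zones,
        config.schedule,
        meta,
        video_start_seconds_of_day=config.day_start_s,
        occupancy_threshold=config.occupancy_threshold,
        occupancy_rule=config.occupancy_rule,
    )
    bh.activity_frame(activities, meta).to_csv(out / "activity.csv", index=False)
    bundle["frame_counts"] = totals

    summary = bd.budget_from_counts(totals, config.fps, per_animal=config.n_pigs)
    bundle["budget"] = summary
    comparison = None
    if config.manual_budget_json is not None:
        manual = json.loads(Path(config.manual_budget_json).read_text())
        comparison = bd.compare_budgets(
            {b: float(manual[b]) for b in summary.hours}, summary.hours
        )
        bundle["comparison"] = comparison
    bd.write_budget_report(summary, out / "budget.csv", comparison)

    if config.microclimate_csv is not None:
        climate = mc.read_microclimate_csv(config.microclimate_csv)
        timeline = mc.comfort_timeline(climate, config.thresholds)
        timeline.to_csv(out / "comfort.csv", index=False)
        bundle["comfort"] = timeline
        stats = mc.summarize_series(climate)
        stats.to_csv(out / "microclimate_summary.csv")
        bundle["microclimate_summary"] = stats

    if config.physiology_csv is not None:
        phys = mc.read_physiology_csv(config.physiology_csv)
        phys = phys.assign(
            status=[
                mc.classify_physiology(rt, rr, config.thresholds)
                for rt, rr in zip(phys["rt"], phys["rr"])
            ]
        )
        phys.to_csv(out / "physiology_status.csv", index=False)
        bundle["physiology"] = phys

    if config.truth_dir is not None:
        truths = read_label_directory(config.truth_dir, meta)
        report = ev.evaluate_detections(filtered, truths, meta)
        report.table().to_csv(out / "evaluation.csv", index=False)
        (out / "evaluation.json").write_text(
            report.table().to_json(orient="records", indent=2)
        )
        bundle["evaluation"] = report

    _write_summary(out / "summary.txt", bundle)
    return bundle


def _write_summary(path: Path, bundle: dict) -> None:
    lines = ["pigwatch run summary", "=" * 20, ""]
    if "budget" in bundle:
        lines.append("Time budget (per animal):")
        lines.append(bundle["budget"].rounded().to_string(index=False))
        lines.append("")
    if "comparison" in bundle:
        lines.append("Manual vs automatic budget (hours):")
        lines.append(bundle["comparison"].frame().round(4).to_string(index=False))
        lines.append("")
    if "microclimate_summary" in bundle:
        lines.append("Microclimate (mean/min/max):")
        lines.append(bundle["microclimate_summary"].round(2).to_string())
        lines.append("")
    if "evaluation" in bundle:
        lines.append("Detector evaluation:")
        lines.append(bundle["evaluation"].table().round(3).to_string(index=False))
        lines.append("")
    path.write_text("\n".join(lines))


def run_scenario(
    scenario: syn.ScenarioConfig,
    seed: int | None = None,
    evaluate: bool = True,
) -> dict:
    """Simulate a scenario and push it through the full inference chain in
    memory.

    Returns a dict with the ground truth, the pipeline's per-behavior frame
    counts and per-animal hour budget, comparisons of that budget against the
    ground truth's true and detected-frame budgets, and (optionally) the
    detector evaluation report.
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    states = syn.generate_behavior_states(scenario, rng)
    preds, truths, gt = syn.render_detections(states, scenario, rng)
    filtered = [
        io.FrameDetections(f.frame_index, f.timestamp, io.filter_confidence(f.detections))
        for f in preds
    ]
    _, totals = bh.infer_video(
        filtered,
        scenario.zones,
        scenario.schedule,
        scenario.meta,
        video_start_seconds_of_day=scenario.day_start_s,
    )
    summary = bd.budget_from_counts(totals, scenario.fps, per_animal=scenario.n_pigs)
    result = {
        "ground_truth": gt,
        "frame_counts": totals,
        "budget": summary,
        "auto_hours": summary.hours,
        "vs_true": bd.compare_budgets(gt.true_hours(), summary.hours),
        "vs_detected": bd.compare_budgets(gt.detected_hours(), summary.hours),
    }
    if evaluate:
        result["evaluation"] = ev.evaluate_detections(
            filtered, truths, scenario.meta, iou_thresholds=(0.5,)
        )
    return result
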