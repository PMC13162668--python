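"""Ethogram time budgets: frame counts → hours → percentages, and the
manual-vs-automatic comparison.

A behavior observed in ``k`` frames of a stream captured at ``FPS`` frames
per second lasted ``k / (FPS · 3600)`` hours.  Two frame rates exist in a
deployment: the camera's native capture rate, which governs how long a
recorded behavior actually lasted, and the detector's throughput
``FPS = 1000 / (tp + ti + tnms)`` computed from per-frame processing,
inference and non-maximum-suppression times in milliseconds.  Durations are
always converted with the capture rate; the throughput figure is reported as
a speed diagnostic only (it says how fast frames are analyzed, not how long
behaviors lasted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .behavior import BEHAVIORS

__all__ = [
    "FrameTimings",
    "EthogramSummary",
    "BudgetComparison",
    "fps_from_timings",
    "frames_to_hours",
    "summarize_budget",
    "budget_from_counts",
    "compare_budgets",
    "write_budget_report",
]


@dataclass(frozen=True)
class FrameTimings:
    """Per-frame detector timings in milliseconds: pre-processing (tp),
    inference (ti) and non-maximum suppression (tnms)."""

    tp: float
    ti: float
    tnms: float

    def __post_init__(self) -> None:
        if min(self.tp, self.ti, self.tnms) < 0:
            raise ValueError("timings must be nonnegative")
        if self.tp + self.ti + self.tnms <= 0:
            raise ValueError("total frame time must be positive")


def fps_from_timings(timings: FrameTimings) -> float:
    """Detector throughput in frames·s⁻¹: FPS = 1000 / (tp + ti + tnms)."""
    return 1000.0 / (timings.tp + timings.ti + timings.tnms)


def frames_to_hours(frame_count: float, fps: float) -> float:
    """Convert a per-behavior frame count to hours at a given frame rate."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    if frame_count < 0:
        raise ValueError("frame count must be nonnegative")
    return frame_count / (fps * 3600.0)


@dataclass(frozen=True)
class EthogramSummary:
    """Hours and percentage of total per behavior, for one pen/period.

    ``percents`` are exact (pre-rounding) and sum to 100; reporting rounds
    hours to 4 decimals and percentages to 2.
    """

    hours: dict[str, float]
    percents: dict[str, float]
    total_hours: float
    frame_counts: dict[str, int] | None = None

    def rounded(self) -> pd.DataFrame:
        rows = [
            {
                "behavior": b,
                "hours": round(self.hours[b], 4),
                "percent": round(self.percents[b], 2),
            }
            for b in self.hours
        ]
        return pd.DataFrame(rows)


def summarize_budget(hours: Mapping[str, float]) -> EthogramSummary:
    """Build an :class:`EthogramSummary` from per-behavior hours.

    percent(b) = 100 · hours(b) / Σ hours over the supplied behaviors.
    """
    if not hours:
        raise ValueError("empty budget")
    if any(h < 0 for h in hours.values()):
        raise ValueError("hours must be nonnegative")
    total = float(sum(hours.values()))
    if total <= 0:
        raise ValueError("all-zero budget has no percentage breakdown")
    percents = {b: 100.0 * h / total for b, h in hours.items()}
    return EthogramSummary(hours=dict(hours), percents=percents, total_hours=total)


def budget_from_counts(
    frame_counts: Mapping[str, int],
    fps: float,
    per_animal: int | None = None,
) -> EthogramSummary:
    """Summarize per-behavior frame counts captured at ``fps``.

    With ``per_animal=n`` the counts (summed over all animals in each frame)
    are divided by the group size, yielding the mean per-animal budget — the
    convention under which a pen's budget sums to the observation span.
    """
    divisor = fps * (per_animal or 1)
    hours = {b: frames_to_hours(c, divisor) for b, c in frame_counts.items()}
    summary = summarize_budget(hours)
    return EthogramSummary(
        hours=summary.hours,
        percents=summary.percents,
        total_hours=summary.total_hours,
        frame_counts=dict(frame_counts),
    )


@dataclass(frozen=True)
class BudgetComparison:
    """Signed and absolute per-behavior differences between a manually
    observed and an automatically estimated budget (auto − manual)."""

    manual_hours: dict[str, float]
    auto_hours: dict[str, float]
    difference_hours: dict[str, float]
    abs_difference_hours: dict[str, float]
    max_abs_behavior: str

    @property
    def max_abs_difference(self) -> float:
        return self.abs_difference_hours[self.max_abs_behavior]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "behavior": b,
                    "manual_hours": self.manual_hours[b],
                    "auto_hours": self.auto_hours[b],
                    "difference_hours": self.difference_hours[b],
                    "abs_difference_hours": self.abs_difference_hours[b],
                }
                for b in self.manual_hours
            ]
        )


def compare_budgets(
    manual: Mapping[str, float], auto: Mapping[str, float]
) -> BudgetComparison:
    """Compare per-behavior hour budgets; keys must match exactly."""
    if set(manual) != set(auto):
        raise ValueError(
            f"behavior keys differ: {sorted(set(manual) ^ set(auto))}"
        )
    if not manual:
        raise ValueError("empty budgets")
    diff = {b: auto[b] - manual[b] for b in manual}
    abs_diff = {b: abs(d) for b, d in diff.items()}
    max_b = max(abs_diff, key=lambda b: abs_diff[b])
    return BudgetComparison(
        manual_hours=dict(manual),
        auto_hours=dict(auto),
        difference_hours=diff,
        abs_difference_hours=abs_diff,
        max_abs_behavior=max_b,
    )


def write_budget_report(
    summary: EthogramSummary,
    path_csv: str | Path,
    comparison: BudgetComparison | None = None,
) -> None:
    """Write the budget report CSV
    (``behavior,frame_count,hours,percent[,manual_hours,abs_difference]``)
    and a JSON mirror next to it."""
    rows = []
    for b in summary.hours:
        row = {
            "behavior": b,
            "frame_count": (summary.frame_counts or {}).get(b),
            "hours": round(summary.hours[b], 4),
            "percent": round(summary.percents[b], 2),
        }
        if comparison is not None and b in comparison.manual_hours:
            row["manual_hours"] = comparison.manual_hours[b]
            row["abs_difference"] = round(comparison.abs_difference_hours[b], 4)
        rows.append(row)
    path_csv = Path(path_csv)
    pd.DataFrame(rows).to_csv(path_csv, index=False)
    payload = {
        "total_hours": summary.total_hours,
        "behaviors": rows,
    }
    path_csv.with_suffix(".json").write_text(json.dumps(payload, indent=2, default=float))
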