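"""Thermal-comfort indices and classification for the pig barn microclimate.

The black globe humidity index (BGHI) summarizes radiant plus humid heat load::

    BGHI = BGT + 0.36 * DPT + 41.5

where BGT is the black-globe temperature (°C) and DPT the dew-point
temperature (°C).  The dew point is estimated from dry-bulb temperature T and
relative humidity RH with the Magnus form

    gamma(T, RH) = ln(RH/100) + c*T / (b + T)
    DPT          = b * gamma / (c - gamma)

using b = 238.88 °C and c = 17.368, the constants of the saturation vapor
pressure curve es(T) = 6.1121 * exp(c*T/(b+T)) hPa.  This form is exact at
saturation (DPT = T when RH = 100) and monotone in both arguments.

Classification against the published comfort tables (BGHI classes,
rectal-temperature/respiratory-rate limits, per-phase air temperature and
humidity ranges) is driven entirely by :class:`pigwatch.config.ComfortThresholds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS, ComfortThresholds, DewPointConstants

__all__ = [
    "MicroclimateRecord",
    "AirComfort",
    "dew_point",
    "saturation_vapor_pressure",
    "bghi",
    "classify_bghi",
    "classify_physiology",
    "classify_air",
    "summarize_series",
    "read_microclimate_csv",
    "read_physiology_csv",
    "comfort_timeline",
]


@dataclass(frozen=True)
class MicroclimateRecord:
    """One timestamped environment reading.

    t_air   dry-bulb air temperature (°C)
    rh      relative humidity (%), in [0, 100]
    t_globe black-globe temperature (°C); optional — BGHI needs it
    """

    timestamp: pd.Timestamp
    t_air: float
    rh: float
    t_globe: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh <= 100.0:
            raise ValueError(f"relative humidity {self.rh} outside [0, 100]")
        if self.t_globe is not None and not math.isfinite(self.t_globe):
            raise ValueError("black-globe temperature must be finite when present")


def saturation_vapor_pressure(
    t_air: float, constants: DewPointConstants = DewPointConstants()
) -> float:
    """Saturation vapor pressure es(T) in hPa (Magnus form)."""
    return constants.es0_hpa * math.exp(constants.c * t_air / (constants.b + t_air))


def dew_point(
    t_air: float, rh: float, constants: DewPointConstants = DewPointConstants()
) -> float:
    """Dew-point temperature (°C) from dry-bulb temperature and RH (%).

    Raises ``ValueError`` for rh outside (0, 100] (the logarithm is undefined
    at 0) or a dry-bulb temperature outside the plausible −20..60 °C range.
    """
    if not 0.0 < rh <= 100.0:
        raise ValueError(f"relative humidity {rh} outside (0, 100]")
    if not -20.0 <= t_air <= 60.0:
        raise ValueError(f"air temperature {t_air} outside plausible range [-20, 60] °C")
    gamma = math.log(rh / 100.0) + constants.c * t_air / (constants.b + t_air)
    return constants.b * gamma / (constants.c - gamma)


def bghi(t_globe: float, dpt: float) -> float:
    """Black globe humidity index: BGT + 0.36·DPT + 41.5 (dimensionless)."""
    if not (math.isfinite(t_globe) and math.isfinite(dpt)):
        raise ValueError("BGHI inputs must be finite")
    return t_globe + 0.36 * dpt + 41.5


def classify_bghi(
    index: float, thresholds: ComfortThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Map a BGHI value to its comfort class (stress/comfort/alert/emergency).

    Class bounds are contiguous half-open intervals with inclusive upper
    bounds; every finite index maps to exactly one label.
    """
    if not math.isfinite(index):
        raise ValueError("BGHI index must be finite")
    for label, upper in thresholds.bghi_classes:
        if index <= upper:
            return label
    return thresholds.bghi_top_label


def classify_physiology(
    rt: float, rr: float, thresholds: ComfortThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Classify an animal's physiological state from rectal temperature (°C)
    and respiratory rate (mov·min⁻¹).

    Returns ``"heat_stress"`` iff either variable strictly exceeds its
    inclusive limit (defaults RT ≤ 39.3 °C, RR ≤ 60 mov·min⁻¹ are normal).
    """
    if rt <= 0 or rr <= 0:
        raise ValueError("rectal temperature and respiratory rate must be positive")
    return "heat_stress" if rt > thresholds.rt_max or rr > thresholds.rr_max else "normal"


@dataclass(frozen=True)
class AirComfort:
    """Deterministic labels for one (T, RH) reading against the phase tables.

    temperature: one of below_recommended | below_optimal | optimal |
        above_optimal | above_recommended (optimal ⊂ recommended, so
        ``above_optimal`` means above optimal but still within recommended).
    humidity: one of critical_low | below_good | good | above_good |
        critical_high.
    """

    temperature: str
    humidity: str


def classify_air(
    t_air: float,
    rh: float,
    phase: str,
    thresholds: ComfortThresholds = DEFAULT_THRESHOLDS,
) -> AirComfort:
    """Classify a dry-bulb temperature and humidity reading for a production
    phase ("growth" or "termination"). Bounds are inclusive."""
    try:
        rng = thresholds.air_ranges[phase]
    except KeyError:
        raise ValueError(
            f"unknown phase {phase!r}; expected one of {sorted(thresholds.air_ranges)}"
        ) from None
    if t_air < rng.recommended_min:
        temperature = "below_recommended"
    elif t_air > rng.recommended_max:
        temperature = "above_recommended"
    elif rng.optimal_min <= t_air <= rng.optimal_max:
        temperature = "optimal"
    elif t_air < rng.optimal_min:
        temperature = "below_optimal"
    else:
        temperature = "above_optimal"

    hum = thresholds.humidity
    if rh < hum.critical_min:
        humidity = "critical_low"
    elif rh > hum.critical_max:
        humidity = "critical_high"
    elif rh < hum.good_min:
        humidity = "below_good"
    elif rh > hum.good_max:
        humidity = "above_good"
    else:
        humidity = "good"
    return AirComfort(temperature=temperature, humidity=humidity)


def _to_frame(records: Iterable[MicroclimateRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        {
            "timestamp": r.timestamp,
            "t_air": r.t_air,
            "rh": r.rh,
            "t_globe": np.nan if r.t_globe is None else r.t_globe,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def summarize_series(
    records: Iterable[MicroclimateRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Mean/min/max per environment variable over a series.

    Returns a DataFrame indexed by ``["mean", "min", "max"]`` with one column
    per variable present (``t_air``, ``rh``, ``t_globe``).
    """
    df = _to_frame(records)
    if df.empty:
        raise ValueError("cannot summarize an empty microclimate series")
    cols = [c for c in ("t_air", "rh", "t_globe") if c in df.columns and df[c].notna().any()]
    agg = df[cols].agg(["mean", "min", "max"])
    agg.index = ["mean", "min", "max"]
    return agg


def read_microclimate_csv(path: str | Path) -> pd.DataFrame:
    """Read a microclimate CSV with columns timestamp,t_air,rh,t_globe
    (ISO-8601 timestamps; t_globe optional). Validates RH range and strictly
    increasing timestamps."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"timestamp", "t_air", "rh"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if ((df["rh"] < 0) | (df["rh"] > 100)).any():
        bad = df.index[(df["rh"] < 0) | (df["rh"] > 100)][0]
        raise ValueError(f"{path}: relative humidity outside [0,100] at row {bad}")
    if not df["timestamp"].is_monotonic_increasing or df["timestamp"].duplicated().any():
        raise ValueError(f"{path}: timestamps must be strictly increasing")
    return df


def read_physiology_csv(path: str | Path) -> pd.DataFrame:
    """Read a physiological-records CSV with columns
    timestamp,animal_id,rt,rr."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "animal_id", "rt", "rr"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def comfort_timeline(
    climate: pd.DataFrame, thresholds: ComfortThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Per-record dew point, BGHI and BGHI class for a microclimate frame.

    Rows without a black-globe temperature get NaN BGHI and a null class.
    """
    out = climate.copy()
    out["dpt"] = [
        dew_point(t, r, thresholds.dew_point) for t, r in zip(out["t_air"], out["rh"])
    ]
    has_globe = "t_globe" in out.columns
    bghis: list[float] = []
    labels: list[str | None] = []
    for i in range(len(out)):
        tg = out["t_globe"].iat[i] if has_globe else np.nan
        if has_globe and np.isfinite(tg):
            idx = bghi(float(tg), float(out["dpt"].iat[i]))
            bghis.append(idx)
            labels.append(classify_bghi(idx, thresholds))
        else:
            bghis.append(np.nan)
            labels.append(None)
    out["bghi"] = bghis
    out["bghi_class"] = labels
    return out
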