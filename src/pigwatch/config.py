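"""Configurable thresholds and physical constants.

Every published threshold used by the pipeline lives here, with the printed
literature values as defaults; nothing downstream hard-codes a number.  A YAML
file with the same key layout can override any subset of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = [
    "DewPointConstants",
    "AirRange",
    "HumidityRange",
    "ComfortThresholds",
    "DEFAULT_THRESHOLDS",
    "load_thresholds",
]


@dataclass(frozen=True)
class DewPointConstants:
    """Magnus constants for the dew-point estimate.

    ``b`` (°C) and ``c`` (dimensionless) parameterize the saturation vapor
    pressure curve es(T) = es0 * exp(c*T / (b + T)).
    """

    b: float = 238.88
    c: float = 17.368
    es0_hpa: float = 6.1121  # saturation vapor pressure at 0 °C

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.c > 0 and self.es0_hpa > 0):
            raise ValueError("dew-point constants must be positive")


@dataclass(frozen=True)
class AirRange:
    """Optimal and recommended dry-bulb temperature bounds (°C) for one
    production phase."""

    optimal_min: float
    optimal_max: float
    recommended_min: float
    recommended_max: float

    def __post_init__(self) -> None:
        if not (
            self.recommended_min
            <= self.optimal_min
            <= self.optimal_max
            <= self.recommended_max
        ):
            raise ValueError("air temperature ranges must nest: recommended ⊇ optimal")


@dataclass(frozen=True)
class HumidityRange:
    """Relative-humidity comfort bounds (%).

    ``good_min``–``good_max`` is the ideal band; below ``critical_min`` or
    above ``critical_max`` is critical.
    """

    good_min: float = 50.0
    good_max: float = 70.0
    critical_min: float = 40.0
    critical_max: float = 90.0

    def __post_init__(self) -> None:
        if not (
            0 <= self.critical_min <= self.good_min <= self.good_max <= self.critical_max <= 100
        ):
            raise ValueError("humidity bounds must be ordered within [0, 100]")


@dataclass(frozen=True)
class ComfortThresholds:
    """All thermal-comfort thresholds used by :mod:`pigwatch.microclimate`.

    ``bghi_classes`` is an ordered sequence of ``(label, upper_bound)`` pairs;
    an index is assigned to the first class whose (inclusive) upper bound it
    does not exceed, and to ``bghi_top_label`` beyond the last bound.  The
    default classes for finishing pigs are::

        stress    BGHI <= 67
        comfort   67 < BGHI <= 74
        alert     74 < BGHI <= 76
        emergency BGHI > 76

    ``rt_max`` / ``rr_max`` are the inclusive physiological limits (rectal
    temperature °C, respiratory rate mov·min⁻¹) above which an animal is
    flagged as heat stressed.
    """

    bghi_classes: tuple[tuple[str, float], ...] = (
        ("stress", 67.0),
        ("comfort", 74.0),
        ("alert", 76.0),
    )
    bghi_top_label: str = "emergency"
    rt_max: float = 39.3
    rr_max: float = 60.0
    air_ranges: dict[str, AirRange] = field(
        default_factory=lambda: {
            "growth": AirRange(18.0, 21.0, 8.0, 30.0),
            "termination": AirRange(15.0, 18.0, 5.0, 27.0),
        }
    )
    humidity: HumidityRange = field(default_factory=HumidityRange)
    dew_point: DewPointConstants = field(default_factory=DewPointConstants)

    def __post_init__(self) -> None:
        bounds = [b for _, b in self.bghi_classes]
        if any(not math.isfinite(b) for b in bounds):
            raise ValueError("BGHI class bounds must be finite")
        if sorted(bounds) != bounds or len(set(bounds)) != len(bounds):
            raise ValueError("BGHI class bounds must be strictly increasing")
        labels = [lab for lab, _ in self.bghi_classes] + [self.bghi_top_label]
        if len(set(labels)) != len(labels):
            raise ValueError("BGHI class labels must be unique")

    @property
    def bghi_labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.bghi_classes) + (self.bghi_top_label,)


DEFAULT_THRESHOLDS = ComfortThresholds()


def load_thresholds(path: str | Path) -> ComfortThresholds:
    """Load a :class:`ComfortThresholds` from YAML, defaulting absent keys.

    Layout mirrors the dataclass, e.g.::

        bghi_classes: [[stress, 67], [comfort, 74], [alert, 76]]
        rt_max: 39.3
        humidity: {good_min: 50, good_max: 70}
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "bghi_classes" in raw:
        kwargs["bghi_classes"] = tuple((str(l), float(b)) for l, b in raw["bghi_classes"])
    for key in ("bghi_top_label", "rt_max", "rr_max"):
        if key in raw:
            kwargs[key] = raw[key]
    if "air_ranges" in raw:
        kwargs["air_ranges"] = {
            phase: AirRange(**spec) for phase, spec in raw["air_ranges"].items()
        }
    if "humidity" in raw:
        kwargs["humidity"] = replace(HumidityRange(), **raw["humidity"])
    if "dew_point" in raw:
        kwargs["dew_point"] = replace(DewPointConstants(), **raw["dew_point"])
    return replace(DEFAULT_THRESHOLDS, **kwargs)
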