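"""Synthetic barn simulator: microclimate, physiology, behavior states and
noisy detections with ground truth.

The simulator stands in for the cameras and the trained detector.  It
emulates a pen of three finishing pigs under one of two thermal regimes —
``cooled`` (air-conditioned, mean ≈22.6 °C / 82 % RH) and ``uncooled``
(naturally ventilated, mean ≈30.4 °C / 54.6 % RH) — with a sinusoidal
diurnal temperature cycle peaking mid-afternoon and humidity in anti-phase.

Behavior follows a first-order Markov chain per pig over the four-state
ethogram {lying, standing, eating, drinking} at 1-s resolution.  The chain
is a constant-switch-rate mixture ``P = (1-r)·I + r·1πᵀ`` whose stationary
distribution is exactly the target occupancy ``π``; eating is confined to
the feeding windows by splitting the overall target into an in-window and an
out-of-window chain whose time-weighted mixture reproduces it.  Default
targets are the published time-budget fractions of detected time (cooled:
lying .680 / standing .200 / eating .115 / drinking .004; uncooled:
.697 / .168 / .123 / .012).

Detector noise reproduces the reported failure modes: per-detection misses
(occlusion, low light — more frequent in the uncooled pen, whose detected
time falls short of the observed time), Gaussian box jitter, Beta-distributed
confidences concentrated in 0.9–1, and spurious standing boxes at an unused
feeder and on the soiled floor.  Detections are emitted in the two-class
lying/standing scheme (eating and drinking render as standing; the pipeline
recovers them from zone occupancy), ground truth keeps the four classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .behavior import BEHAVIORS, FeedingSchedule, Zone
from .detections import (
    Detection,
    FrameDetections,
    NormalizedBox,
    PixelBox,
    VideoMeta,
    write_label_file,
    write_zones_csv,
    FOUR_CLASS_NAMES,
)

__all__ = [
    "BEHAVIOR_TARGETS",
    "DEFAULT_MISS_PROBABILITY",
    "RegimeClimate",
    "CLIMATE_BY_REGIME",
    "ScenarioConfig",
    "GroundTruth",
    "transition_matrix",
    "stationary_distribution",
    "split_stationary",
    "generate_microclimate",
    "generate_physiology",
    "generate_behavior_states",
    "render_detections",
    "generate_fixture",
]

Regime = Literal["cooled", "uncooled"]

#: target long-run behavior fractions of detected time, by thermal regime
BEHAVIOR_TARGETS: dict[str, dict[str, float]] = {
    "cooled": {"lying": 0.680, "standing": 0.200, "eating": 0.115, "drinking": 0.004},
    "uncooled": {"lying": 0.697, "standing": 0.168, "eating": 0.123, "drinking": 0.012},
}

#: per-detection miss probability by regime.  The uncooled pen's detector
#: missed more (tarpaulin, wet floor, overlap): its detected time is ~88 % of
#: the observed time, versus essentially complete coverage when cooled.
DEFAULT_MISS_PROBABILITY: dict[str, float] = {"cooled": 0.05, "uncooled": 0.12}


@dataclass(frozen=True)
class RegimeClimate:
    """Diurnal climate model for one regime: T(t) = mean + amp·cos(2π(h−peak)/24)
    plus Gaussian noise; RH in anti-phase; black-globe = T + radiant offset."""

    t_mean: float
    t_amp: float
    rh_mean: float
    rh_amp: float
    t_noise_sd: float
    rh_noise_sd: float
    globe_offset: float
    peak_hour: float = 14.0


CLIMATE_BY_REGIME: dict[str, RegimeClimate] = {
    "cooled": RegimeClimate(22.59, 1.8, 81.99, 6.0, 0.25, 1.5, 0.4),
    "uncooled": RegimeClimate(30.43, 4.0, 54.62, 9.0, 0.30, 2.0, 0.6),
}


def _default_zones() -> tuple[Zone, ...]:
    # 640×360 scene: trough along the top wall, nipple drinker on the right
    # wall, a second (unused) trough left of the active one.
    return (
        Zone("feeder", "feeder", PixelBox(240, 0, 400, 42)),
        Zone("drinker", "drinker", PixelBox(560, 150, 616, 200)),
        Zone("old_feeder", "inactive_feeder", PixelBox(40, 0, 160, 40)),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one simulated pen recording.

    The defaults are the study conditions: 3 pigs, a 16-h observation day
    starting 06:00 sampled at 1 frame·s⁻¹ in a 640×360 scene, twice-daily
    feeding windows (07–09 h and 15–17 h), regime-specific behavior targets
    and detector noise.  ``switch_rate`` is the per-second probability that
    the Markov chain redraws its state, setting bout lengths (≈20 s drinking,
    ≈40 s eating, ≈1 min lying bouts at the default 0.05).
    """

    regime: Regime = "cooled"
    meta: VideoMeta = field(default_factory=lambda: VideoMeta(640, 360, native_fps=1.0))
    zones: tuple[Zone, ...] = field(default_factory=_default_zones)
    n_pigs: int = 3
    n_seconds: int = 57_600  # 16-h observation day
    fps: float = 1.0  # rendered label-stream rate (frames per state-second)
    day_start_s: float = 6 * 3600.0
    schedule: FeedingSchedule = field(default_factory=FeedingSchedule)
    behavior_targets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: BEHAVIOR_TARGETS
    )
    switch_rate: float = 0.05
    p_miss: Mapping[str, float] | float = field(
        default_factory=lambda: DEFAULT_MISS_PROBABILITY
    )
    box_jitter_sd: float = 2.0  # px, per edge
    p_fp_feeder: float = 0.01  # spurious standing box at the unused feeder, per frame
    p_fp_floor: float = 0.01  # spurious standing box on the soiled floor, per frame
    confidence_beta: tuple[float, float] = (76.0, 4.0)  # mean .95, mass in 0.9–1
    standing_box: tuple[int, int] = (90, 60)  # px (w, h)
    lying_box: tuple[int, int] = (110, 70)
    zone_box_inflation: int = 8  # px the eating/drinking box extends past its zone
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in BEHAVIOR_TARGETS:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_pigs <= 0 or self.n_seconds <= 0 or self.fps <= 0:
            raise ValueError("n_pigs, n_seconds and fps must be positive")
        for p in self._miss_table().values():
            if not 0.0 <= p < 1.0:
                raise ValueError("miss probability must be in [0, 1)")
        if not 0.0 < self.switch_rate <= 1.0:
            raise ValueError("switch_rate must be in (0, 1]")

    def _miss_table(self) -> dict[str, float]:
        if isinstance(self.p_miss, Mapping):
            return dict(self.p_miss)
        return {r: float(self.p_miss) for r in BEHAVIOR_TARGETS}

    @property
    def miss_probability(self) -> float:
        return self._miss_table()[self.regime]

    @property
    def n_frames(self) -> int:
        return int(round(self.n_seconds * self.fps))

    def targets(self, regime: str | None = None) -> np.ndarray:
        t = self.behavior_targets[regime or self.regime]
        pi = np.array([t[b] for b in BEHAVIORS], dtype=float)
        return pi / pi.sum()

    def window_fraction(self) -> float:
        """Fraction of the observation span inside feeding windows."""
        start, end = self.day_start_s, self.day_start_s + self.n_seconds
        covered = 0.0
        for ws, we in self.schedule.windows:
            for day in range(int(end // 86400) + 1):
                s, e = ws + 86400 * day, we + 86400 * day
                covered += max(0.0, min(e, end) - max(s, start))
        return covered / self.n_seconds


# ---------------------------------------------------------------------------
# Markov machinery


def transition_matrix(pi: Sequence[float], switch_rate: float) -> np.ndarray:
    """Constant-switch-rate chain ``P = (1-r)·I + r·1πᵀ`` with stationary
    distribution exactly ``pi``."""
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1 or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must be a probability vector")
    if not 0.0 < switch_rate <= 1.0:
        raise ValueError("switch_rate must be in (0, 1]")
    n = len(pi)
    return (1.0 - switch_rate) * np.eye(n) + switch_rate * np.tile(pi, (n, 1))


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector
    of eigenvalue 1, normalized)."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1] or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("P must be square and row-stochastic")
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()


def split_stationary(
    overall: np.ndarray, window_fraction: float, eating_index: int = BEHAVIORS.index("eating")
) -> tuple[np.ndarray, np.ndarray]:
    """Split an overall occupancy target into in-window and out-of-window
    stationary vectors whose time-weighted mixture equals it, with all eating
    concentrated inside the windows.

    In-window eating is ``overall_eating / window_fraction``; the remaining
    in-window mass keeps the relative proportions of the non-eating
    behaviors.
    """
    w = window_fraction
    if not 0.0 < w < 1.0:
        raise ValueError("window fraction must be in (0, 1) to gate eating")
    pi = np.asarray(overall, dtype=float)
    eat_in = pi[eating_index] / w
    if eat_in >= 0.9:
        raise ValueError(
            f"eating target {pi[eating_index]:.3f} not achievable inside "
            f"{w:.0%} of the day"
        )
    non_eat = pi.copy()
    non_eat[eating_index] = 0.0
    pi_in = non_eat / non_eat.sum() * (1.0 - eat_in)
    pi_in[eating_index] = eat_in
    pi_out = (pi - w * pi_in) / (1.0 - w)
    pi_out = np.clip(pi_out, 0.0, None)
    pi_out /= pi_out.sum()
    return pi_in, pi_out


# ---------------------------------------------------------------------------
# Microclimate and physiology


def generate_microclimate(
    regime: Regime,
    n_days: int,
    seed: int | np.random.Generator = 0,
    cadence_minutes: float = 15.0,
    start: str | pd.Timestamp = "2023-01-01",
    climate: RegimeClimate | None = None,
) -> pd.DataFrame:
    """Simulate a microclimate series at a fixed cadence.

    Returns a DataFrame with columns timestamp, t_air, rh, t_globe; the
    diurnal temperature peaks at ``climate.peak_hour`` with humidity in
    anti-phase, plus independent Gaussian noise per reading.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    clim = climate or CLIMATE_BY_REGIME[regime]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = int(round(n_days * 24 * 60 / cadence_minutes))
    times = pd.date_range(start=start, periods=steps, freq=f"{cadence_minutes}min")
    hours = times.hour + times.minute / 60.0
    phase = np.cos(2 * np.pi * (hours - clim.peak_hour) / 24.0)
    t_air = clim.t_mean + clim.t_amp * phase + rng.normal(0, clim.t_noise_sd, steps)
    rh = clim.rh_mean - clim.rh_amp * phase + rng.normal(0, clim.rh_noise_sd, steps)
    rh = np.clip(rh, 0.0, 100.0)
    t_globe = t_air + clim.globe_offset
    return pd.DataFrame(
        {"timestamp": times, "t_air": t_air, "rh": rh, "t_globe": t_globe}
    )


#: piecewise-linear physiological response anchors: t_air → (RT °C, RR mov/min)
_PHYS_ANCHORS = np.array(
    [
        # t_air    RT     RR
        [18.0, 38.10, 42.0],
        [22.0, 38.33, 50.0],
        [25.0, 38.45, 58.0],
        [28.0, 38.52, 65.0],
        [31.0, 38.60, 72.0],
        [34.0, 38.80, 80.0],
    ]
)


def generate_physiology(
    climate: pd.DataFrame,
    n_animals: int = 3,
    seed: int | np.random.Generator = 0,
    sample_hours: Sequence[int] = (8, 12, 16),
    rt_noise_sd: float = 0.08,
    rr_noise_sd: float = 2.5,
) -> pd.DataFrame:
    """Rectal temperature and respiratory rate records driven by air
    temperature.

    RT and RR respond piecewise-linearly to the concurrent dry-bulb
    temperature (anchored so that a cooled pen stays below the heat-stress
    limits while an uncooled midday reading exceeds the RR limit), plus
    Gaussian animal-level noise.  Records are drawn at the given clock hours.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sel = climate[climate["timestamp"].dt.minute.eq(0) & climate["timestamp"].dt.hour.isin(sample_hours)]
    rows = []
    for r in sel.itertuples(index=False):
        rt0 = float(np.interp(r.t_air, _PHYS_ANCHORS[:, 0], _PHYS_ANCHORS[:, 1]))
        rr0 = float(np.interp(r.t_air, _PHYS_ANCHORS[:, 0], _PHYS_ANCHORS[:, 2]))
        for a in range(n_animals):
            rows.append(
                {
                    "timestamp": r.timestamp,
                    "animal_id": f"pig_{a + 1}",
                    "rt": rt0 + rng.normal(0, rt_noise_sd),
                    "rr": max(10.0, rr0 + rng.normal(0, rr_noise_sd)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Behavior states


def generate_behavior_states(
    scenario: ScenarioConfig,
    seed: int | np.random.Generator | None = None,
    bghi_series: np.ndarray | None = None,
    bghi_stress_threshold: float = 74.0,
) -> np.ndarray:
    """Simulate per-pig behavior state sequences at 1-s resolution.

    Returns an ``(n_pigs, n_seconds)`` int8 array of indices into
    :data:`pigwatch.behavior.BEHAVIORS`.  Each pig runs an independent
    first-order Markov chain whose transition matrix switches between the
    in-window and out-of-window chains of the scenario's regime.  When a
    per-second ``bghi_series`` is supplied, seconds whose BGHI exceeds
    ``bghi_stress_threshold`` use the uncooled (heat-stress) targets and the
    rest the cooled ones, so heat spells shift the budget toward drinking.
    Fixed seed ⇒ identical output.
    """
    if seed is None:
        seed = scenario.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, npigs, r = scenario.n_seconds, scenario.n_pigs, scenario.switch_rate
    w = scenario.window_fraction()

    def chain_pair(regime: str) -> tuple[np.ndarray, np.ndarray]:
        pi = scenario.targets(regime)
        if w <= 0.0:
            pi_out = pi.copy()
            pi_out[BEHAVIORS.index("eating")] = 0.0
            pi_out /= pi_out.sum()
            return pi_out, pi_out
        if w >= 1.0:
            return pi, pi
        return split_stationary(pi, w)

    pairs = {reg: chain_pair(reg) for reg in scenario.behavior_targets}

    if bghi_series is not None:
        bghi_series = np.asarray(bghi_series, dtype=float)
        if bghi_series.shape != (n,):
            raise ValueError("bghi_series must have one value per simulated second")
        regime_of_t = np.where(bghi_series > bghi_stress_threshold, "uncooled", "cooled")
    else:
        regime_of_t = None

    seconds = np.arange(n)
    in_window = np.fromiter(
        (scenario.schedule.in_window(scenario.day_start_s + float(t)) for t in seconds),
        dtype=bool,
        count=n,
    )

    # cumulative target distributions per (regime, window) for inverse sampling
    cums: dict[tuple[str, bool], np.ndarray] = {}
    for reg, (pi_in, pi_out) in pairs.items():
        cums[(reg, True)] = np.cumsum(pi_in)
        cums[(reg, False)] = np.cumsum(pi_out)

    idx_eat = BEHAVIORS.index("eating")
    states = np.empty((npigs, n), dtype=np.int8)
    for p in range(npigs):
        u = rng.random(n)
        jumps = rng.random(n) < r
        reg0 = scenario.regime if regime_of_t is None else str(regime_of_t[0])
        s = int(np.searchsorted(cums[(reg0, bool(in_window[0]))], rng.random()))
        for t in range(n):
            win = bool(in_window[t])
            if jumps[t]:
                reg = scenario.regime if regime_of_t is None else str(regime_of_t[t])
                s = int(np.searchsorted(cums[(reg, win)], u[t]))
            elif not win and s == idx_eat:
                # a closing window interrupts an eating bout immediately
                reg = scenario.regime if regime_of_t is None else str(regime_of_t[t])
                s = int(np.searchsorted(cums[(reg, False)], u[t]))
            states[p, t] = s
    return states


# ---------------------------------------------------------------------------
# Detection rendering


@dataclass
class GroundTruth:
    """What really happened in the simulated pen, in both bookkeeping
    conventions.

    ``true_frame_counts`` counts every pig-frame by its true behavior (the
    manual-observation analog); ``detected_frame_counts`` counts only the
    pig-frames whose detection survived the simulated detector (misses
    removed) — the two differ exactly by the missed detections.
    """

    states: np.ndarray  # (n_pigs, n_seconds) indices into BEHAVIORS
    fps: float
    n_pigs: int
    true_frame_counts: dict[str, int]
    detected_frame_counts: dict[str, int]

    def true_hours(self, per_animal: bool = True) -> dict[str, float]:
        div = self.fps * 3600.0 * (self.n_pigs if per_animal else 1)
        return {b: c / div for b, c in self.true_frame_counts.items()}

    def detected_hours(self, per_animal: bool = True) -> dict[str, float]:
        div = self.fps * 3600.0 * (self.n_pigs if per_animal else 1)
        return {b: c / div for b, c in self.detected_frame_counts.items()}


def _clip_box(x0: float, y0: float, x1: float, y1: float, meta: VideoMeta) -> PixelBox:
    x0i = int(np.clip(round(x0), 0, meta.width - 2))
    y0i = int(np.clip(round(y0), 0, meta.height - 2))
    x1i = int(np.clip(round(x1), x0i + 2, meta.width))
    y1i = int(np.clip(round(y1), y0i + 2, meta.height))
    return PixelBox(x0i, y0i, x1i, y1i)


def render_detections(
    states: np.ndarray,
    scenario: ScenarioConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[FrameDetections], list[FrameDetections], GroundTruth]:
    """Render per-frame detections (with detector noise) and ground truth.

    Returns ``(predicted_frames, truth_frames, ground_truth)``.  True boxes
    are placed by behavior: eating/drinking boxes blanket their zone (plus a
    small per-pig offset), lying and standing boxes land on the open floor
    away from every zone.  The detector channel applies per-detection misses,
    per-edge Gaussian jitter, Beta confidences and spurious standing boxes at
    the unused feeder and on the floor; its classes are the merged two-class
    scheme.  Truth frames carry the merged classes too (for detector
    evaluation); the four-class record lives in ``ground_truth.states``.
    """
    if seed is None:
        seed = scenario.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta, npigs = scenario.meta, scenario.n_pigs
    if states.shape[0] != npigs:
        raise ValueError("states row count must equal n_pigs")
    n_frames = int(round(states.shape[1] * scenario.fps))

    zones = {z.role: z for z in scenario.zones}
    feeder, drinker = zones.get("feeder"), zones.get("drinker")
    inactive = zones.get("inactive_feeder")
    if feeder is None or drinker is None:
        raise ValueError("scenario zones must include a feeder and a drinker")

    # open-floor placement region, clear of every zone by at least a box size
    margin_w = max(scenario.standing_box[0], scenario.lying_box[0]) // 2 + 1
    margin_h = max(scenario.standing_box[1], scenario.lying_box[1]) // 2 + 1
    zone_max_y = max(z.rect.y1 for z in (feeder, inactive) if z is not None)
    floor = PixelBox(20, zone_max_y + 2 * margin_h, drinker.rect.x0 - 2 * margin_w, meta.height - 20)
    if floor.area <= 0:
        raise ValueError("pen geometry leaves no open floor for lying/standing boxes")

    infl = scenario.zone_box_inflation
    eat_base = (feeder.rect.x0 - infl, feeder.rect.y0 - infl, feeder.rect.x1 + infl, feeder.rect.y1 + infl)
    drink_base = (drinker.rect.x0 - infl, drinker.rect.y0 - infl, drinker.rect.x1 + infl, drinker.rect.y1 + infl)

    idx_eat = BEHAVIORS.index("eating")
    idx_drink = BEHAVIORS.index("drinking")
    idx_lying = BEHAVIORS.index("lying")

    a_conf, b_conf = scenario.confidence_beta
    p_miss = scenario.miss_probability

    # pre-drawn noise, one block per frame
    miss_draw = rng.random((n_frames, npigs))
    jitter = rng.normal(0.0, scenario.box_jitter_sd, size=(n_frames, npigs + 2, 4))
    conf_draw = rng.beta(a_conf, b_conf, size=(n_frames, npigs + 2))
    fp_feeder_draw = rng.random(n_frames)
    fp_floor_draw = rng.random(n_frames)
    cx_draw = rng.uniform(floor.x0 + margin_w, floor.x1 - margin_w, size=(n_frames, npigs + 1))
    cy_draw = rng.uniform(floor.y0 + margin_h, floor.y1 - margin_h, size=(n_frames, npigs + 1))
    pig_offset = rng.integers(-6, 7, size=(n_frames, npigs, 2))

    pred_frames: list[FrameDetections] = []
    truth_frames: list[FrameDetections] = []
    true_counts = {b: 0 for b in BEHAVIORS}
    det_counts = {b: 0 for b in BEHAVIORS}

    for f in range(n_frames):
        t = min(int(f / scenario.fps), states.shape[1] - 1)
        ts = f / scenario.fps
        truth_dets: list[Detection] = []
        pred_dets: list[Detection] = []
        for p in range(npigs):
            b = int(states[p, t])
            name = BEHAVIORS[b]
            true_counts[name] += 1
            ox, oy = pig_offset[f, p]
            if b == idx_eat:
                px = _clip_box(eat_base[0] + ox, eat_base[1], eat_base[2] + ox, eat_base[3] + abs(oy), meta)
            elif b == idx_drink:
                px = _clip_box(drink_base[0] + ox, drink_base[1] + oy, drink_base[2] + ox, drink_base[3] + oy, meta)
            else:
                bw, bh = scenario.lying_box if b == idx_lying else scenario.standing_box
                cx, cy = cx_draw[f, p], cy_draw[f, p]
                px = _clip_box(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2, meta)
            merged = "lying" if b == idx_lying else "standing"
            truth_dets.append(Detection(merged, NormalizedBox.from_pixels(px, meta)))
            if miss_draw[f, p] < p_miss:
                continue
            det_counts[name] += 1
            j = jitter[f, p]
            noisy = _clip_box(px.x0 + j[0], px.y0 + j[1], px.x1 + j[2], px.y1 + j[3], meta)
            pred_dets.append(
                Detection(merged, NormalizedBox.from_pixels(noisy, meta), float(conf_draw[f, p]))
            )
        if inactive is not None and fp_feeder_draw[f] < scenario.p_fp_feeder:
            j = jitter[f, npigs]
            r = inactive.rect
            noisy = _clip_box(r.x0 - infl + j[0], r.y0 + j[1], r.x1 + infl + j[2], r.y1 + infl + j[3], meta)
            pred_dets.append(
                Detection("standing", NormalizedBox.from_pixels(noisy, meta), float(conf_draw[f, npigs]))
            )
        if fp_floor_draw[f] < scenario.p_fp_floor:
            j = jitter[f, npigs + 1]
            bw, bh = scenario.standing_box
            cx, cy = cx_draw[f, npigs], cy_draw[f, npigs]
            noisy = _clip_box(cx - bw / 2 + j[0], cy - bh / 2 + j[1], cx + bw / 2 + j[2], cy + bh / 2 + j[3], meta)
            pred_dets.append(
                Detection("standing", NormalizedBox.from_pixels(noisy, meta), float(conf_draw[f, npigs + 1]))
            )
        truth_frames.append(FrameDetections(f, ts, tuple(truth_dets)))
        pred_frames.append(FrameDetections(f, ts, tuple(pred_dets)))

    gt = GroundTruth(
        states=states,
        fps=scenario.fps,
        n_pigs=npigs,
        true_frame_counts=true_counts,
        detected_frame_counts=det_counts,
    )
    return pred_frames, truth_frames, gt


# ---------------------------------------------------------------------------
# Fixture emission


def generate_fixture(
    scenario: ScenarioConfig,
    outdir: str | Path,
    seed: int | None = None,
    n_climate_days: int = 3,
) -> Path:
    """Emit a complete on-disk fixture: prediction and truth label files,
    zones CSV, microclimate CSV, physiology CSV, ground-truth JSON and the
    scenario YAML.  Deterministic for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)

    states = generate_behavior_states(scenario, rng)
    preds, truths, gt = render_detections(states, scenario, rng)
    for frame in preds:
        write_label_file(frame, outdir / "labels" / "pred")
    for frame in truths:
        write_label_file(frame, outdir / "labels" / "truth")
    write_zones_csv(scenario.zones, outdir / "zones.csv")

    climate = generate_microclimate(scenario.regime, n_climate_days, rng)
    climate.to_csv(outdir / "microclimate.csv", index=False)
    phys = generate_physiology(climate, scenario.n_pigs, rng)
    phys.to_csv(outdir / "physiology.csv", index=False)

    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "true_frame_counts": gt.true_frame_counts,
                "detected_frame_counts": gt.detected_frame_counts,
                "true_hours_per_animal": gt.true_hours(),
                "detected_hours_per_animal": gt.detected_hours(),
                "fps": gt.fps,
                "n_pigs": gt.n_pigs,
            },
            indent=2,
        )
    )
    (outdir / "scenario.yaml").write_text(
        yaml.safe_dump(
            {
                "regime": scenario.regime,
                "n_pigs": scenario.n_pigs,
                "n_seconds": scenario.n_seconds,
                "fps": scenario.fps,
                "day_start_s": scenario.day_start_s,
                "feeding_windows": [list(w) for w in scenario.schedule.windows],
                "p_miss": scenario.miss_probability,
                "box_jitter_sd": scenario.box_jitter_sd,
                "p_fp_feeder": scenario.p_fp_feeder,
                "p_fp_floor": scenario.p_fp_floor,
                "seed": seed,
            }
        )
    )
    return outdir
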