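"""Zone occupancy and per-frame behavior classification."""

import numpy as np
import pytest

from pigwatch.behavior import (
    BEHAVIORS,
    FeedingSchedule,
    FrameActivity,
    Zone,
    classify_frame,
    infer_video,
    zone_occupancy,
)
from pigwatch.detections import Detection, FrameDetections, NormalizedBox, PixelBox, VideoMeta

META = VideoMeta(640, 360, native_fps=25.0)
FEEDER = Zone("feeder", "feeder", PixelBox(240, 0, 400, 42))
DRINKER = Zone("drinker", "drinker", PixelBox(560, 150, 616, 200))
INACTIVE = Zone("old", "inactive_feeder", PixelBox(40, 0, 160, 40))
ZONES = [FEEDER, DRINKER, INACTIVE]
ALL_DAY = FeedingSchedule(windows=((0.0, 86400.0),))
MORNING = FeedingSchedule(windows=((7 * 3600.0, 9 * 3600.0),))


def det(label, px: PixelBox, conf=None):
    return Detection(label, NormalizedBox.from_pixels(px, META), conf)


def frame(dets, idx=0, ts=0.0):
    return FrameDetections(idx, ts, tuple(dets))


def raster_occupancy(boxes, zone: Zone) -> float:
    mask = np.zeros((META.height, META.width), dtype=bool)
    for b in boxes:
        mask[b.y0 : b.y1, b.x0 : b.x1] = True
    z = zone.rect
    return float(mask[z.y0 : z.y1, z.x0 : z.x1].sum()) / zone.rect.area


class TestZoneOccupancy:
    def test_full_cover(self):
        assert zone_occupancy([PixelBox(230, 0, 410, 50)], FEEDER) == pytest.approx(1.0)

    def test_no_contact(self):
        assert zone_occupancy([PixelBox(0, 100, 50, 150)], FEEDER) == 0.0

    def test_two_halves_vs_duplicated_half(self):
        left = PixelBox(240, 0, 320, 42)
        right = PixelBox(320, 0, 400, 42)
        assert zone_occupancy([left, right], FEEDER) == pytest.approx(1.0)
        assert zone_occupancy([left, left], FEEDER) == pytest.approx(0.5)

    def test_union_not_double_counted_and_monotone(self, rng):
        boxes = []
        prev = 0.0
        for _ in range(8):
            x0 = int(rng.integers(200, 380))
            y0 = int(rng.integers(0, 30))
            boxes.append(PixelBox(x0, y0, x0 + int(rng.integers(10, 80)), y0 + int(rng.integers(5, 40))))
            oc = zone_occupancy(boxes, FEEDER)
            assert oc >= prev - 1e-12  # adding a box never decreases OC
            assert oc == pytest.approx(zone_occupancy(boxes + [boxes[0]], FEEDER))
            prev = oc

    def test_against_rasterized_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(0, 5))
            boxes = []
            for _ in range(n):
                x0 = int(rng.integers(0, 620))
                y0 = int(rng.integers(0, 340))
                boxes.append(
                    PixelBox(x0, y0, x0 + int(rng.integers(1, 140)), y0 + int(rng.integers(1, 90)))
                )
            boxes = [b.clip(META) for b in boxes]
            zone = [FEEDER, DRINKER][int(rng.integers(0, 2))]
            assert zone_occupancy(boxes, zone) == pytest.approx(raster_occupancy(boxes, zone))

    def test_zero_area_zone_rejected(self):
        with pytest.raises(ValueError):
            Zone("z", "feeder", PixelBox(0, 0, 0, 10))


class TestClassifyFrame:
    COVERING = PixelBox(230, 0, 410, 50)  # blankets the feeder

    def test_eating_inside_feeding_window(self):
        act = classify_frame(
            frame([det("standing", self.COVERING)]), ZONES, MORNING, META,
            seconds_of_day=8 * 3600.0,
        )
        assert act.assignments == ("eating",)

    def test_standing_outside_feeding_window(self):
        act = classify_frame(
            frame([det("standing", self.COVERING)]), ZONES, MORNING, META,
            seconds_of_day=12 * 3600.0,
        )
        assert act.assignments == ("standing",)

    def test_lying_at_drinker_stays_lying(self):
        act = classify_frame(
            frame([det("lying", PixelBox(550, 140, 626, 210))]), ZONES, ALL_DAY, META,
            seconds_of_day=0.0,
        )
        assert act.assignments == ("lying",)

    def test_drinking_any_time(self):
        act = classify_frame(
            frame([det("standing", PixelBox(550, 140, 626, 210))]), ZONES, MORNING, META,
            seconds_of_day=23 * 3600.0,
        )
        assert act.assignments == ("drinking",)

    def test_inactive_feeder_never_produces_eating(self):
        covering_inactive = PixelBox(30, 0, 170, 50)
        act = classify_frame(
            frame([det("standing", covering_inactive)]), ZONES, ALL_DAY, META,
            seconds_of_day=8 * 3600.0,
        )
        assert act.assignments == ("standing",)

    def test_half_occupancy_threshold(self):
        # box covering exactly half of the feeder triggers at 0.5, not above
        half = PixelBox(240, 0, 320, 42)
        act = classify_frame(
            frame([det("standing", half)]), ZONES, ALL_DAY, META, seconds_of_day=0.0
        )
        assert act.assignments == ("eating",)
        act = classify_frame(
            frame([det("standing", half)]), ZONES, ALL_DAY, META,
            seconds_of_day=0.0, occupancy_threshold=0.51,
        )
        assert act.assignments == ("standing",)

    def test_box_rule_variant(self):
        # small box fully inside the feeder: passes the per-box rule but not
        # the zone-occupancy rule
        small = PixelBox(300, 10, 330, 30)
        zone_rule = classify_frame(
            frame([det("standing", small)]), ZONES, ALL_DAY, META, seconds_of_day=0.0
        )
        assert zone_rule.assignments == ("standing",)
        box_rule = classify_frame(
            frame([det("standing", small)]), ZONES, ALL_DAY, META,
            seconds_of_day=0.0, occupancy_rule="box",
        )
        assert box_rule.assignments == ("eating",)

    def test_counts_partition_detections(self):
        dets = [
            det("lying", PixelBox(50, 100, 160, 170)),
            det("standing", self.COVERING),
            det("standing", PixelBox(550, 140, 626, 210)),
            det("standing", PixelBox(100, 200, 190, 260)),
        ]
        act = classify_frame(frame(dets), ZONES, ALL_DAY, META, seconds_of_day=8 * 3600.0)
        assert sum(act.counts.values()) == len(dets)
        assert act.counts == {"lying": 1, "standing": 1, "eating": 1, "drinking": 1}

    def test_activity_invariant_enforced(self):
        with pytest.raises(ValueError):
            FrameActivity(0, {"lying": 2}, ("lying",))


class TestInferVideo:
    def test_all_empty_frames(self):
        frames = [frame([], idx=i, ts=i / 25.0) for i in range(10)]
        _, totals = infer_video(frames, ZONES, ALL_DAY, META)
        assert totals == {b: 0 for b in BEHAVIORS}

    def test_constant_lying_counts(self):
        lying = det("lying", PixelBox(50, 100, 160, 170))
        frames = [frame([lying] * 3, idx=i, ts=i / 25.0) for i in range(40)]
        _, totals = infer_video(frames, ZONES, ALL_DAY, META)
        assert totals["lying"] == 120

    def test_scripted_drinking_bout(self):
        """Pig walks to the drinker, drinks 100 frames, leaves."""
        away = PixelBox(100, 200, 190, 260)
        at_drinker = PixelBox(550, 140, 626, 210)
        frames = []
        for i in range(300):
            px = at_drinker if 100 <= i < 200 else away
            frames.append(frame([det("standing", px)], idx=i, ts=i / 25.0))
        _, totals = infer_video(frames, ZONES, ALL_DAY, META)
        assert totals["drinking"] == 100
        assert totals["standing"] == 200

    def test_empty_schedule_gates_all_eating(self):
        covering = PixelBox(230, 0, 410, 50)
        frames = [frame([det("standing", covering)], idx=i, ts=i / 25.0) for i in range(20)]
        _, totals = infer_video(frames, ZONES, FeedingSchedule.empty(), META)
        assert totals["eating"] == 0

    def test_duplicate_frame_index_rejected(self):
        frames = [frame([], idx=0), frame([], idx=0)]
        with pytest.raises(ValueError, match="duplicated"):
            infer_video(frames, ZONES, ALL_DAY, META)

    def test_timestamp_outside_span_rejected(self):
        meta = VideoMeta(640, 360, native_fps=25.0, n_frames=100)
        bad = [frame([], idx=5, ts=10.0)]  # span is 4 s
        with pytest.raises(ValueError, match="span"):
            infer_video(bad, ZONES, ALL_DAY, meta)


class TestOracleAgreement:
    """classify_frame against a brute-force rasterization implementation."""

    @staticmethod
    def brute_force(dets, zones, schedule, seconds_of_day, threshold=0.5):
        pixel = [d.box.to_pixels(META) for d in dets]
        standing = [p for d, p in zip(dets, pixel) if d.class_label == "standing"]
        active = {}
        for z in zones:
            if z.role == "inactive_feeder":
                continue
            if z.role == "feeder" and not schedule.in_window(seconds_of_day):
                continue
            active[z.zone_id] = raster_occupancy(standing, z) >= threshold
        out = []
        for d, p in zip(dets, pixel):
            if d.class_label == "lying":
                out.append("lying")
                continue
            best = None
            for z in zones:
                if z.zone_id not in active or not active[z.zone_id]:
                    continue
                mask = np.zeros((META.height, META.width), dtype=bool)
                mask[p.y0 : p.y1, p.x0 : p.x1] = True
                inter = int(mask[z.rect.y0 : z.rect.y1, z.rect.x0 : z.rect.x1].sum())
                if inter == 0:
                    continue
                frac = inter / z.rect.area
                prio = 1 if z.role == "drinker" else 0
                beh = "drinking" if z.role == "drinker" else "eating"
                if best is None or (frac, prio) > best[:2]:
                    best = (frac, prio, beh)
            out.append(best[2] if best else "standing")
        return tuple(out)

    def test_random_frames(self, rng):
        schedule = MORNING
        for k in range(250):
            n = int(rng.integers(0, 5))
            dets = []
            for _ in range(n):
                x0 = int(rng.integers(0, 600))
                y0 = int(rng.integers(0, 330))
                px = PixelBox(
                    x0, y0, x0 + int(rng.integers(20, 200)), y0 + int(rng.integers(20, 120))
                ).clip(META)
                label = "lying" if rng.random() < 0.5 else "standing"
                dets.append(det(label, px))
            sod = float(rng.uniform(0, 86400))
            act = classify_frame(frame(dets), ZONES, schedule, META, seconds_of_day=sod)
            assert act.assignments == self.brute_force(dets, ZONES, schedule, sod)
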