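"""Synthetic barn simulator: climate, behavior dynamics, detector noise."""

import numpy as np
import pytest

from pigwatch.behavior import BEHAVIORS, FeedingSchedule
from pigwatch.detections import parse_label_text, write_label_lines
from pigwatch.microclimate import classify_physiology
from pigwatch.pipeline import run_scenario
from pigwatch.synthetic import (
    BEHAVIOR_TARGETS,
    DEFAULT_MISS_PROBABILITY,
    RegimeClimate,
    ScenarioConfig,
    generate_behavior_states,
    generate_fixture,
    generate_microclimate,
    generate_physiology,
    render_detections,
    split_stationary,
    stationary_distribution,
    transition_matrix,
)


class TestMicroclimateGenerator:
    def test_zero_noise_zero_amplitude_is_constant(self):
        clim = RegimeClimate(22.59, 0.0, 80.0, 0.0, 0.0, 0.0, 0.4)
        df = generate_microclimate("cooled", 1, seed=0, climate=clim)
        assert np.allclose(df["t_air"], 22.59)
        assert np.allclose(df["t_globe"], 22.99)

    def test_mean_converges_to_configured_mean(self):
        df = generate_microclimate("cooled", n_days=92, seed=3)
        assert df["t_air"].mean() == pytest.approx(22.59, abs=0.3)
        assert df["rh"].mean() == pytest.approx(81.99, abs=1.0)

    def test_temperature_peaks_in_the_afternoon(self):
        clim = RegimeClimate(30.43, 4.0, 54.62, 9.0, 0.0, 0.0, 0.6)
        df = generate_microclimate("uncooled", n_days=3, seed=0, climate=clim)
        for _, day in df.groupby(df["timestamp"].dt.date):
            peak = day.loc[day["t_air"].idxmax(), "timestamp"]
            assert 12 <= peak.hour <= 16

    def test_humidity_antiphase_with_temperature(self):
        df = generate_microclimate("uncooled", n_days=7, seed=1)
        assert np.corrcoef(df["t_air"], df["rh"])[0, 1] < -0.7

    def test_deterministic_under_seed(self):
        a = generate_microclimate("cooled", 2, seed=5)
        b = generate_microclimate("cooled", 2, seed=5)
        assert a.equals(b)

    def test_rejects_zero_days(self):
        with pytest.raises(ValueError):
            generate_microclimate("cooled", 0)


class TestPhysiologyGenerator:
    def test_heat_stress_tracks_regime(self):
        cooled = generate_physiology(generate_microclimate("cooled", 3, seed=2), seed=2)
        uncooled = generate_physiology(generate_microclimate("uncooled", 3, seed=2), seed=2)

        def stress_fraction(df):
            flags = [classify_physiology(rt, rr) == "heat_stress"
                     for rt, rr in zip(df["rt"], df["rr"])]
            return np.mean(flags)

        assert stress_fraction(cooled) < stress_fraction(uncooled)
        midday = uncooled[uncooled["timestamp"].dt.hour == 12]
        assert (midday["rr"] > 60).mean() > 0.5  # heat raises the respiratory rate


class TestMarkovMachinery:
    def test_transition_matrix_stationary_is_target(self):
        pi = np.array([0.68, 0.20, 0.115, 0.005])
        P = transition_matrix(pi, 0.05)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(stationary_distribution(P), pi, atol=1e-12)

    def test_split_preserves_time_weighted_mixture(self):
        pi = np.array([0.68, 0.20, 0.115, 0.005])
        w = 0.25
        pi_in, pi_out = split_stationary(pi, w)
        assert pi_out[BEHAVIORS.index("eating")] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(w * pi_in + (1 - w) * pi_out, pi, atol=1e-12)

    def test_unachievable_eating_target_rejected(self):
        with pytest.raises(ValueError, match="not achievable"):
            split_stationary(np.array([0.05, 0.05, 0.88, 0.02]), 0.25)

    def test_invalid_matrix_inputs(self):
        with pytest.raises(ValueError):
            transition_matrix([0.5, 0.6], 0.05)
        with pytest.raises(ValueError):
            stationary_distribution(np.array([[0.5, 0.6], [0.5, 0.5]]))


class TestBehaviorStates:
    def test_absorbing_lying_target_yields_all_lying(self):
        scenario = ScenarioConfig(
            n_seconds=600,
            behavior_targets={
                "cooled": {"lying": 1.0, "standing": 0.0, "eating": 0.0, "drinking": 0.0},
                "uncooled": BEHAVIOR_TARGETS["uncooled"],
            },
        )
        states = generate_behavior_states(scenario, seed=0)
        assert (states == BEHAVIORS.index("lying")).all()

    def test_same_seed_identical_sequences(self):
        scenario = ScenarioConfig(n_seconds=1200)
        a = generate_behavior_states(scenario, seed=9)
        b = generate_behavior_states(scenario, seed=9)
        assert (a == b).all()

    def test_eating_confined_to_feeding_windows(self):
        scenario = ScenarioConfig(n_seconds=14400, day_start_s=6 * 3600.0, seed=4)
        states = generate_behavior_states(scenario)
        eat = BEHAVIORS.index("eating")
        for t in range(scenario.n_seconds):
            if (states[:, t] == eat).any():
                assert scenario.schedule.in_window(scenario.day_start_s + t)

    def test_empty_schedule_means_no_eating(self):
        scenario = ScenarioConfig(n_seconds=3600, schedule=FeedingSchedule.empty(), seed=4)
        states = generate_behavior_states(scenario)
        assert not (states == BEHAVIORS.index("eating")).any()

    def test_stationary_occupancy_recovered(self, cooled_day_run):
        """Empirical lying fraction over a 16-h day is within 2 pp of the
        chain's analytic stationary probability (window-weighted)."""
        scenario = ScenarioConfig(regime="cooled", seed=11)
        w = scenario.window_fraction()
        pi_in, pi_out = split_stationary(scenario.targets(), w)
        st_in = stationary_distribution(transition_matrix(pi_in, scenario.switch_rate))
        st_out = stationary_distribution(transition_matrix(pi_out, scenario.switch_rate))
        predicted = w * st_in + (1 - w) * st_out
        states = cooled_day_run["ground_truth"].states
        for i, b in enumerate(BEHAVIORS):
            empirical = (states == i).mean()
            assert empirical == pytest.approx(predicted[i], abs=0.02), b

    def test_bghi_series_switches_targets(self):
        scenario = ScenarioConfig(n_seconds=7200, schedule=FeedingSchedule.empty(), seed=3)
        hot = generate_behavior_states(scenario, seed=3, bghi_series=np.full(7200, 80.0))
        cool = generate_behavior_states(scenario, seed=3, bghi_series=np.full(7200, 70.0))
        drink = BEHAVIORS.index("drinking")
        assert (hot == drink).mean() > (cool == drink).mean()


class TestRenderDetections:
    def _zero_noise(self, **kw):
        return ScenarioConfig(
            p_miss=0.0, box_jitter_sd=0.0, p_fp_feeder=0.0, p_fp_floor=0.0, **kw
        )

    def test_zero_noise_recovers_ground_truth_exactly(self, zero_noise_scenario):
        result = run_scenario(zero_noise_scenario)
        assert all(
            v == pytest.approx(0.0, abs=1e-12)
            for v in result["vs_true"].abs_difference_hours.values()
        )
        assert result["evaluation"].precision_mean == pytest.approx(1.0)
        assert result["evaluation"].recall_mean == pytest.approx(1.0)
        # the run exercises every behavior
        assert all(result["ground_truth"].true_frame_counts[b] > 0 for b in BEHAVIORS)

    def test_miss_probability_sets_recall(self):
        scenario = ScenarioConfig(
            n_seconds=3600, p_miss=0.05, box_jitter_sd=0.0,
            p_fp_feeder=0.0, p_fp_floor=0.0, seed=13,
        )
        result = run_scenario(scenario)
        n = 3 * 3600
        ci = 3 * np.sqrt(0.95 * 0.05 / n)
        assert result["evaluation"].recall_mean == pytest.approx(0.95, abs=ci + 0.005)

    def test_inactive_feeder_false_positives_inflate_standing_only(self):
        base = dict(n_seconds=1800, schedule=FeedingSchedule.empty(), seed=21,
                    p_miss=0.0, box_jitter_sd=0.0, p_fp_floor=0.0)
        clean = run_scenario(ScenarioConfig(p_fp_feeder=0.0, **base))
        noisy = run_scenario(ScenarioConfig(p_fp_feeder=0.3, **base))
        assert noisy["frame_counts"]["eating"] == 0
        assert clean["frame_counts"]["eating"] == 0
        assert noisy["frame_counts"]["standing"] > clean["frame_counts"]["standing"]
        assert noisy["frame_counts"]["lying"] == clean["frame_counts"]["lying"]

    def test_determinism_end_to_end(self):
        scenario = ScenarioConfig(n_seconds=600, seed=17)
        runs = []
        for _ in range(2):
            states = generate_behavior_states(scenario)
            preds, truths, gt = render_detections(states, scenario)
            runs.append((states, preds, gt.detected_frame_counts))
        assert (runs[0][0] == runs[1][0]).all()
        assert runs[0][2] == runs[1][2]
        text0 = "".join(write_label_lines(f.detections) for f in runs[0][1])
        text1 = "".join(write_label_lines(f.detections) for f in runs[1][1])
        assert text0 == text1

    def test_heat_stress_shifts_budget_signs(self, cooled_day_run, uncooled_day_run):
        """Uncooled pens drink more; with the regime miss rates, detected
        eating time drops despite a larger true eating fraction."""
        cooled = cooled_day_run["auto_hours"]
        uncooled = uncooled_day_run["auto_hours"]
        assert uncooled["drinking"] > cooled["drinking"]
        # the eating-hours sign is driven by the calibrated expectation
        span = 16.0
        for regime, run in (("cooled", cooled_day_run), ("uncooled", uncooled_day_run)):
            sc = ScenarioConfig(regime=regime)
            expected = sc.targets()[BEHAVIORS.index("eating")] * (1 - sc.miss_probability) * span
            assert run["auto_hours"]["eating"] == pytest.approx(expected, abs=0.2)
        exp_cool = BEHAVIOR_TARGETS["cooled"]["eating"] * (1 - DEFAULT_MISS_PROBABILITY["cooled"])
        exp_hot = BEHAVIOR_TARGETS["uncooled"]["eating"] * (1 - DEFAULT_MISS_PROBABILITY["uncooled"])
        assert exp_hot < exp_cool


def test_fixture_directory_is_complete(tmp_path):
    scenario = ScenarioConfig(n_seconds=120, seed=5)
    out = generate_fixture(scenario, tmp_path / "fix")
    for rel in ("zones.csv", "microclimate.csv", "physiology.csv",
                "ground_truth.json", "scenario.yaml"):
        assert (out / rel).exists(), rel
    pred_files = sorted((out / "labels" / "pred").glob("*.txt"))
    assert len(pred_files) == 120
    parsed = parse_label_text(pred_files[0].read_text(), 0, scenario.meta)
    assert all(d.confidence is not None for d in parsed.detections)
    truth0 = (out / "labels" / "truth" / "0.txt").read_text()
    assert len(truth0.splitlines()) == scenario.n_pigs
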