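import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pigwatch.detections import VideoMeta
from pigwatch.synthetic import ScenarioConfig
from pigwatch.pipeline import run_scenario


@pytest.fixture
def meta():
    return VideoMeta(640, 360, native_fps=25.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def _zero_noise(regime="cooled", **kw):
    return ScenarioConfig(
        regime=regime,
        p_miss=0.0,
        box_jitter_sd=0.0,
        p_fp_feeder=0.0,
        p_fp_floor=0.0,
        **kw,
    )


@pytest.fixture
def zero_noise_scenario():
    # two hours straddling the morning feeding window so every behavior occurs
    return _zero_noise(n_seconds=7200, day_start_s=6.5 * 3600.0, seed=7)


@pytest.fixture(scope="session")
def cooled_day_run():
    """Default-noise cooled 16-h day through the full pipeline (shared: the
    simulation is the expensive part of the suite)."""
    return run_scenario(ScenarioConfig(regime="cooled", seed=11), evaluate=False)


@pytest.fixture(scope="session")
def uncooled_day_run():
    return run_scenario(ScenarioConfig(regime="uncooled", seed=11), evaluate=False)
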