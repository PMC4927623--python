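import numpy as np
import pytest
from hypothesis import settings

import emgprofile as ep

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_recording(rng):
    """One second of white noise at 1 kHz."""
    return ep.EmgRecording(samples=rng.standard_normal(1000), sampling_rate=1000.0)


@pytest.fixture
def sim_config():
    return ep.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 2-group × 3-subject × 5-muscle cohort with 30-s work recordings,
    shared across pipeline/CLI tests to keep the suite fast."""
    out = tmp_path_factory.mktemp("cohort")
    spec = ep.CohortSpec(
        groups={
            "large_herd_US": ep.GroupSpec(
                n_subjects=3,
                muscle_levels=ep.simulate.DEFAULT_GROUP_LEVELS["large_herd_US"],
                between_subject_sd=2.0,
                rest_fraction=0.13,
            ),
            "small_herd_IT": ep.GroupSpec(
                n_subjects=3,
                muscle_levels=ep.simulate.DEFAULT_GROUP_LEVELS["small_herd_IT"],
                between_subject_sd=2.0,
                rest_fraction=0.05,
            ),
        },
        work_duration=30.0,
    )
    config = ep.SimulationConfig(seed=7, cohort=spec)
    manifest, truths, truth_table = ep.simulate_cohort(config, out)
    return {
        "dir": out,
        "config": config,
        "manifest": manifest,
        "truths": truths,
        "truth_table": truth_table,
    }
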