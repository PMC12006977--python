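import numpy as np
import pytest

from bxk.config import ModelConfig
from bxk.exposure import BlastEvent, ExposureTimeline, TrainingSchedule
from bxk.simulate import scenario_from_schedule
from bxk.stats import load_table1
from bxk.synthetic import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def single_event_timeline():
    """One supra-threshold 8-psi blast 1 h into the study."""
    return ExposureTimeline((BlastEvent(1.0, 8.0),))


@pytest.fixture(scope="session")
def three_day_scenario():
    schedule = TrainingSchedule(n_days=3, daily_bop=(5.0, 6.0, 8.0))
    return scenario_from_schedule("s1", schedule)


@pytest.fixture(scope="session")
def noise_free_cohort(config):
    """Small noise-free cohort generated at the default x = 1.5."""
    return generate_cohort(CohortDesign(n_subjects=5, noise_cv=0.0, seed=11), config)


def with_params(config: ModelConfig, **groups) -> ModelConfig:
    """Config copy with per-group field overrides, e.g. pbpk={'x': 0}."""
    update = {
        name: getattr(config, name).model_copy(update=fields)
        for name, fields in groups.items()
    }
    return config.model_copy(update=update, deep=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
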