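import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import keeljump as kj
from keeljump.simulate import truth_metrics_frame

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_config(seed: int, **kwargs) -> kj.SimConfig:
    """A 12-hen, 2-pen study: same structure as the full design, desk-sized."""
    defaults = dict(n_hens_per_hybrid=6, n_pens=2, n_jumps=3)
    defaults.update(kwargs)
    return kj.SimConfig(seed=seed, **defaults)


def simulate_metrics(config: kj.SimConfig) -> pd.DataFrame:
    """Truth-level metrics table (no trace rendering) for a config."""
    roster = kj.simulate_roster(config)
    schedule = kj.make_schedule(roster, n_days=config.n_days, seed=config.seed,
                                n_jumps=config.n_jumps)
    truths = kj.draw_outcomes(schedule, roster, config)
    return truth_metrics_frame(truths)


@pytest.fixture(scope="session")
def default_roster():
    return kj.simulate_roster(kj.SimConfig(seed=5))


@pytest.fixture(scope="session")
def default_schedule(default_roster):
    return kj.make_schedule(default_roster, seed=5)


@pytest.fixture(scope="session")
def small_metrics():
    """Metrics from a small study drawn with the default effect sizes."""
    return simulate_metrics(small_config(31))


@pytest.fixture
def hen_record():
    return kj.HenRecord("NC01", "P1", "nick_chick", 1.6, 1.8)
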