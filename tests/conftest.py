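import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from actitrend import EpochSeries, SimConfig, simulate_cohort


def make_series(counts, start="2010-06-07 06:00:00", epoch_length=60, **kw):
    """EpochSeries helper with all flags initialised worn / not excluded."""
    return EpochSeries(
        kw.pop("participant_id", "p1"),
        kw.pop("wave_index", 1),
        pd.Timestamp(start),
        epoch_length,
        np.asarray(counts, dtype=np.int64),
        **kw,
    )


@pytest.fixture
def small_cohort():
    """Compact simulated cohort for model unit tests (3 studies x 40)."""
    cfg = SimConfig(n_studies=3, participants_per_study=40)
    table, truth = simulate_cohort(cfg, seed=11)
    return cfg, table, truth


@pytest.fixture
def noiseless_config():
    """Config with all random components switched off."""
    zero = {"sed": 0.0, "lpa": 0.0, "mvpa": 0.0}
    return SimConfig(
        n_studies=3,
        participants_per_study=25,
        sd_study=dict(zero),
        sd_participant=dict(zero),
        sd_residual=dict(zero),
    )
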