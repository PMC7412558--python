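import numpy as np
import pytest

from glucast import (
    EventSchedule, NetConfig, PatientParams, SplitSpec,
    build_windows, generate_cohort, simulate_patient,
)
from glucast.evaluation import fit_patient


@pytest.fixture(scope="session")
def default_params():
    return PatientParams()


@pytest.fixture(scope="session")
def one_day_series(default_params):
    """Deterministic one-day 15-min record with one meal+bolus pair."""
    schedule = EventSchedule(
        meals=((8 * 60.0, 60.0),),
        fast_boluses=((8 * 60.0, 4.0),),
        slow_boluses=((22 * 60.0, 12.0),),
        duration_min=1440.0,
    )
    return simulate_patient(default_params, schedule, dt_min=15.0)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(2, 3, 15.0, seed=7)


@pytest.fixture(scope="session")
def tiny_trained(small_cohort):
    """A cheap trained model + its validation windows, shared across tests."""
    series = small_cohort[0][2]
    cfg = NetConfig(memory_units=4, combiner_width=4, epochs=25, seed=3,
                    dt_min=15.0)
    split = SplitSpec(mode="random_fraction", train_fraction=0.7, seed=3)
    model, val = fit_patient(series, cfg, split)
    return model, val, series
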