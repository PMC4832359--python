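"""Shared fixtures.

The expensive simulate-then-fit round trips (second-order glucose-group fit,
first-order fit, first-order fit of second-order data) are session-scoped so
the recovery, comparison and identifiability tests share one computation.
"""

import numpy as np
import pytest
from hypothesis import settings

import hpkinetics as hp

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

SEED = 20160118  # fixed study seed for the test session


@pytest.fixture(scope="session")
def schedule():
    return hp.AcquisitionSchedule()  # 2 s TR, 10 deg, 90 points


@pytest.fixture(scope="session")
def glucose_preset():
    return hp.GLUCOSE_ONLY


@pytest.fixture(scope="session")
def glucose_second_order_data(schedule, glucose_preset):
    """Noiseless normalized second-order data, glucose-only truth."""
    params = glucose_preset["second_order"]
    relax = glucose_preset["relaxation"]
    inp = hp.calibrate_input_amplitude("second_order", params, relax, schedule,
                                       hp.InputParams())
    ts, traj = hp.simulate("second_order", params, relax, schedule, inp)
    return {"data": hp.normalize(ts), "trajectory": traj, "params": params,
            "relax": relax, "inp": inp}


@pytest.fixture(scope="session")
def glucose_first_order_data(schedule, glucose_preset):
    """Noiseless normalized first-order data, glucose-only truth."""
    params = glucose_preset["first_order"]
    relax = glucose_preset["relaxation"]
    inp = hp.calibrate_input_amplitude("first_order", params, relax, schedule,
                                       hp.InputParams())
    ts, traj = hp.simulate("first_order", params, relax, schedule, inp)
    return {"data": hp.normalize(ts), "trajectory": traj, "params": params,
            "relax": relax, "inp": inp}


@pytest.fixture(scope="session")
def glucose_second_order_fit(glucose_second_order_data):
    """Second-order fit of the noiseless second-order data (16 multistarts)."""
    est = hp.KineticsFitter(model_kind="second_order", n_starts=16,
                            random_state=SEED)
    est.fit(glucose_second_order_data["data"])
    return est


@pytest.fixture(scope="session")
def first_order_fit_of_second_order_data(glucose_second_order_data):
    """First-order fit of the same second-order data (the mis-specified model)."""
    est = hp.KineticsFitter(model_kind="first_order", n_starts=16,
                            random_state=SEED)
    est.fit(glucose_second_order_data["data"])
    return est


@pytest.fixture(scope="session")
def glucose_first_order_fit(glucose_first_order_data):
    """First-order fit of the noiseless first-order data."""
    est = hp.KineticsFitter(model_kind="first_order", n_starts=16,
                            random_state=SEED)
    est.fit(glucose_first_order_data["data"])
    return est
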