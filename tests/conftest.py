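import logging

import pytest
from hypothesis import settings as hyp_settings

from dlbcl_cea.cohort_model import build_strategy, run_cohort
from dlbcl_cea.inputs import ModelInputs
from dlbcl_cea.synthetic_data import calibrate_to_targets, make_life_table
from dlbcl_cea.transitions import CycleSchedule, load_parameter_table

logging.getLogger("dlbcl_cea").setLevel(logging.ERROR)

hyp_settings.register_profile("repro", derandomize=True, deadline=None)
hyp_settings.load_profile("repro")


@pytest.fixture(scope="session")
def schedule():
    return CycleSchedule()


@pytest.fixture(scope="session")
def params():
    return load_parameter_table()


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def traces(params, schedule, life_table):
    out = {}
    for arm in ("RCHOP", "I-RCHOP"):
        model = build_strategy(arm, params, schedule)
        out[arm] = run_cohort(model, schedule, life_table, 55.0)
    return out


@pytest.fixture(scope="session")
def calibrated():
    """Best-effort calibration against the published per-strategy totals."""
    return calibrate_to_targets(strict=False, seed=1)


@pytest.fixture(scope="session")
def calibrated_inputs():
    """Full input bundle with calibrated synthetic economics."""
    return ModelInputs.default(seed=1, calibrated=True)
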