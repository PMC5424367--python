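import logging

import pytest

from bongaarts.records import WomanRecord
from bongaarts.simulate import SimulationParams, simulate_cohort

logging.getLogger("bongaarts").setLevel(logging.ERROR)


def make_woman(
    woman_id="W0",
    weight=1.0,
    age_months=300,
    interview_cm=1404,
    marital_status="married",
    current_method="none",
    insusceptible_now=False,
    births_ago=(),
    **stratifiers,
):
    """Build a record from an age in months and birth lags before interview."""
    return WomanRecord(
        woman_id=woman_id,
        weight=weight,
        dob_cm=interview_cm - age_months,
        interview_cm=interview_cm,
        marital_status=marital_status,
        current_method=current_method,
        insusceptible_now=insusceptible_now,
        births_cm=tuple(interview_cm - lag for lag in births_ago),
        stratifiers=stratifiers,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """300 women under the default generative parameters (mixed marriage)."""
    return simulate_cohort(SimulationParams(n_women=300, seed=11))


@pytest.fixture(scope="session")
def married_cohort():
    """500 all-married women: nonmarital fertility zero by construction."""
    params = SimulationParams(n_women=500, seed=17, marriage_schedule=(1.0,) * 7)
    return simulate_cohort(params)
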