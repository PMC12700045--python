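"""Shared fixtures: the default synthetic cohort and its processed stages."""

import pandas as pd
import pytest

from glycacro import diet, phenotype, simulate, urine


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, seed 42."""
    return simulate.generate_cohort(simulate.CohortConfig(), seed=42)


@pytest.fixture(scope="session")
def daily(cohort):
    return urine.add_daily_ratios(urine.daily_excretion(cohort["urine"]))


@pytest.fixture(scope="session")
def overnight(cohort):
    on = urine.overnight_excretion(cohort["urine"])
    on["dinner_class"] = [
        diet.DEFAULT_EXPOSURE.classify_day(int(d)) for d in on["study_day"]
    ]
    return on


@pytest.fixture(scope="session")
def calls(daily):
    return phenotype.classify_cohort(daily)


@pytest.fixture()
def simple_intervals():
    """One participant, two clean 12 h collections inside study day 1."""
    return pd.DataFrame(
        {
            "participant": ["P01", "P01"],
            "start": pd.to_datetime(["2024-03-04 08:00", "2024-03-04 20:00"]),
            "end": pd.to_datetime(["2024-03-04 20:00", "2024-03-05 08:00"]),
            "urine_weight_g": [600.0, 700.0],
            "conc_hpma_ng_ml": [100.0, 120.0],
            "conc_cema_ng_ml": [80.0, 60.0],
        }
    )
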