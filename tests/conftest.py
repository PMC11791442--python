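import numpy as np
import pytest

from cvdtrends import default_engine
from cvdtrends.synthgen import DesignParams, TrendScenario


@pytest.fixture(scope="session")
def lab_engine():
    """Illustrative WHO-style laboratory models and recalibration table."""
    return default_engine("who_style", "laboratory")


@pytest.fixture(scope="session")
def nonlab_engine():
    return default_engine("who_style", "non_laboratory")


@pytest.fixture(scope="session")
def small_scenario():
    """Reduced-size scenario (~1,100 persons/year) for fast pipeline tests."""
    return TrendScenario(
        design=DesignParams(n_strata=9, psus_per_stratum=4, persons_per_psu=30),
        seed=20,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_table_and_models(rng, variant="laboratory"):
    """Random but valid table/model pair used by property tests."""
    from cvdtrends.risk_engine import (
        VARIANT_FACTORS,
        HazardModel,
        HazardTerm,
        RecalibrationCell,
        RecalibrationTable,
    )

    factors = VARIANT_FACTORS[variant]
    models = {}
    cells = []
    for sex in ("male", "female"):
        models[sex] = {}
        for outcome in ("chd", "stroke"):
            terms = tuple(
                HazardTerm(
                    f,
                    main_log_hr=rng.uniform(0.005, 0.06)
                    if f in ("sbp", "total_chol", "bmi")
                    else rng.uniform(0.3, 1.5),
                    age_interaction_log_hr=-rng.uniform(0, 5e-4)
                    if f in ("sbp", "total_chol", "bmi")
                    else -rng.uniform(0, 0.012),
                )
                for f in factors
            )
            models[sex][outcome] = HazardModel(
                outcome=outcome, sex=sex, variant=variant,
                algorithm="who_style", terms=terms,
            )
        for lo in range(40, 85, 5):
            cells.append(
                RecalibrationCell(
                    sex=sex,
                    age_lo=lo,
                    age_hi=lo + 5,
                    mean_sbp=rng.uniform(120, 150),
                    smoking_prev=rng.uniform(0.05, 0.4),
                    diabetes_prev=rng.uniform(0.02, 0.2),
                    mean_tc=rng.uniform(4.5, 6.5),
                    mean_bmi=rng.uniform(24, 30),
                    event_rates={
                        "chd": rng.uniform(0.0005, 0.03),
                        "stroke": rng.uniform(0.0005, 0.02),
                    },
                )
            )
    table = RecalibrationTable(region_label="random", base_year=2020, cells=tuple(cells))
    return models, table
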