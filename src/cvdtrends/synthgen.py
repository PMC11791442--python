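"""Synthetic multi-year survey data with the structure the analysis assumes.

Emulates, at configurable scale, the features of a repeated cross-sectional
health-examination survey that the downstream pipeline depends on:

* 17 annual cross-sections with a two-stage design (region-like strata ->
  PSUs -> individuals) and modest PSU-level clustering of blood pressure;
* secular linear trends in risk-factor means/prevalences whose defaults are
  calibrated so the first->last-year changes approximate the observed
  population deltas (SBP -8/-10 mm Hg in men/women, total cholesterol
  -0.6/-0.5 mmol/L, BMI +1.1/+1.0 kg/m2, smoking -5 percentage points in
  women, diagnosed diabetes +6/+3 points);
* staged nonresponse (interview -> nurse visit -> blood sample) with
  age/sex logistic participation, inverse-probability stage weights scaled
  to mean 1 within each year, and weights fixed at 1 before 2003;
* the pre-2003 device era: stored SBP readings are on the Dinamap scale,
  obtained by inverting the calibration regression so harmonization
  recovers the intended Omron-scale values exactly;
* banded-only ages in the last two years, a split diabetes-module year
  (2006), boost samples (2002, 2005), item missingness, and rare injected
  outliers.

Continuous factors are normal around year/sex/age-shifted means and
binaries are Bernoulli with logit age adjustments around the year trend —
a documented simplification (real risk-factor distributions are skewed).
A ``risk_index`` column carries a configurable injected linear drift for
parameter-recovery testing of the trend estimator.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError
from .harmonize import (
    ANALYSIS_YEARS,
    DINAMAP_SBP_INTERCEPT,
    DINAMAP_SBP_SLOPE,
    FIRST_WEIGHTED_YEAR,
    hba1c_mmol_to_pct,
)

FIRST_YEAR = 1998
LAST_YEAR = 2017
_SPAN = LAST_YEAR - FIRST_YEAR  # 19 calendar years of drift


class FactorTrend(BaseModel):
    """Baseline (1998) level, per-calendar-year linear drift, residual SD."""

    model_config = ConfigDict(extra="forbid")
    base: float
    drift: float = 0.0
    sd: float = Field(default=0.0, ge=0.0)

    def mean_in(self, year: int) -> float:
        return self.base + self.drift * (year - FIRST_YEAR)


class SexParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sbp: FactorTrend
    total_chol: FactorTrend
    bmi: FactorTrend
    smoking: FactorTrend  # prevalence scale; sd unused
    diabetes: FactorTrend
    risk_index: FactorTrend


class DesignParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_strata: int = Field(default=9, ge=1)  # region-like strata
    psus_per_stratum: int = Field(default=8, ge=1)
    persons_per_psu: int = Field(default=70, ge=1)
    sbp_psu_sd: float = Field(default=2.0, ge=0)
    risk_index_psu_sd: float = Field(default=0.5, ge=0)

    @property
    def persons_per_year(self) -> int:
        return self.n_strata * self.psus_per_stratum * self.persons_per_psu


class StageLogit(BaseModel):
    """Participation logit: intercept + age_coef*(age-50) + female_coef*female."""

    model_config = ConfigDict(extra="forbid")
    intercept: float
    age_coef: float
    female_coef: float = 0.0

    def prob(self, age: np.ndarray, female: np.ndarray) -> np.ndarray:
        z = self.intercept + self.age_coef * (age - 50.0) + self.female_coef * female
        return 1.0 / (1.0 + np.exp(-z))


class ParticipationModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nurse: StageLogit = StageLogit(intercept=1.7, age_coef=-0.018, female_coef=0.10)
    blood: StageLogit = StageLogit(intercept=1.1, age_coef=-0.015, female_coef=0.05)


_DEFAULT_MALE = SexParams(
    sbp=FactorTrend(base=138.0, drift=-8.0 / _SPAN, sd=16.0),
    total_chol=FactorTrend(base=6.0, drift=-0.6 / _SPAN, sd=1.05),
    bmi=FactorTrend(base=27.0, drift=1.1 / _SPAN, sd=4.4),
    smoking=FactorTrend(base=0.28, drift=-0.03 / _SPAN),
    diabetes=FactorTrend(base=0.04, drift=0.06 / _SPAN),
    risk_index=FactorTrend(base=10.0, drift=-0.09, sd=6.0),
)
_DEFAULT_FEMALE = SexParams(
    sbp=FactorTrend(base=134.0, drift=-10.0 / _SPAN, sd=17.0),
    total_chol=FactorTrend(base=6.1, drift=-0.5 / _SPAN, sd=1.10),
    bmi=FactorTrend(base=26.8, drift=1.0 / _SPAN, sd=5.0),
    smoking=FactorTrend(base=0.27, drift=-0.05 / _SPAN),
    diabetes=FactorTrend(base=0.03, drift=0.03 / _SPAN),
    risk_index=FactorTrend(base=5.6, drift=-0.09, sd=5.0),
)

# fixed age gradients around age 50 (additive for continuous factors,
# on the logit for binaries)
_AGE_SLOPES = {"sbp": 0.45, "total_chol": 0.008, "bmi": 0.01}
_AGE_LOGIT_SLOPES = {"smoking": -0.035, "diabetes": 0.055}


class TrendScenario(BaseModel):
    """Full specification of a synthetic multi-year survey."""

    model_config = ConfigDict(extra="forbid")
    years: list[int] = Field(default_factory=lambda: list(ANALYSIS_YEARS))
    male: SexParams = _DEFAULT_MALE
    female: SexParams = _DEFAULT_FEMALE
    design: DesignParams = DesignParams()
    participation: ParticipationModel = ParticipationModel()
    age_mean: float = 52.0
    age_sd: float = 16.0
    age_range: tuple[float, float] = (16.0, 90.0)
    prop_female: float = Field(default=0.51, ge=0, le=1)
    outlier_rate: float = Field(default=0.002, ge=0, le=0.05)
    anthropometry_missing_base: float = Field(default=0.04, ge=0, le=0.5)
    banded_age_years: list[int] = Field(default_factory=lambda: [2016, 2017])
    seed: int = 1

    @model_validator(mode="after")
    def _prevalences_feasible(self) -> "TrendScenario":
        for sex_name in ("male", "female"):
            params: SexParams = getattr(self, sex_name)
            for factor in ("smoking", "diabetes"):
                ft: FactorTrend = getattr(params, factor)
                for y in self.years:
                    p = ft.mean_in(y)
                    if not (0.0 < p < 1.0):
                        raise ConfigError(
                            f"{sex_name} {factor} prevalence drifts to {p:.3f} in {y}; "
                            "must stay inside (0, 1)"
                        )
        return self

    @classmethod
    def from_yaml(cls, path) -> "TrendScenario":
        from pathlib import Path

        raw = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(raw or {})


def _year_rng(seed: int, year: int) -> np.random.Generator:
    # deterministic per-year substream: adding a year never perturbs others
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(year)]))


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out >= hi)
    return out


def _rescale_mean_one(weights: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full(len(weights), np.nan)
    if mask.any():
        out[mask] = weights[mask] / weights[mask].mean()
    return out


def generate_year(scenario: TrendScenario, year: int, seed: int | None = None) -> pd.DataFrame:
    """One survey year of raw records in the harmonize input schema."""
    rng = _year_rng(scenario.seed if seed is None else seed, year)
    d = scenario.design
    n = d.persons_per_year

    stratum = np.repeat(np.arange(1, d.n_strata + 1), d.psus_per_stratum * d.persons_per_psu)
    psu_local = np.repeat(np.arange(d.n_strata * d.psus_per_stratum), d.persons_per_psu)
    psu = np.array([f"{year}-{s}-{p}" for s, p in zip(stratum, psu_local)])

    female = rng.random(n) < scenario.prop_female
    sex = np.where(female, "female", "male")
    age = _truncated_normal(
        rng, scenario.age_mean, scenario.age_sd, *scenario.age_range, n
    )

    # boost samples: 2002 child/young-adult boost year (general-population
    # subsample retained), 2005 boost of adults aged >= 65
    sample_flag = np.full(n, "general_population", dtype=object)
    if year == 2002:
        sample_flag[rng.random(n) < 0.25] = "boost"
    if year == 2005:
        boost = (age >= 65) & (rng.random(n) < 0.35)
        sample_flag[boost] = "boost"

    dy = year - FIRST_YEAR
    psu_sbp_eff = rng.normal(0.0, d.sbp_psu_sd, d.n_strata * d.psus_per_stratum)[psu_local]
    psu_ri_eff = rng.normal(0.0, d.risk_index_psu_sd, d.n_strata * d.psus_per_stratum)[psu_local]

    def per_sex(factor: str, continuous: bool) -> np.ndarray:
        out = np.empty(n)
        for sex_name, mask in (("male", ~female), ("female", female)):
            params: SexParams = getattr(scenario, sex_name)
            ft: FactorTrend = getattr(params, factor)
            m = ft.mean_in(year)
            if continuous:
                vals = m + _AGE_SLOPES[factor] * (age[mask] - 50.0) + rng.normal(
                    0.0, ft.sd, mask.sum()
                )
            else:
                logit = np.log(m / (1 - m)) + _AGE_LOGIT_SLOPES[factor] * (age[mask] - 50.0)
                vals = (rng.random(mask.sum()) < 1 / (1 + np.exp(-logit))).astype(float)
            out[mask] = vals
        return out

    sbp_latent = per_sex("sbp", True) + psu_sbp_eff
    total_chol = per_sex("total_chol", True)
    bmi = np.clip(per_sex("bmi", True), 15.0, None)
    smoker = per_sex("smoking", False).astype(bool)
    diabetes = per_sex("diabetes", False).astype(bool)

    risk_index = np.empty(n)
    for sex_name, mask in (("male", ~female), ("female", female)):
        ft = getattr(scenario, sex_name).risk_index
        risk_index[mask] = ft.mean_in(year) + rng.normal(0.0, ft.sd, mask.sum())
    risk_index += psu_ri_eff

    height = np.where(female, rng.normal(1.62, 0.065, n), rng.normal(1.76, 0.07, n))
    weight = bmi * height**2

    # staged participation (everyone in the frame completed the interview)
    p_nurse = scenario.participation.nurse.prob(age, female.astype(float))
    nurse = rng.random(n) < p_nurse
    p_blood = scenario.participation.blood.prob(age, female.astype(float))
    blood = nurse & (rng.random(n) < p_blood)

    # three seated SBP readings on the Omron scale: first-reading elevation,
    # per-reading noise, occasional protocol violations
    readings = (
        sbp_latent[:, None]
        + np.array([2.5, 0.0, 0.0])
        + rng.normal(0.0, 3.0, (n, 3))
    )
    valid = rng.random((n, 3)) >= 0.03
    readings[~nurse] = np.nan
    valid[~nurse] = False

    # item missingness: anthropometry propensity rises with age
    p_miss = scenario.anthropometry_missing_base * np.exp(0.02 * (age - 50.0))
    miss_anthro = rng.random(n) < np.clip(p_miss, 0, 0.9)
    height[miss_anthro] = np.nan
    weight[miss_anthro] = np.nan
    smoker_f = smoker.astype(float)
    smoker_f[rng.random(n) < 0.01] = np.nan
    diab_f = diabetes.astype(float)
    diab_f[rng.random(n) < 0.01] = np.nan
    total_chol = np.where(blood, total_chol, np.nan)

    # HbA1c: mmol/mol latent; percent-era storage before 2012; calibrator
    # flag from late-2013 fieldwork onward
    hba1c_mmol = rng.normal(37.0, 6.0, n) + 16.0 * diabetes
    hba1c_mmol = np.where(blood, hba1c_mmol, np.nan)
    if year < 2012:
        hba1c_unit = "percent"
        hba1c = hba1c_mmol_to_pct(hba1c_mmol)
    else:
        hba1c_unit = "mmol_per_mol"
        hba1c = hba1c_mmol
    if year >= 2014:
        needs_adj = np.ones(n, dtype=bool)
    elif year == 2013:
        needs_adj = rng.random(n) < 0.25
    else:
        needs_adj = np.zeros(n, dtype=bool)

    # rare gross outliers (entered before any filtering downstream)
    n_out = rng.binomial(n, scenario.outlier_rate)
    if n_out:
        idx = rng.choice(n, n_out, replace=False)
        kind = rng.integers(0, 4, n_out)
        sel = idx[kind == 0]
        readings[sel] = rng.choice([40.0, 300.0], len(sel))[:, None]
        sel = idx[kind == 1]
        weight[sel] = rng.choice([20.0, 280.0], len(sel))
        sel = idx[kind == 2]
        height[sel] = rng.choice([1.0, 2.4], len(sel))
        sel = idx[kind == 3]
        total_chol[sel] = np.where(
            np.isnan(total_chol[sel]), np.nan, rng.choice([1.0, 25.0], len(sel))
        )
        readings[~nurse] = np.nan  # injection never reaches unmeasured stages

    # device era: store pre-2003 readings on the Dinamap scale by inverting
    # the calibration regression, so harmonization recovers the Omron values
    if year < FIRST_WEIGHTED_YEAR:  # pre-2003 is also the Dinamap era
        device = "dinamap"
        stored = (readings - DINAMAP_SBP_INTERCEPT) / DINAMAP_SBP_SLOPE
    else:
        device = "omron"
        stored = readings

    # stage weights: inverse participation probability among respondents,
    # rescaled to mean 1 within the year; fixed at 1 before 2003
    if year >= FIRST_WEIGHTED_YEAR:
        w_nurse = _rescale_mean_one(1.0 / p_nurse, nurse)
        w_blood = _rescale_mean_one(1.0 / (p_nurse * p_blood), blood)
        w_int = np.ones(n)
    else:
        w_int = np.ones(n)
        w_nurse = np.where(nurse, 1.0, np.nan)
        w_blood = np.where(blood, 1.0, np.nan)

    # split diabetes/CVD interview module (2006: random half of ages >= 65)
    cvd_module = np.ones(n, dtype=bool)
    if year == 2006:
        older = age >= 65
        cvd_module[older] = rng.random(older.sum()) < 0.5
        diab_f[~cvd_module] = np.nan

    banded = year in scenario.banded_age_years
    band_lo = (np.floor(age / 5.0) * 5).astype(float)
    band_hi = band_lo + 4.0
    open_band = band_lo >= 90
    band_hi[open_band] = np.nan

    df = pd.DataFrame(
        {
            "survey_year": year,
            "sample_flag": sample_flag,
            "sex": sex,
            "age_continuous": np.where(banded, np.nan, age),
            "age_band_lo": band_lo if banded else np.nan,
            "age_band_hi": band_hi if banded else np.nan,
            "sbp1": stored[:, 0],
            "sbp2": stored[:, 1],
            "sbp3": stored[:, 2],
            "sbp1_valid": valid[:, 0],
            "sbp2_valid": valid[:, 1],
            "sbp3_valid": valid[:, 2],
            "bp_device": device,
            "height_m": height,
            "weight_kg": weight,
            "smoker_current": smoker_f,
            "diagnosed_diabetes": diab_f,
            "total_chol": total_chol,
            "hba1c": hba1c,
            "hba1c_unit": hba1c_unit,
            "hba1c_needs_adjustment": needs_adj,
            "cvd_module": cvd_module,
            "interview": True,
            "nurse": nurse,
            "blood": blood,
            "weight_interview": w_int,
            "weight_nurse": w_nurse,
            "weight_blood": w_blood,
            "psu": psu,
            "stratum": stratum,
            "risk_index": risk_index,
        }
    )
    # cholesterol stored on the era's assay scale: 2011-2014 calibrators read
    # 0.1 mmol/L high, so the stored raw value sits above the harmonized one
    if 2011 <= year <= 2014:
        df["total_chol"] = df["total_chol"] + 0.1
    return df


def generate(scenario: TrendScenario, seed: int | None = None) -> dict[int, pd.DataFrame]:
    """All survey years of a scenario; keyed by year, byte-stable given seed."""
    return {y: generate_year(scenario, y, seed) for y in scenario.years}


def generate_pooled(scenario: TrendScenario, seed: int | None = None) -> pd.DataFrame:
    frames = generate(scenario, seed)
    return pd.concat(frames.values(), ignore_index=True)


# ---------------------------------------------------------------------------
# canned edge-case fixtures (tiny, deterministic, constructed in code)
# ---------------------------------------------------------------------------

#: expected per-status counts of the "flow" fixture under the laboratory
#: variant, by construction (see make_fixture)
FLOW_EXPECTED_LAB = {
    "eligible": 4,
    "boost_year": 2,
    "year_not_in_variant": 1,
    "boost_sample": 1,
    "age_range": 2,
    "missing_component": 3,
    "missing_weight": 1,
}


def _base_row(**over) -> dict:
    row = dict(
        survey_year=2012,
        sample_flag="general_population",
        sex="male",
        age_continuous=55.0,
        age_band_lo=np.nan,
        age_band_hi=np.nan,
        sbp1=132.0,
        sbp2=128.0,
        sbp3=126.0,
        sbp1_valid=True,
        sbp2_valid=True,
        sbp3_valid=True,
        bp_device="omron",
        height_m=1.76,
        weight_kg=82.0,
        smoker_current=False,
        diagnosed_diabetes=False,
        total_chol=5.6,
        hba1c=38.0,
        hba1c_unit="mmol_per_mol",
        hba1c_needs_adjustment=False,
        cvd_module=True,
        interview=True,
        nurse=True,
        blood=True,
        weight_interview=1.0,
        weight_nurse=1.1,
        weight_blood=1.2,
        psu="P1",
        stratum=1,
        risk_index=8.0,
    )
    row.update(over)
    return row


def make_fixture(name: str) -> pd.DataFrame:
    """Small deterministic datasets for edge-case tests.

    ``edge_bp``: SBP outlier boundaries (60 survives, 59 does not; 270 vs
    271), a Dinamap-era record, and <3-valid-readings cases.
    ``flow``: one record per exclusion reason with known audit counts
    (:data:`FLOW_EXPECTED_LAB`).
    ``banded_age``: banded-only ages including an open-ended top band.
    ``split_module``: 2006-style records with and without the CVD module.
    ``missing_weights``: weighted-year records lacking stage weights.
    """
    if name == "edge_bp":
        rows = [
            # boundary values survive the strict filters
            _base_row(psu="P1", sbp1=60.0, sbp2=60.0, sbp3=60.0),
            _base_row(psu="P2", sbp1=59.0, sbp2=59.0, sbp3=59.0),
            _base_row(psu="P3", sbp1=270.0, sbp2=270.0, sbp3=270.0),
            _base_row(psu="P4", sbp1=271.0, sbp2=271.0, sbp3=271.0),
            # second reading invalid: strict rule -> missing SBP
            _base_row(psu="P5", sbp1=130.0, sbp2=124.0, sbp3=126.0, sbp2_valid=False),
            # only two readings taken
            _base_row(psu="P6", sbp1=130.0, sbp2=124.0, sbp3=np.nan),
            # Dinamap era: stored readings convert to Omron 128/124/126
            _base_row(
                psu="P7",
                survey_year=1998,
                bp_device="dinamap",
                sbp1=(128.0 - DINAMAP_SBP_INTERCEPT) / DINAMAP_SBP_SLOPE,
                sbp2=(124.0 - DINAMAP_SBP_INTERCEPT) / DINAMAP_SBP_SLOPE,
                sbp3=(126.0 - DINAMAP_SBP_INTERCEPT) / DINAMAP_SBP_SLOPE,
                weight_nurse=np.nan,
                weight_blood=np.nan,
            ),
        ]
        return pd.DataFrame(rows)
    if name == "flow":
        rows = [
            _base_row(psu="E1"),
            _base_row(psu="E2", stratum=2),
            _base_row(psu="E3"),
            _base_row(psu="E4", stratum=2),
            _base_row(psu="X1", survey_year=1999),
            _base_row(psu="X2", survey_year=2004),
            _base_row(psu="X3", survey_year=2001),  # non-lab-only year
            _base_row(psu="X4", survey_year=2006, sample_flag="boost"),
            _base_row(psu="X5", age_continuous=39.0),
            _base_row(psu="X6", age_continuous=75.0),
            _base_row(psu="X7", total_chol=np.nan),
            _base_row(psu="X8", sbp2_valid=False),
            _base_row(psu="X9", diagnosed_diabetes=np.nan),
            _base_row(psu="X10", weight_blood=np.nan),
        ]
        return pd.DataFrame(rows)
    if name == "banded_age":
        rows = [
            _base_row(psu=f"B{i}", survey_year=2016, age_continuous=np.nan,
                      age_band_lo=lo, age_band_hi=hi)
            for i, (lo, hi) in enumerate([(40, 44), (70, 74), (75, 79), (90, np.nan)])
        ]
        return pd.DataFrame(rows)
    if name == "split_module":
        rows = [
            _base_row(psu="M1", survey_year=2006, age_continuous=70.0, cvd_module=True),
            _base_row(psu="M2", survey_year=2006, age_continuous=70.0, cvd_module=False,
                      diagnosed_diabetes=np.nan),
            _base_row(psu="M3", survey_year=2006, age_continuous=50.0, cvd_module=True),
        ]
        return pd.DataFrame(rows)
    if name == "missing_weights":
        rows = [
            _base_row(psu="W1"),
            _base_row(psu="W2", weight_blood=np.nan),
            _base_row(psu="W3", weight_nurse=np.nan, weight_blood=1.0),
        ]
        return pd.DataFrame(rows)
    raise KeyError(f"unknown fixture: {name!r}")
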