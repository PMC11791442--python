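"""Loading and validation of hazard-coefficient / recalibration tables.

The risk engine is fully table-driven. Real analyses supply the published
coefficient sets and national recalibration inputs (group mean risk-factor
levels and annual CHD/stroke event rates) as a YAML config with schema::

    algorithm: who_style | globorisk_style
    variant: laboratory | non_laboratory
    region_label: <text>
    base_year: <calendar year>
    models:
      - sex: male | female
        outcome: chd | stroke | cvd
        terms:
          - {risk_factor: sbp, main_log_hr: 0.05, age_interaction_log_hr: -0.0005}
          ...
    cells:
      - {sex: male, age_lo: 40, age_hi: 45, mean_sbp: 126.0, smoking_prev: 0.30,
         diabetes_prev: 0.03, mean_tc: 5.6, mean_bmi: 27.0,
         event_rates: {chd: 0.0015, stroke: 0.0007}}
      ...

The defaults built by :func:`illustrative_tables` are ILLUSTRATIVE ONLY:
they have plausible epidemiologic magnitudes (positive, age-attenuating
log-HRs; event rates rising with age; men above women for CHD) but are NOT
the published WHO or Globorisk coefficients, which are not reproduced here.
Results computed with them demonstrate the machinery, not published risks.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError
from .risk_engine import (
    HazardModel,
    HazardTerm,
    RecalibrationCell,
    RecalibrationTable,
)


class _TermSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    risk_factor: str
    main_log_hr: float
    age_interaction_log_hr: float = 0.0


class _ModelSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sex: Literal["male", "female"]
    outcome: Literal["chd", "stroke", "cvd"]
    terms: list[_TermSpec] = Field(min_length=1)


class _CellSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sex: Literal["male", "female"]
    age_lo: float
    age_hi: float
    mean_sbp: float
    smoking_prev: float = Field(ge=0, le=1)
    diabetes_prev: float = Field(ge=0, le=1)
    mean_tc: float
    mean_bmi: float
    event_rates: dict[str, float]


class TableConfig(BaseModel):
    """Validated on-disk representation of one algorithm x variant table set."""

    model_config = ConfigDict(extra="forbid")
    algorithm: Literal["who_style", "globorisk_style"]
    variant: Literal["laboratory", "non_laboratory"]
    region_label: str
    base_year: int
    models: list[_ModelSpec] = Field(min_length=1)
    cells: list[_CellSpec] = Field(min_length=1)

    def build(self) -> tuple[dict[str, dict[str, HazardModel]], RecalibrationTable]:
        """Materialize engine objects: (sex -> outcome -> model, table)."""
        models: dict[str, dict[str, HazardModel]] = {}
        for m in self.models:
            hm = HazardModel(
                outcome=m.outcome,
                sex=m.sex,
                variant=self.variant,
                algorithm=self.algorithm,
                terms=tuple(
                    HazardTerm(t.risk_factor, t.main_log_hr, t.age_interaction_log_hr)
                    for t in m.terms
                ),
            )
            if m.outcome in models.setdefault(m.sex, {}):
                raise ConfigError(f"duplicate model for sex={m.sex}, outcome={m.outcome}")
            models[m.sex][m.outcome] = hm
        table = RecalibrationTable(
            region_label=self.region_label,
            base_year=self.base_year,
            cells=tuple(
                RecalibrationCell(
                    sex=c.sex,
                    age_lo=c.age_lo,
                    age_hi=c.age_hi,
                    mean_sbp=c.mean_sbp,
                    smoking_prev=c.smoking_prev,
                    diabetes_prev=c.diabetes_prev,
                    mean_tc=c.mean_tc,
                    mean_bmi=c.mean_bmi,
                    event_rates=dict(c.event_rates),
                )
                for c in self.cells
            ),
        )
        return models, table


def load_table_config(path: str | Path) -> TableConfig:
    """Read and validate a YAML table config; raise ConfigError with context."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return TableConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_table_config(cfg: TableConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


# ---------------------------------------------------------------------------
# illustrative defaults
# ---------------------------------------------------------------------------

#: 5-year age bands on attained age covering [40, 85)
_BANDS = [(a, a + 5) for a in range(40, 85, 5)]

# Group mean risk-factor levels by sex and band index (40-44 ... 80-84).
# Magnitudes chosen to look like a contemporary high-income population:
# SBP and diabetes rise with age, smoking falls, cholesterol peaks mid-life.
_MEANS = {
    "male": {
        "mean_sbp": [126, 128, 131, 134, 137, 140, 142, 144, 146],
        "smoking_prev": [0.30, 0.28, 0.26, 0.23, 0.20, 0.17, 0.14, 0.11, 0.09],
        "diabetes_prev": [0.03, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14, 0.15, 0.16],
        "mean_tc": [5.6, 5.8, 5.9, 5.9, 5.8, 5.7, 5.6, 5.5, 5.4],
        "mean_bmi": [27.2, 27.5, 27.7, 27.8, 27.8, 27.7, 27.5, 27.2, 26.8],
    },
    "female": {
        "mean_sbp": [120, 123, 127, 131, 135, 139, 142, 145, 148],
        "smoking_prev": [0.27, 0.25, 0.23, 0.21, 0.18, 0.15, 0.12, 0.10, 0.08],
        "diabetes_prev": [0.02, 0.03, 0.04, 0.05, 0.07, 0.09, 0.11, 0.12, 0.13],
        "mean_tc": [5.4, 5.6, 5.9, 6.1, 6.2, 6.2, 6.1, 6.0, 5.9],
        "mean_bmi": [26.8, 27.1, 27.4, 27.6, 27.7, 27.7, 27.6, 27.4, 27.0],
    },
}

# Annual first-event rates per person-year by band; roughly exponential in
# age, men above women for CHD, stroke closer between sexes.
_RATES = {
    "male": {
        "chd": [0.0016, 0.0026, 0.0040, 0.0059, 0.0086, 0.0122, 0.0170, 0.0232, 0.0310],
        "stroke": [0.0006, 0.0009, 0.0015, 0.0023, 0.0036, 0.0055, 0.0083, 0.0124, 0.0183],
    },
    "female": {
        "chd": [0.0005, 0.0009, 0.0015, 0.0025, 0.0040, 0.0063, 0.0097, 0.0146, 0.0215],
        "stroke": [0.0005, 0.0008, 0.0013, 0.0021, 0.0033, 0.0051, 0.0078, 0.0118, 0.0175],
    },
}

# Main / age-interaction log-HRs per factor, outcome, sex. Age attenuation
# (negative interaction) reflects the usual decline of proportional effects
# with age. Globorisk-style sets differ modestly, with stronger smoking and
# diabetes effects in women.
_LOG_HRS = {
    "who_style": {
        "chd": {
            "male": {
                "sbp": (0.052, -0.00050),
                "current_smoker": (1.30, -0.0110),
                "diabetes": (1.50, -0.0130),
                "total_chol": (0.62, -0.0065),
                "bmi": (0.105, -0.0011),
            },
            "female": {
                "sbp": (0.050, -0.00048),
                "current_smoker": (1.42, -0.0120),
                "diabetes": (1.70, -0.0145),
                "total_chol": (0.58, -0.0060),
                "bmi": (0.100, -0.0010),
            },
        },
        "stroke": {
            "male": {
                "sbp": (0.068, -0.00066),
                "current_smoker": (0.95, -0.0080),
                "diabetes": (1.10, -0.0095),
                "total_chol": (0.12, -0.0010),
                "bmi": (0.070, -0.0007),
            },
            "female": {
                "sbp": (0.066, -0.00064),
                "current_smoker": (1.05, -0.0090),
                "diabetes": (1.25, -0.0105),
                "total_chol": (0.10, -0.0009),
                "bmi": (0.065, -0.0006),
            },
        },
    },
}
# Globorisk-style: scale WHO-style coefficients, boost female smoking/diabetes.
_GLOBORISK_SCALE = {"sbp": 0.95, "current_smoker": 1.00, "diabetes": 1.00,
                    "total_chol": 0.90, "bmi": 0.95}
_GLOBORISK_FEMALE_BOOST = {"current_smoker": 1.15, "diabetes": 1.12}
#: Globorisk-style illustrative event rates are lower (fatal-weighted source
#: mix), giving systematically lower absolute scores.
_GLOBORISK_RATE_SCALE = 0.70


def _terms_for(algorithm: str, outcome: str, sex: str, factors: tuple[str, ...]) -> list[_TermSpec]:
    base = _LOG_HRS["who_style"][outcome][sex]
    terms = []
    for f in factors:
        main, inter = base[f]
        if algorithm == "globorisk_style":
            scale = _GLOBORISK_SCALE[f]
            if sex == "female":
                scale *= _GLOBORISK_FEMALE_BOOST.get(f, 1.0)
            main, inter = main * scale, inter * scale
        terms.append(_TermSpec(risk_factor=f, main_log_hr=round(main, 6),
                               age_interaction_log_hr=round(inter, 7)))
    return terms


def illustrative_tables(algorithm: str, variant: str) -> TableConfig:
    """Build the illustrative default config for one algorithm x variant.

    These numbers are invented for demonstration and testing; they are not
    the published WHO or Globorisk coefficients or recalibration inputs.
    """
    if algorithm not in ("who_style", "globorisk_style"):
        raise ConfigError(f"unknown algorithm: {algorithm!r}")
    if variant not in ("laboratory", "non_laboratory"):
        raise ConfigError(f"unknown variant: {variant!r}")
    factors = ("sbp", "current_smoker", "diabetes", "total_chol") if variant == "laboratory" \
        else ("sbp", "current_smoker", "bmi")
    rate_scale = _GLOBORISK_RATE_SCALE if algorithm == "globorisk_style" else 1.0
    models = [
        _ModelSpec(sex=sex, outcome=outcome, terms=_terms_for(algorithm, outcome, sex, factors))
        for sex in ("male", "female")
        for outcome in ("chd", "stroke")
    ]
    cells = [
        _CellSpec(
            sex=sex,
            age_lo=lo,
            age_hi=hi,
            mean_sbp=_MEANS[sex]["mean_sbp"][i],
            smoking_prev=_MEANS[sex]["smoking_prev"][i],
            diabetes_prev=_MEANS[sex]["diabetes_prev"][i],
            mean_tc=_MEANS[sex]["mean_tc"][i],
            mean_bmi=_MEANS[sex]["mean_bmi"][i],
            event_rates={
                "chd": round(_RATES[sex]["chd"][i] * rate_scale, 6),
                "stroke": round(_RATES[sex]["stroke"][i] * rate_scale, 6),
            },
        )
        for sex in ("male", "female")
        for i, (lo, hi) in enumerate(_BANDS)
    ]
    return TableConfig(
        algorithm=algorithm,
        variant=variant,
        region_label="illustrative-GB",
        base_year=2020,
        models=models,
        cells=cells,
    )


def default_engine(algorithm: str, variant: str):
    """(models_by_sex, table) built from the illustrative defaults."""
    return illustrative_tables(algorithm, variant).build()
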