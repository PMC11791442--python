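"""Recalibrated 10-year total CVD risk engine.

Implements the standard recalibration arithmetic used by global CVD risk
scores (WHO-style and Globorisk-style): hazard ratios with age-interacting
log-HR coefficients are applied to the *distance* between an individual's
risk-factor profile and group (sex x age band) mean levels; the joint HR
scales group-specific annual event rates into one-year risks; one-year
survivals ``exp(-risk)`` are accumulated over a 10-year horizon (follow-up
years 0..9), and the cumulative risk in the final year is the predicted
absolute 10-year risk.

The engine is fully table-driven: coefficients and recalibration inputs are
supplied as :class:`HazardModel` / :class:`RecalibrationTable` objects
(loaded from YAML via :mod:`cvdtrends.tables`, which also provides
clearly-labelled illustrative defaults). Two score variants exist:

* ``laboratory``: SBP, current smoking, diagnosed diabetes, total cholesterol
* ``non_laboratory``: SBP, current smoking, BMI

Outcome-specific (CHD and stroke) models are recalibrated separately and
combined by summing cause-specific one-year hazards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, CoverageError, InvalidInputError, ScoringIneligibleError

Sex = Literal["male", "female"]
Outcome = Literal["chd", "stroke", "cvd"]
Variant = Literal["laboratory", "non_laboratory"]
Algorithm = Literal["who_style", "globorisk_style"]

#: components each variant requires, in canonical order
VARIANT_FACTORS: dict[str, tuple[str, ...]] = {
    "laboratory": ("sbp", "current_smoker", "diabetes", "total_chol"),
    "non_laboratory": ("sbp", "current_smoker", "bmi"),
}

#: map risk-factor name -> recalibration-cell mean attribute
_CELL_MEAN_ATTR = {
    "sbp": "mean_sbp",
    "current_smoker": "smoking_prev",
    "diabetes": "diabetes_prev",
    "total_chol": "mean_tc",
    "bmi": "mean_bmi",
}

HORIZON_YEARS = 10

CATEGORY_LABELS = ("very_low", "low", "moderate", "high", "very_high")
#: left-closed, right-open cutpoints on the proportion scale
CATEGORY_CUTS = (0.05, 0.10, 0.20, 0.30)


@dataclass(frozen=True)
class RiskFactorProfile:
    """One participant's scoring inputs.

    Binary factors are booleans; ``None`` marks a missing component. Age is
    baseline (year-0) age in years and must lie in [40, 75).
    """

    sex: Sex
    age: float
    sbp: float | None = None
    current_smoker: bool | None = None
    diabetes: bool | None = None
    total_chol: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"unknown sex: {self.sex!r}")
        if not math.isfinite(self.age) or not (40 <= self.age < 75):
            raise InvalidInputError(f"baseline age must be in [40, 75): got {self.age}")

    def value(self, risk_factor: str) -> float | None:
        """Numeric value of a factor (binaries coded 0/1); None if missing."""
        v = getattr(self, risk_factor)
        if v is None:
            return None
        return float(v)


@dataclass(frozen=True)
class HazardTerm:
    """Main and age-interaction log hazard-ratio coefficients for one factor."""

    risk_factor: str
    main_log_hr: float
    age_interaction_log_hr: float = 0.0

    def __post_init__(self) -> None:
        for name in ("main_log_hr", "age_interaction_log_hr"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigError(f"{self.risk_factor}: {name} must be finite, got {v}")


@dataclass(frozen=True)
class HazardModel:
    """Outcome-, sex-, and variant-specific set of hazard terms.

    Sex differences (for Globorisk-style scores) are realized as separate
    sex-specific coefficient sets rather than explicit interaction terms.
    """

    outcome: Outcome
    sex: Sex
    variant: Variant
    algorithm: Algorithm
    terms: tuple[HazardTerm, ...]

    def __post_init__(self) -> None:
        factors = [t.risk_factor for t in self.terms]
        if len(set(factors)) != len(factors):
            raise ConfigError(f"duplicate risk factor in model terms: {factors}")
        required = set(VARIANT_FACTORS[self.variant])
        if set(factors) != required:
            raise ConfigError(
                f"{self.variant} model must cover exactly {sorted(required)}, got {sorted(factors)}"
            )

    def term(self, risk_factor: str) -> HazardTerm:
        for t in self.terms:
            if t.risk_factor == risk_factor:
                return t
        raise KeyError(risk_factor)


@dataclass(frozen=True)
class RecalibrationCell:
    """Group mean risk-factor levels and annual event rates for one sex x age band.

    ``age_band`` is half-open [lo, hi) on attained age; prevalences stand in
    for means of the 0/1-coded binary factors.
    """

    sex: Sex
    age_lo: float
    age_hi: float
    mean_sbp: float
    smoking_prev: float
    diabetes_prev: float
    mean_tc: float
    mean_bmi: float
    event_rates: Mapping[str, float]  # outcome -> events per person-year

    def __post_init__(self) -> None:
        if not self.age_lo < self.age_hi:
            raise ConfigError(f"bad age band [{self.age_lo}, {self.age_hi})")
        for name in ("smoking_prev", "diabetes_prev"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        for outcome, rate in self.event_rates.items():
            if rate < 0:
                raise ConfigError(f"negative event rate for {outcome}: {rate}")

    def mean(self, risk_factor: str) -> float:
        return float(getattr(self, _CELL_MEAN_ATTR[risk_factor]))


@dataclass(frozen=True)
class RecalibrationTable:
    """Collection of recalibration cells; lookup by (sex, attained age).

    Age bands must be disjoint per sex and cover the attained-age range
    [40, 85) needed to follow a participant aged up to 74 for 10 years.
    """

    region_label: str
    base_year: int
    cells: tuple[RecalibrationCell, ...]

    def __post_init__(self) -> None:
        for sex in ("male", "female"):
            bands = sorted(
                [(c.age_lo, c.age_hi) for c in self.cells if c.sex == sex]
            )
            if not bands:
                raise ConfigError(f"no recalibration cells for sex={sex}")
            if bands[0][0] > 40 or bands[-1][1] < 85:
                raise ConfigError(
                    f"{sex} cells must cover attained ages [40, 85), got [{bands[0][0]}, {bands[-1][1]})"
                )
            for (lo1, hi1), (lo2, _hi2) in zip(bands, bands[1:]):
                if lo2 < hi1:
                    raise ConfigError(f"overlapping {sex} age bands [{lo1},{hi1}) and [{lo2},..)")
                if lo2 > hi1:
                    raise ConfigError(f"gap in {sex} age bands between {hi1} and {lo2}")

    def lookup(self, sex: Sex, attained_age: float) -> RecalibrationCell:
        for c in self.cells:
            if c.sex == sex and c.age_lo <= attained_age < c.age_hi:
                return c
        raise CoverageError(
            f"no recalibration cell for sex={sex}, attained age {attained_age}"
        )


@dataclass(frozen=True)
class RiskTrajectory:
    """Year-by-year (t = 0..9) intermediates of the 10-year risk calculation."""

    attained_age: tuple[float, ...]
    joint_hr: tuple[float, ...]
    one_year_risk: tuple[float, ...]
    one_year_survival: tuple[float, ...]
    cumulative_survival: tuple[float, ...]
    cumulative_risk: tuple[float, ...]


@dataclass(frozen=True)
class RiskScore:
    """Final predicted absolute 10-year risk and its category."""

    ten_year_risk: float
    category: str
    variant: Variant
    algorithm: Algorithm
    trajectory: RiskTrajectory | None = field(default=None, compare=False)


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def term_hr(
    term: HazardTerm,
    individual_value: float,
    group_mean: float,
    attained_age: float,
) -> float:
    """Risk-factor-specific hazard ratio for one follow-up year.

    exp((main + interaction * attained_age) * (individual - group_mean)).
    Binary factors are coded 0/1 with the group prevalence as the mean.
    """
    for label, v in (
        ("individual value", individual_value),
        ("group mean", group_mean),
        ("attained age", attained_age),
    ):
        if v is None or not math.isfinite(v):
            raise InvalidInputError(
                f"non-finite {label} for risk factor {term.risk_factor!r}: {v}"
            )
    loghr = term.main_log_hr + term.age_interaction_log_hr * attained_age
    return math.exp(loghr * (individual_value - group_mean))


def joint_hr(
    profile: RiskFactorProfile,
    model: HazardModel,
    cell: RecalibrationCell,
    attained_age: float,
) -> float:
    """Product of the risk-factor-specific HRs over the model's terms.

    Equals 1 exactly when the profile sits at the cell's means/prevalences.
    """
    out = 1.0
    for term in model.terms:
        x = profile.value(term.risk_factor)
        if x is None:
            raise ScoringIneligibleError(
                f"profile missing {term.risk_factor!r} required by the {model.variant} variant"
            )
        out *= term_hr(term, x, cell.mean(term.risk_factor), attained_age)
    return out


def one_year_step(joint_hr_value: float, event_rate: float) -> tuple[float, float]:
    """One-year risk and survival: risk = HR x rate, survival = exp(-risk)."""
    if not math.isfinite(joint_hr_value) or joint_hr_value <= 0:
        raise InvalidInputError(f"joint HR must be positive and finite, got {joint_hr_value}")
    if not math.isfinite(event_rate) or event_rate < 0:
        raise ConfigError(f"annual event rate must be >= 0, got {event_rate}")
    risk = joint_hr_value * event_rate
    return risk, math.exp(-risk)


def accumulate(one_year_survivals: Sequence[float]) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Cumulative survival (running product) and cumulative risk (1 - it)."""
    if len(one_year_survivals) != HORIZON_YEARS:
        raise InvalidInputError(
            f"expected {HORIZON_YEARS} yearly survivals, got {len(one_year_survivals)}"
        )
    cum_surv: list[float] = []
    running = 1.0
    for s in one_year_survivals:
        if not (0 < s <= 1):
            raise InvalidInputError(f"one-year survival must be in (0, 1], got {s}")
        running *= s
        cum_surv.append(running)
    return tuple(cum_surv), tuple(1.0 - s for s in cum_surv)


def categorize(risk: float) -> str:
    """Risk category on the conventional 5/10/20/30% cutoffs.

    Bands are left-closed, right-open: [0,5%) very_low, [5,10%) low,
    [10,20%) moderate, [20,30%) high, [30%,100%] very_high.
    """
    if not math.isfinite(risk) or not (0 <= risk <= 1):
        raise InvalidInputError(f"risk must be a proportion in [0,1], got {risk}")
    idx = 0
    for cut in CATEGORY_CUTS:
        if risk >= cut:
            idx += 1
    return CATEGORY_LABELS[idx]


def _clip_final_risk(risk: float) -> float:
    if risk < 0 or risk > 1:
        if min(abs(risk), abs(risk - 1)) > 1e-9:
            warnings.warn(
                f"final 10-year risk {risk} outside [0,1] by more than 1e-9; clipping",
                RuntimeWarning,
                stacklevel=3,
            )
        risk = min(max(risk, 0.0), 1.0)
    return risk


def _combined_one_year_risk(risks_by_outcome: dict[str, float], mode: str) -> float:
    # Both modes coincide exactly under survival = exp(-risk):
    # exp(-(r_chd + r_stroke)) == exp(-r_chd) * exp(-r_stroke).
    if mode not in ("sum_hazards", "product_of_survivals"):
        raise ConfigError(f"unknown combination mode: {mode!r}")
    return sum(risks_by_outcome.values())


def ten_year_risk(
    profile: RiskFactorProfile,
    models: Mapping[str, HazardModel] | HazardModel,
    table: RecalibrationTable,
    *,
    combination: str = "sum_hazards",
    age_basis: Literal["attained", "baseline"] = "attained",
) -> RiskScore:
    """Predicted absolute 10-year total CVD risk for one participant.

    For each follow-up year t = 0..9 the attained age is baseline age + t;
    the recalibration cell is looked up by attained age (or held at the
    baseline cell when ``age_basis='baseline'``, the age interaction always
    uses attained age); outcome-specific one-year risks (joint HR x annual
    event rate) are combined across CHD and stroke; one-year survivals
    ``exp(-risk)`` accumulate multiplicatively. The cumulative risk at t = 9
    is the 10-year risk.
    """
    if isinstance(models, HazardModel):
        models = {models.outcome: models}
    if not models:
        raise ConfigError("at least one outcome-specific hazard model is required")
    variants = {m.variant for m in models.values()}
    algorithms = {m.algorithm for m in models.values()}
    if len(variants) != 1 or len(algorithms) != 1:
        raise ConfigError("all outcome models must share one variant and algorithm")
    for m in models.values():
        if m.sex != profile.sex:
            raise ConfigError(f"model sex {m.sex} does not match profile sex {profile.sex}")

    attained_ages: list[float] = []
    joint_hrs: list[float] = []
    risks: list[float] = []
    survs: list[float] = []
    baseline_cell = None
    if age_basis == "baseline":
        baseline_cell = table.lookup(profile.sex, profile.age)
    elif age_basis != "attained":
        raise ConfigError(f"unknown age basis: {age_basis!r}")

    for t in range(HORIZON_YEARS):
        aa = profile.age + t
        try:
            cell = baseline_cell if baseline_cell is not None else table.lookup(profile.sex, aa)
        except CoverageError as exc:
            raise CoverageError(
                f"attained age {aa} in follow-up year {t} outside table coverage", year=t
            ) from exc
        by_outcome: dict[str, float] = {}
        jhr_prod = 1.0
        for outcome, model in models.items():
            if outcome not in cell.event_rates:
                raise ConfigError(f"recalibration cell lacks event rate for outcome {outcome!r}")
            jhr = joint_hr(profile, model, cell, aa)
            r, _s = one_year_step(jhr, cell.event_rates[outcome])
            by_outcome[outcome] = r
            jhr_prod *= jhr
        r_total = _combined_one_year_risk(by_outcome, combination)
        attained_ages.append(aa)
        joint_hrs.append(jhr_prod)
        risks.append(r_total)
        survs.append(math.exp(-r_total))

    cum_surv, cum_risk = accumulate(survs)
    final = _clip_final_risk(cum_risk[-1])
    variant = next(iter(variants))
    algorithm = next(iter(algorithms))
    traj = RiskTrajectory(
        attained_age=tuple(attained_ages),
        joint_hr=tuple(joint_hrs),
        one_year_risk=tuple(risks),
        one_year_survival=tuple(survs),
        cumulative_survival=cum_surv,
        cumulative_risk=cum_risk,
    )
    return RiskScore(
        ten_year_risk=final,
        category=categorize(final),
        variant=variant,
        algorithm=algorithm,
        trajectory=traj,
    )


# ---------------------------------------------------------------------------
# vectorized batch scorer
# ---------------------------------------------------------------------------

def _cell_arrays(table: RecalibrationTable, sex: Sex) -> dict[str, np.ndarray]:
    cells = sorted([c for c in table.cells if c.sex == sex], key=lambda c: c.age_lo)
    arr = {
        "lo": np.array([c.age_lo for c in cells]),
        "hi": np.array([c.age_hi for c in cells]),
    }
    for factor, attr in _CELL_MEAN_ATTR.items():
        arr[factor] = np.array([getattr(c, attr) for c in cells], dtype=float)
    outcomes = set().union(*(c.event_rates.keys() for c in cells))
    for o in outcomes:
        arr[f"rate_{o}"] = np.array([c.event_rates[o] for c in cells], dtype=float)
    return arr


def score_batch(
    df: pd.DataFrame,
    models_by_sex: Mapping[str, Mapping[str, HazardModel]],
    table: RecalibrationTable,
    *,
    combination: str = "sum_hazards",
    age_basis: str = "attained",
) -> pd.DataFrame:
    """Vectorized 10-year risk for a frame of complete-case profiles.

    ``df`` needs columns ``sex``, ``age`` and the variant's components
    (``sbp``, ``current_smoker`` and, per variant, ``diabetes``/``total_chol``
    or ``bmi``). ``models_by_sex`` maps sex -> outcome -> HazardModel.
    Returns a copy with ``ten_year_risk`` (proportion), ``risk_pct``,
    ``category``, ``variant``, ``algorithm`` appended. Equivalent to the
    scalar :func:`ten_year_risk` loop on every row (tested to 1e-10).
    """
    any_models = next(iter(models_by_sex.values()))
    variant = next(iter(any_models.values())).variant
    algorithm = next(iter(any_models.values())).algorithm
    required = VARIANT_FACTORS[variant]
    missing_cols = [c for c in ("sex", "age", *required) if c not in df.columns]
    if missing_cols:
        raise ScoringIneligibleError(f"input frame lacks columns: {missing_cols}")
    if df[list(required)].isna().any().any() or df["age"].isna().any():
        raise ScoringIneligibleError(
            "batch scorer requires complete cases; filter eligibility upstream"
        )

    out = df.copy()
    risk = np.full(len(df), np.nan)
    for sex, models in models_by_sex.items():
        mask = (df["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        age = df.loc[mask, "age"].to_numpy(dtype=float)
        x = {f: df.loc[mask, f].to_numpy(dtype=float) for f in required}
        cells = _cell_arrays(table, sex)
        log_cum_surv = np.zeros(mask.sum())
        for t in range(HORIZON_YEARS):
            aa = age + t
            lookup_age = age if age_basis == "baseline" else aa
            idx = np.searchsorted(cells["lo"], lookup_age, side="right") - 1
            bad = (idx < 0) | (lookup_age >= cells["hi"][np.clip(idx, 0, None)])
            if bad.any():
                raise CoverageError(
                    f"attained age outside table coverage in follow-up year {t}", year=t
                )
            r_total = np.zeros_like(aa)
            for outcome, model in models.items():
                log_jhr = np.zeros_like(aa)
                for term in model.terms:
                    dist = x[term.risk_factor] - cells[term.risk_factor][idx]
                    log_jhr += (term.main_log_hr + term.age_interaction_log_hr * aa) * dist
                r_total += np.exp(log_jhr) * cells[f"rate_{outcome}"][idx]
            log_cum_surv -= r_total
        risk[mask] = 1.0 - np.exp(log_cum_surv)

    excursion = np.maximum(risk - 1.0, -risk).max(initial=0.0)
    if excursion > 1e-9:
        warnings.warn("batch 10-year risks outside [0,1] by more than 1e-9; clipping", RuntimeWarning)
    risk = np.clip(risk, 0.0, 1.0)
    out["ten_year_risk"] = risk
    out["risk_pct"] = risk * 100.0
    out["category"] = pd.Series(risk, index=out.index).map(categorize)
    out["variant"] = variant
    out["algorithm"] = algorithm
    return out
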