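"""Harmonization of repeated cross-sectional survey extracts.

Turns raw per-year extracts (one row per interviewed adult) into a pooled
analysis-ready dataset: device-era blood-pressure conversion, laboratory
calibrator corrections for total cholesterol and HbA1c, outlier rules,
component derivations (SBP reading selection, BMI, age from bands), variant
eligibility filtering with audit counts, and analysis-weight selection.

Input column contract (one CSV per survey year):

====================  =====================================================
survey_year           calendar year of the cross-section
sample_flag           'general_population' or 'boost'
sex                   'male' / 'female'
age_continuous        years; may be missing when only banded age is released
age_band_lo/age_band_hi  5-year band bounds (inclusive, e.g. 40/44); hi
                      missing marks an open-ended top band
sbp1..sbp3            up to three seated SBP readings, mm Hg (device scale)
sbp1_valid..sbp3_valid  validity flags (False when the protocol was broken)
bp_device             'dinamap' (pre-2003 era) or 'omron'
height_m, weight_kg   interviewer measurements
smoker_current        current cigarette smoker (boolean)
diagnosed_diabetes    self-reported physician-diagnosed diabetes (boolean)
total_chol            nonfasting total cholesterol, mmol/L (era scale)
hba1c, hba1c_unit     glycated haemoglobin + unit ('percent'/'mmol_per_mol')
hba1c_needs_adjustment  True for fieldwork after the calibrator change
cvd_module            participant received the diabetes/CVD interview module
interview/nurse/blood   staged participation flags (monotone)
weight_interview/_nurse/_blood  stage nonresponse weights (NaN pre-2003)
psu, stratum          design identifiers
====================  =====================================================

All adjustments are era-gated reads of raw columns into new harmonized
columns (never in-place), so harmonization is idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError

# Survey-year availability of the score components (component sets differ:
# the laboratory variant needs the diabetes item and a blood sample).
LAB_YEARS = frozenset({1998, 2003, 2006} | set(range(2009, 2018)))
NONLAB_YEARS = frozenset({1998, 2001, 2002, 2003} | set(range(2005, 2018)))
#: years fielded only as subgroup boosts, never part of the harmonized series
BOOST_ONLY_YEARS = frozenset({1999, 2000, 2004})
ANALYSIS_YEARS = tuple(sorted(LAB_YEARS | NONLAB_YEARS))  # 17 cross-sections

VARIANT_YEARS = {"laboratory": LAB_YEARS, "non_laboratory": NONLAB_YEARS}
#: harmonized columns each variant requires non-missing
VARIANT_COMPONENTS = {
    "laboratory": ("sbp", "smoker_current", "diagnosed_diabetes", "chol_harmonized"),
    "non_laboratory": ("sbp", "smoker_current", "bmi"),
}

# Dinamap -> Omron calibration-study regression
DINAMAP_SBP_INTERCEPT, DINAMAP_SBP_SLOPE = 8.90, 0.91
DINAMAP_DBP_INTERCEPT, DINAMAP_DBP_SLOPE = 19.78, 0.73

# outlier bounds (strict inequalities; boundary values are kept)
SBP_BOUNDS = (60.0, 270.0)
HEIGHT_BOUNDS = (1.2, 2.2)
WEIGHT_BOUNDS = {"male": (35.0, 250.0), "female": (25.0, 250.0)}
BMI_LOWER = 10.0
CHOL_BOUNDS = (1.8, 20.0)

# NGSP (%) -> IFCC (mmol/mol) linear conversion; constants recorded here as
# the adopted standard equation.
NGSP_TO_IFCC_SLOPE, NGSP_TO_IFCC_INTERCEPT = 10.93, -23.50
HBA1C_PCT_RANGE = (2.5, 24.9)

AGE_RANGE = (40.0, 75.0)  # half-open: ages 40-74 inclusive

FIRST_WEIGHTED_YEAR = 2003


def cholesterol_era(year: int) -> str:
    """Calibrator era of the cholesterol assay for a survey year."""
    if year <= 2010:
        return "pre2010"
    if year <= 2014:
        return "y2011_2014"
    return "post2015"


@dataclass
class YearMeta:
    """Per-year metadata: device and calibrator eras, weight availability."""

    year: int
    bp_device: str = field(default="")
    chol_era: str = field(default="")
    weighted: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.bp_device:
            self.bp_device = "dinamap" if self.year < 2003 else "omron"
        if not self.chol_era:
            self.chol_era = cholesterol_era(self.year)
        self.weighted = self.year >= FIRST_WEIGHTED_YEAR


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def convert_dinamap_bp(reading: float, which: str = "systolic") -> float:
    """Convert a Dinamap-era BP reading onto the Omron scale."""
    if reading is None or not math.isfinite(reading):
        raise InvalidInputError(f"BP reading must be finite, got {reading}")
    if which == "systolic":
        return DINAMAP_SBP_INTERCEPT + DINAMAP_SBP_SLOPE * reading
    if which == "diastolic":
        return DINAMAP_DBP_INTERCEPT + DINAMAP_DBP_SLOPE * reading
    raise InvalidInputError(f"which must be 'systolic' or 'diastolic', got {which!r}")


def select_sbp(
    readings: list[float | None],
    valid: list[bool],
    rule: str = "strict",
) -> float:
    """SBP from up to three readings: mean of the 2nd and 3rd *valid* ones.

    ``strict`` (default) requires at least three valid readings; ``lenient``
    averages all valid readings after the first and requires at least two.
    Returns NaN when the rule cannot be satisfied.
    """
    if rule not in ("strict", "lenient"):
        raise ConfigError(f"unknown SBP rule: {rule!r}")
    vals = [
        float(r)
        for r, ok in zip(readings, valid)
        if ok and r is not None and not (isinstance(r, float) and math.isnan(r))
    ]
    if rule == "strict":
        if len(vals) < 3:
            return float("nan")
        return (vals[1] + vals[2]) / 2.0
    if len(vals) < 2:
        return float("nan")
    return float(np.mean(vals[1:]))


def adjust_cholesterol(value: float, era: str) -> float:
    """Harmonize total cholesterol across calibrator eras (cholval13 scale).

    2011-2014 assays read 0.1 mmol/L high relative to the pre-2010 scale and
    are shifted down; the post-2015 calibrator restored equivalence.
    """
    if era == "y2011_2014":
        return value - 0.1
    if era in ("pre2010", "post2015"):
        return value
    raise ConfigError(f"unknown cholesterol era: {era!r}")


def adjust_hba1c(value: float, needs_adjustment: bool) -> float:
    """Upward calibrator correction for HbA1c (mmol/mol), range-dependent.

    +1 for 16-41, +2 for 42-68, +3 for >=69; values below 16 pass unchanged.
    Applied only to fieldwork after the calibrator change.
    """
    if not needs_adjustment or not math.isfinite(value):
        return value
    if value < 16:
        return value
    if value <= 41:
        return value + 1
    if value <= 68:
        return value + 2
    return value + 3


def hba1c_pct_to_mmol(pct: float) -> float:
    """NGSP percent -> IFCC mmol/mol; non-plausible percentages become NaN."""
    if pct is None or not math.isfinite(pct):
        return float("nan")
    lo, hi = HBA1C_PCT_RANGE
    if not (lo <= pct <= hi):
        return float("nan")
    return NGSP_TO_IFCC_SLOPE * pct + NGSP_TO_IFCC_INTERCEPT


def hba1c_mmol_to_pct(mmol: float) -> float:
    """Inverse of :func:`hba1c_pct_to_mmol` (no plausibility filter)."""
    return (mmol - NGSP_TO_IFCC_INTERCEPT) / NGSP_TO_IFCC_SLOPE


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Weight (kg) over height (m) squared; NaN propagates."""
    if weight_kg is None or height_m is None:
        return float("nan")
    if not (math.isfinite(weight_kg) and math.isfinite(height_m)) or height_m == 0:
        return float("nan")
    return weight_kg / height_m**2


def resolve_age(
    age_continuous: float | None,
    age_band_lo: float | None = None,
    age_band_hi: float | None = None,
) -> float:
    """Continuous age when released, else the 5-year band midpoint (lo + 2).

    Open-ended top bands have no midpoint and resolve to NaN (irrelevant in
    the 40-74 analysis range).
    """
    if age_continuous is not None and math.isfinite(age_continuous):
        return float(age_continuous)
    if age_band_lo is None or not math.isfinite(age_band_lo):
        return float("nan")
    if age_band_hi is None or not math.isfinite(age_band_hi):
        return float("nan")  # open-ended band
    return float(age_band_lo) + 2.0


# ---------------------------------------------------------------------------
# frame-level harmonization
# ---------------------------------------------------------------------------

def _series_or_nan(df: pd.DataFrame, col: str) -> pd.Series:
    if col in df.columns:
        return pd.to_numeric(df[col], errors="coerce")
    return pd.Series(np.nan, index=df.index)


_BOOL01_MAP = {
    True: 1.0, False: 0.0, 1: 1.0, 0: 0.0, 1.0: 1.0, 0.0: 0.0,
    "True": 1.0, "False": 0.0, "true": 1.0, "false": 0.0,
}


def _bool01(s: pd.Series) -> pd.Series:
    """0/1 float coding of a boolean-ish column (robust to CSV round trips);
    unrecognized or missing values become NaN."""
    if s.dtype == bool:
        return s.astype(float)
    if s.dtype.kind in "fiu":
        return s.astype(float)
    return s.map(_BOOL01_MAP).astype(float)


def harmonize_records(df: pd.DataFrame, sbp_rule: str = "strict") -> pd.DataFrame:
    """Harmonize a frame of raw records (one or several survey years).

    Adds: ``age_years``, ``sbp`` (Omron scale, selected reading mean),
    ``bmi``, ``chol_harmonized``, ``hba1c_mmol_mol``. Raw columns are kept
    untouched, so the function is idempotent. Outlier filtering
    (:func:`apply_outlier_filters`) runs as the final step.
    """
    out = df.copy()
    year = out["survey_year"].astype(int)

    # age: continuous where released, else band midpoint
    cont = _series_or_nan(out, "age_continuous")
    lo = _series_or_nan(out, "age_band_lo")
    hi = _series_or_nan(out, "age_band_hi")
    midpoint = lo + 2.0
    midpoint[hi.isna()] = np.nan  # open-ended top band
    out["age_years"] = cont.where(cont.notna(), midpoint)

    # SBP: device-era conversion of each reading, then valid-reading selection
    readings = np.column_stack([_series_or_nan(out, f"sbp{i}").to_numpy() for i in (1, 2, 3)])
    valid = np.column_stack(
        [
            (_bool01(out[f"sbp{i}_valid"]).fillna(0.0) > 0).to_numpy()
            if f"sbp{i}_valid" in out.columns
            else np.ones(len(out), bool)
            for i in (1, 2, 3)
        ]
    )
    device = out.get("bp_device", pd.Series("omron", index=out.index)).fillna("omron")
    dinamap = (device == "dinamap").to_numpy()
    converted = readings.copy()
    converted[dinamap] = DINAMAP_SBP_INTERCEPT + DINAMAP_SBP_SLOPE * readings[dinamap]
    out["sbp"] = _select_sbp_matrix(converted, valid, sbp_rule)

    # cholesterol: era shift onto the pre-2010 scale
    chol = _series_or_nan(out, "total_chol")
    era = year.map(cholesterol_era)
    out["chol_harmonized"] = chol - 0.1 * (era == "y2011_2014").astype(float)

    # HbA1c: percent -> mmol/mol, then calibrator correction
    hba1c = _series_or_nan(out, "hba1c")
    unit = out.get("hba1c_unit", pd.Series("mmol_per_mol", index=out.index))
    pct = unit == "percent"
    mmol = hba1c.copy()
    in_range = hba1c.between(*HBA1C_PCT_RANGE)
    mmol[pct] = np.where(
        in_range[pct], NGSP_TO_IFCC_SLOPE * hba1c[pct] + NGSP_TO_IFCC_INTERCEPT, np.nan
    )
    needs = (
        _bool01(out["hba1c_needs_adjustment"]).fillna(0.0) > 0
        if "hba1c_needs_adjustment" in out.columns
        else pd.Series(False, index=out.index)
    )
    shift = pd.Series(0.0, index=out.index)
    shift[needs & (mmol >= 16) & (mmol <= 41)] = 1.0
    shift[needs & (mmol >= 42) & (mmol <= 68)] = 2.0
    shift[needs & (mmol >= 69)] = 3.0
    out["hba1c_mmol_mol"] = mmol + shift

    return apply_outlier_filters(out)


def _select_sbp_matrix(readings: np.ndarray, valid: np.ndarray, rule: str) -> np.ndarray:
    if rule not in ("strict", "lenient"):
        raise ConfigError(f"unknown SBP rule: {rule!r}")
    ok = valid & np.isfinite(readings)
    n_valid = ok.sum(axis=1)
    # rank of each valid reading among the row's valid readings (0-based)
    rank = np.where(ok, np.cumsum(ok, axis=1) - 1, -1)
    if rule == "strict":
        usable = (rank == 1) | (rank == 2)
        enough = n_valid >= 3
    else:
        usable = rank >= 1
        enough = n_valid >= 2
    num = np.where(usable, readings, 0.0).sum(axis=1)
    den = usable.sum(axis=1)
    with np.errstate(invalid="ignore"):
        sbp = np.where(enough & (den > 0), num / np.maximum(den, 1), np.nan)
    return sbp


def apply_outlier_filters(df: pd.DataFrame) -> pd.DataFrame:
    """Set biologically implausible harmonized values to missing.

    Bounds are strict inequalities exactly as printed in the component
    dictionary (boundary values survive): SBP <60 or >270 mm Hg; height
    <1.2 or >2.2 m; weight <35 kg (men) / <25 kg (women) or >250 kg; BMI
    <10 kg/m2 (recomputed after the height/weight filters); total
    cholesterol <1.8 or >20 mmol/L. Per-field removal counts are stored in
    ``df.attrs['outlier_counts']``.
    """
    out = df.copy()
    counts: dict[str, int] = {}

    sbp = _series_or_nan(out, "sbp")
    bad = sbp.notna() & ((sbp < SBP_BOUNDS[0]) | (sbp > SBP_BOUNDS[1]))
    counts["sbp"] = int(bad.sum())
    out["sbp"] = sbp.mask(bad)

    height = _series_or_nan(out, "height_m")
    bad = height.notna() & ((height < HEIGHT_BOUNDS[0]) | (height > HEIGHT_BOUNDS[1]))
    counts["height"] = int(bad.sum())
    height = height.mask(bad)

    weight = _series_or_nan(out, "weight_kg")
    wlo = out["sex"].map({"male": WEIGHT_BOUNDS["male"][0], "female": WEIGHT_BOUNDS["female"][0]})
    bad = weight.notna() & ((weight < wlo) | (weight > WEIGHT_BOUNDS["male"][1]))
    counts["weight"] = int(bad.sum())
    weight = weight.mask(bad)

    # BMI from post-filter height/weight, then its own lower bound
    bmi = weight / height**2
    bad = bmi.notna() & (bmi < BMI_LOWER)
    counts["bmi"] = int(bad.sum())
    out["bmi"] = bmi.mask(bad)
    out["height_m_clean"] = height
    out["weight_kg_clean"] = weight

    chol = _series_or_nan(out, "chol_harmonized")
    bad = chol.notna() & ((chol < CHOL_BOUNDS[0]) | (chol > CHOL_BOUNDS[1]))
    counts["total_chol"] = int(bad.sum())
    out["chol_harmonized"] = chol.mask(bad)

    out.attrs["outlier_counts"] = counts
    return out


# ---------------------------------------------------------------------------
# eligibility and weights
# ---------------------------------------------------------------------------

EXCLUSION_REASONS = (
    "boost_year",
    "year_not_in_variant",
    "boost_sample",
    "age_missing",
    "age_range",
    "missing_component",
    "missing_weight",
)


def eligibility(df: pd.DataFrame, variant: str) -> pd.Series:
    """Per-record eligibility for a score variant.

    Returns 'eligible' or the first applicable exclusion reason, evaluated
    in flowchart order: boost-only year; year outside the variant's series;
    boost (non-general-population) sample; missing/out-of-range age (40-74);
    missing score component (including the split diabetes-module rule for
    the laboratory variant); missing stage weight in a weighted year.
    """
    if variant not in VARIANT_YEARS:
        raise ConfigError(f"unknown variant: {variant!r}")
    year = df["survey_year"].astype(int)
    reason = pd.Series("eligible", index=df.index, dtype=object)

    weights = select_weight_raw(df, variant)
    missing_weight = (year >= FIRST_WEIGHTED_YEAR) & weights.isna()
    reason[missing_weight] = "missing_weight"

    comps = list(VARIANT_COMPONENTS[variant])
    missing_comp = pd.Series(False, index=df.index)
    for c in comps:
        if c not in df.columns:
            missing_comp |= True
            continue
        col = _bool01(df[c]) if c in ("smoker_current", "diagnosed_diabetes") else df[c]
        missing_comp |= pd.isna(col)
    if variant == "laboratory" and "cvd_module" in df.columns:
        missing_comp |= ~(_bool01(df["cvd_module"]).fillna(0.0) > 0)
    reason[missing_comp] = "missing_component"

    age = _series_or_nan(df, "age_years")
    reason[age.notna() & ~((age >= AGE_RANGE[0]) & (age < AGE_RANGE[1]))] = "age_range"
    reason[age.isna()] = "age_missing"

    reason[df["sample_flag"].fillna("general_population") != "general_population"] = "boost_sample"
    reason[~year.isin(sorted(VARIANT_YEARS[variant]))] = "year_not_in_variant"
    reason[year.isin(sorted(BOOST_ONLY_YEARS))] = "boost_year"
    return reason


def select_weight_raw(df: pd.DataFrame, variant: str) -> pd.Series:
    """Stage weight for a variant before rescaling: blood weight for the
    laboratory variant, nurse weight otherwise; 1.0 in pre-weighting years."""
    col = "weight_blood" if variant == "laboratory" else "weight_nurse"
    w = _series_or_nan(df, col)
    if (w < 0).any():
        raise InvalidInputError(f"negative values in {col}")
    year = df["survey_year"].astype(int)
    return w.mask(year < FIRST_WEIGHTED_YEAR, 1.0)


def build_analytic(
    df: pd.DataFrame, variant: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply eligibility and weight selection to a harmonized pooled frame.

    Returns ``(analytic, audit)``: the analytic sample carries an
    ``analysis_weight`` rescaled to mean 1 within each year, plus ``age``
    and variant component columns renamed to the scoring contract; the audit
    frame counts records by (survey_year, status) and reproduces the
    flowchart identity records_in = eligible + sum(excluded by reason).
    """
    status = eligibility(df, variant)
    audit = (
        pd.DataFrame({"survey_year": df["survey_year"].astype(int), "status": status})
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["survey_year", "status"])
        .reset_index(drop=True)
    )
    keep = status == "eligible"
    analytic = df.loc[keep].copy()
    w = select_weight_raw(df, variant).loc[keep]
    # rescale to mean 1 within each year's analytic sample
    year_mean = w.groupby(analytic["survey_year"]).transform("mean")
    analytic["analysis_weight"] = w / year_mean
    analytic["age"] = analytic["age_years"]
    analytic["current_smoker"] = _bool01(analytic["smoker_current"])
    if variant == "laboratory":
        analytic["diabetes"] = _bool01(analytic["diagnosed_diabetes"])
        analytic["total_chol"] = analytic["chol_harmonized"]
    return analytic, audit
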