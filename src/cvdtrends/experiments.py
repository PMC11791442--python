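"""Repeatable validation experiments built from the package's own pieces.

These are the parameter-recovery and end-to-end harnesses used by the test
suite and the reproduction script: they generate synthetic surveys, push
them through harmonization and scoring, and measure how well the
design-based estimators recover what was injected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import harmonize as hz
from .survey_stats import SurveyDesign, svy_trend
from .synthgen import TrendScenario, generate_pooled
from .tables import default_engine


def risk_index_trend_recovery(
    scenario: TrendScenario | None = None,
    n_replicates: int = 100,
    base_seed: int = 0,
) -> dict:
    """Coverage of the injected risk-index drift by the trend estimator's CI.

    For each replicate, a full multi-year survey is generated, the
    survey-weighted linear trend of the injected ``risk_index`` on survey
    year is fitted over the whole interviewed sample (design: PSU within
    region-like stratum, unit weights at the interview stage), and the
    95% CI is checked against the known injected slope. Returns the
    coverage count, the replicate slopes, and the true slope.
    """
    scenario = scenario or TrendScenario()
    true_slope = scenario.male.risk_index.drift
    if scenario.female.risk_index.drift != true_slope:
        raise ValueError("recovery harness assumes a common injected drift")
    covered = 0
    slopes = []
    for r in range(n_replicates):
        df = generate_pooled(scenario, seed=base_seed + r)
        design = SurveyDesign(
            df["psu"].to_numpy(), df["stratum"].to_numpy(), np.ones(len(df))
        )
        res = svy_trend(df["risk_index"].to_numpy(), df["survey_year"].to_numpy(), design)
        slopes.append(res.slope)
        if res.ci_lo <= true_slope <= res.ci_hi:
            covered += 1
    return {
        "covered": covered,
        "n_replicates": n_replicates,
        "true_slope": true_slope,
        "slopes": np.array(slopes),
    }


def scored_trend_summary(
    scenario: TrendScenario | None = None,
    seed: int = 1,
    algorithms: tuple[str, ...] = ("who_style", "globorisk_style"),
    variants: tuple[str, ...] = ("laboratory", "non_laboratory"),
) -> dict[str, pd.DataFrame]:
    """Score a generated survey and summarize risk trends and components.

    Returns ``estimates`` (per year/sex/measure, risk as a percentage) and
    ``trends`` (slope of mean risk in percentage points per calendar year)
    frames across the requested algorithm x variant grid.
    """
    from .risk_engine import score_batch
    from .survey_stats import estimates_by_year, trend_by_sex

    scenario = scenario or TrendScenario()
    raw = generate_pooled(scenario, seed=seed)
    harmonized = hz.harmonize_records(raw)
    est_frames, trend_frames = [], []
    for variant in variants:
        analytic, _ = hz.build_analytic(harmonized, variant)
        for algorithm in algorithms:
            models_by_sex, table = default_engine(algorithm, variant)
            scored = score_batch(analytic, models_by_sex, table)
            est = estimates_by_year(scored)
            est.insert(0, "algorithm", algorithm)
            est.insert(1, "variant", variant)
            est_frames.append(est)
            tr = trend_by_sex(scored)
            tr.insert(0, "algorithm", algorithm)
            tr.insert(1, "variant", variant)
            trend_frames.append(tr)
    return {
        "estimates": pd.concat(est_frames, ignore_index=True),
        "trends": pd.concat(trend_frames, ignore_index=True),
        "harmonized": harmonized,
    }


def component_deltas(estimates: pd.DataFrame) -> pd.DataFrame:
    """Last-minus-first-year change in each risk component, per sex.

    Operates on one algorithm x variant slice of the estimates frame and
    reports changes in the units the surveys measure (mm Hg, mmol/L, kg/m2,
    percentage points for prevalences).
    """
    rows = []
    for (sex, measure), g in estimates.groupby(["sex", "measure"]):
        g = g.sort_values("year")
        first, last = g.iloc[0], g.iloc[-1]
        delta = last["estimate"] - first["estimate"]
        if measure in ("current_smoker", "diabetes"):
            delta *= 100.0  # percentage points
        rows.append(
            {
                "sex": sex,
                "measure": measure,
                "year_first": int(first["year"]),
                "year_last": int(last["year"]),
                "delta": delta,
            }
        )
    return pd.DataFrame(rows)
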