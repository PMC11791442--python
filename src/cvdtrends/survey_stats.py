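"""Design-based estimation for stratified multistage samples.

Weighted means/proportions with Taylor-linearized (delta-method) standard
errors treating PSUs as sampled with replacement within strata — the
standard first-stage approximation for health-examination surveys — plus
two-sample Wald tests between survey years and survey-weighted linear trend
regression with a cluster-robust sandwich variance.

Notation: for records i in PSU c of stratum h with weights w_i, the mean is
the ratio estimator ybar = sum(w y) / sum(w). Its linearized variance is

    V = sum_h  n_h/(n_h - 1)  sum_c (z_hc - zbar_h)^2,

where z_hc are PSU totals of the linearized scores
z_i = w_i (y_i - ybar) / sum(w) and n_h is the number of PSUs in stratum h.
Design degrees of freedom are (number of PSUs) - (number of strata).

Strata with a single PSU ("lonely" PSUs) contribute, by default, their
squared deviation from the grand mean of PSU score totals (certainty
centering) with a warning; collapsing lonely strata into their predecessor
is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

#: above this many design df the t reference is indistinguishable from normal
NORMAL_DF_CUTOFF = 200


@dataclass(frozen=True)
class SurveyDesign:
    """PSU / stratum / weight triplet for a set of records."""

    psu: np.ndarray
    stratum: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        psu = np.asarray(self.psu)
        stratum = np.asarray(self.stratum)
        weight = np.asarray(self.weight, dtype=float)
        if not (len(psu) == len(stratum) == len(weight)):
            raise InvalidInputError("psu, stratum, weight must have equal length")
        if len(weight) == 0:
            raise InvalidInputError("empty design")
        if np.isnan(weight).any() or (weight < 0).any():
            raise InvalidInputError("weights must be non-negative and non-missing")
        if not (weight > 0).any():
            raise InvalidInputError("all weights are zero")
        object.__setattr__(self, "psu", psu)
        object.__setattr__(self, "stratum", stratum)
        object.__setattr__(self, "weight", weight)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, psu: str = "psu", stratum: str = "stratum",
        weight: str = "analysis_weight",
    ) -> "SurveyDesign":
        return cls(df[psu].to_numpy(), df[stratum].to_numpy(), df[weight].to_numpy())

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        return SurveyDesign(self.psu[mask], self.stratum[mask], self.weight[mask])


@dataclass(frozen=True)
class EstimateWithSE:
    """Design-based point estimate with linearized SE and design df."""

    estimate: float
    se: float
    df: int
    n: int
    sum_weights: float


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    p_value: float
    df: float
    degenerate: bool = False


@dataclass(frozen=True)
class TrendResult:
    slope: float
    se: float
    p_value: float
    ci_lo: float
    ci_hi: float
    df: int
    intercept: float


def _psu_codes(design: SurveyDesign) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Integer codes for (stratum, psu-within-stratum); returns
    (stratum_code, global psu code, n_strata, n_psus)."""
    strat_code, strat_uniq = pd.factorize(design.stratum, sort=True)
    combo = pd.MultiIndex.from_arrays([design.stratum, design.psu])
    psu_code, psu_uniq = combo.factorize()
    return strat_code, psu_code, len(strat_uniq), len(psu_uniq)


def design_df(design: SurveyDesign) -> int:
    """Design degrees of freedom: total PSUs minus total strata."""
    _, _, n_strata, n_psus = _psu_codes(design)
    return n_psus - n_strata


def _score_variance(
    scores: np.ndarray, design: SurveyDesign, lonely_psu: str = "centered"
) -> np.ndarray:
    """Stratified with-replacement variance of totals of linearized scores.

    ``scores`` is (n, p); returns the (p, p) covariance of the score total.
    """
    if lonely_psu not in ("centered", "collapse"):
        raise InvalidInputError(f"unknown lonely-PSU rule: {lonely_psu!r}")
    strat_code, psu_code, n_strata, n_psus = _psu_codes(design)
    p = scores.shape[1]
    # PSU totals of scores and the stratum of each PSU
    totals = np.zeros((n_psus, p))
    for j in range(p):
        np.add.at(totals[:, j], psu_code, scores[:, j])
    psu_stratum = np.zeros(n_psus, dtype=int)
    psu_stratum[psu_code] = strat_code

    psus_per_stratum = np.bincount(psu_stratum, minlength=n_strata)
    if lonely_psu == "collapse" and (psus_per_stratum == 1).any():
        # merge each lonely stratum into its nearest multi-PSU stratum
        remap = np.arange(n_strata)
        non_lonely = np.where(psus_per_stratum > 1)[0]
        if len(non_lonely) == 0:
            remap[:] = 0  # no usable stratum: pool everything
        else:
            for h in np.where(psus_per_stratum == 1)[0]:
                remap[h] = non_lonely[np.argmin(np.abs(non_lonely - h))]
        psu_stratum = remap[psu_stratum]
        psus_per_stratum = np.bincount(psu_stratum, minlength=n_strata)

    V = np.zeros((p, p))
    grand_mean = totals.mean(axis=0)
    lonely = 0
    for h in np.unique(psu_stratum):
        t_h = totals[psu_stratum == h]
        n_h = len(t_h)
        if n_h == 1:
            lonely += 1
            d = t_h[0] - grand_mean
            V += np.outer(d, d)
            continue
        d = t_h - t_h.mean(axis=0)
        V += (n_h / (n_h - 1)) * d.T @ d
    if lonely:
        warnings.warn(
            f"{lonely} stratum(s) with a single PSU: certainty-centered at the grand mean",
            RuntimeWarning,
            stacklevel=3,
        )
    return V


def svy_mean(
    y: np.ndarray | pd.Series, design: SurveyDesign, lonely_psu: str = "centered"
) -> EstimateWithSE:
    """Survey-weighted mean with Taylor-linearized SE."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(design.weight):
        raise InvalidInputError("y and design have different lengths")
    if np.isnan(y).any():
        raise InvalidInputError("y contains missing values; subset the design first")
    w = design.weight
    sw = w.sum()
    est = float(np.dot(w, y) / sw)
    scores = (w * (y - est) / sw)[:, None]
    var = _score_variance(scores, design, lonely_psu)[0, 0]
    return EstimateWithSE(
        estimate=est,
        se=float(np.sqrt(max(var, 0.0))),
        df=design_df(design),
        n=len(y),
        sum_weights=float(sw),
    )


def svy_prop(
    indicator: np.ndarray | pd.Series, design: SurveyDesign, lonely_psu: str = "centered"
) -> EstimateWithSE:
    """Survey-weighted proportion: :func:`svy_mean` of the 0/1 coding."""
    ind = np.asarray(indicator, dtype=float)
    if not np.isin(ind[~np.isnan(ind)], (0.0, 1.0)).all():
        raise InvalidInputError("indicator must be 0/1 coded")
    return svy_mean(ind, design, lonely_psu)


def _ref_p(stat: float, df: float) -> float:
    """Two-sided p under a t reference with design df (normal for large df)."""
    if df > NORMAL_DF_CUTOFF:
        return float(2 * stats.norm.sf(abs(stat)))
    return float(2 * stats.t.sf(abs(stat), df=max(df, 1)))


def wald_two_years(e1: EstimateWithSE, e2: EstimateWithSE) -> WaldResult:
    """Wald test of no change between two independent survey-year estimates.

    statistic = (e2 - e1) / sqrt(se1^2 + se2^2); two-sided p from a t
    reference with the summed design df (normal beyond 200 df). Independence
    across years holds because each cross-section draws a fresh sample.
    """
    pooled_se = float(np.hypot(e1.se, e2.se))
    diff = e2.estimate - e1.estimate
    df = e1.df + e2.df
    if pooled_se == 0.0:
        if diff == 0.0:
            return WaldResult(statistic=0.0, p_value=1.0, df=df)
        warnings.warn("zero pooled SE with unequal estimates; degenerate Wald test",
                      RuntimeWarning, stacklevel=2)
        return WaldResult(statistic=np.inf if diff > 0 else -np.inf,
                          p_value=0.0, df=df, degenerate=True)
    stat = diff / pooled_se
    return WaldResult(statistic=float(stat), p_value=_ref_p(stat, df), df=df)


def svy_trend(
    y: np.ndarray | pd.Series,
    year: np.ndarray | pd.Series,
    design: SurveyDesign,
    lonely_psu: str = "centered",
) -> TrendResult:
    """Survey-weighted linear regression of y on calendar year.

    Weighted least squares of y on {1, year}; the slope is the estimated
    change per calendar year in outcome units. Variance is the linearized
    cluster-robust sandwich A^-1 B A^-1 with A = X'WX and B the stratified
    with-replacement covariance of PSU totals of the scores w x e.
    """
    y = np.asarray(y, dtype=float)
    year = np.asarray(year, dtype=float)
    if len(np.unique(year)) < 2:
        raise InvalidInputError("trend regression needs at least 2 distinct years")
    w = design.weight
    # center the year covariate for numerical stability (slope and its SE
    # are invariant; the intercept is mapped back afterwards)
    year_c = float(np.average(year, weights=w))
    X = np.column_stack([np.ones_like(year), year - year_c])
    A = X.T @ (w[:, None] * X)
    try:
        beta = np.linalg.solve(A, X.T @ (w * y))
    except np.linalg.LinAlgError as exc:
        raise InvalidInputError("rank-deficient trend design matrix") from exc
    resid = y - X @ beta
    scores = w[:, None] * X * resid[:, None]
    B = _score_variance(scores, design, lonely_psu)
    Ainv = np.linalg.inv(A)
    V = Ainv @ B @ Ainv
    se = float(np.sqrt(max(V[1, 1], 0.0)))
    df = design_df(design)
    slope = float(beta[1])
    if se == 0.0:
        p = 1.0 if slope == 0.0 else 0.0
        tcrit = 0.0
    else:
        p = _ref_p(slope / se, df)
        tcrit = float(stats.norm.ppf(0.975)) if df > NORMAL_DF_CUTOFF else float(
            stats.t.ppf(0.975, df=max(df, 1))
        )
    return TrendResult(
        slope=slope,
        se=se,
        p_value=p,
        ci_lo=slope - tcrit * se,
        ci_hi=slope + tcrit * se,
        df=df,
        intercept=float(beta[0] - beta[1] * year_c),
    )


# ---------------------------------------------------------------------------
# tidy exports over scored analytic samples
# ---------------------------------------------------------------------------

#: measure name -> column of the scored analytic frame
DEFAULT_MEASURES = {
    "risk_pct": "risk_pct",
    "sbp": "sbp",
    "total_chol": "total_chol",
    "bmi": "bmi",
    "current_smoker": "current_smoker",
    "diabetes": "diabetes",
}
_PROPORTION_MEASURES = {"current_smoker", "diabetes"}


def estimates_by_year(
    scored: pd.DataFrame,
    measures: dict[str, str] | None = None,
    weight_col: str = "analysis_weight",
) -> pd.DataFrame:
    """Per-year, per-sex design-based estimates as a tidy frame.

    Columns: year, sex, measure, estimate, se, n, sum_weights. Proportions
    (smoking, diabetes) are estimated as weighted percentages would be after
    multiplying by 100 downstream; here everything stays in natural units.
    """
    measures = measures or {
        k: v for k, v in DEFAULT_MEASURES.items() if v in scored.columns
    }
    rows = []
    for (yr, sex), g in scored.groupby(["survey_year", "sex"], sort=True):
        for name, col in measures.items():
            vals = g[col]
            mask = vals.notna().to_numpy()
            if mask.sum() == 0:
                continue
            design = SurveyDesign(
                g["psu"].to_numpy()[mask],
                g["stratum"].to_numpy()[mask],
                g[weight_col].to_numpy()[mask],
            )
            fn = svy_prop if name in _PROPORTION_MEASURES else svy_mean
            est = fn(vals.to_numpy()[mask], design)
            rows.append(
                {
                    "year": int(yr),
                    "sex": sex,
                    "measure": name,
                    "estimate": est.estimate,
                    "se": est.se,
                    "df": est.df,
                    "n": est.n,
                    "sum_weights": est.sum_weights,
                }
            )
    return pd.DataFrame(rows)


def trend_by_sex(
    scored: pd.DataFrame,
    outcome_col: str = "risk_pct",
    weight_col: str = "analysis_weight",
    stratum_col: str = "stratum",
) -> pd.DataFrame:
    """Sex-specific survey-weighted linear trend of an outcome on survey year.

    For pooled multi-year models the region-like stratum is the appropriate
    stratification variable. Returns {sex, beta, se, ci_lo, ci_hi, p, df, n}.
    """
    rows = []
    for sex, g in scored.groupby("sex", sort=True):
        mask = g[outcome_col].notna().to_numpy()
        design = SurveyDesign(
            g["psu"].to_numpy()[mask],
            g[stratum_col].to_numpy()[mask],
            g[weight_col].to_numpy()[mask],
        )
        res = svy_trend(
            g[outcome_col].to_numpy()[mask],
            g["survey_year"].to_numpy()[mask],
            design,
        )
        rows.append(
            {
                "sex": sex,
                "beta": res.slope,
                "se": res.se,
                "ci_lo": res.ci_lo,
                "ci_hi": res.ci_hi,
                "p": res.p_value,
                "df": res.df,
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)
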