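"""Unit and property tests for the recalibrated 10-year risk engine."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cvdtrends as ct
from cvdtrends.errors import (
    ConfigError,
    CoverageError,
    InvalidInputError,
    ScoringIneligibleError,
)
from cvdtrends.risk_engine import HORIZON_YEARS, HazardTerm, score_batch, ten_year_risk

from conftest import random_table_and_models


def _mean_profile(cell, sex, age, variant="laboratory"):
    """Profile sitting exactly at a recalibration cell's means/prevalences."""
    kw = dict(sex=sex, age=age, sbp=cell.mean_sbp, current_smoker=cell.smoking_prev)
    if variant == "laboratory":
        kw.update(diabetes=cell.diabetes_prev, total_chol=cell.mean_tc)
    else:
        kw.update(bmi=cell.mean_bmi)
    return ct.RiskFactorProfile(**kw)


class TestTermHR:
    @pytest.mark.parametrize(
        "main,inter,age,x,m,expected",
        [
            (0.7, -0.003, 55.0, 140.0, 140.0, 1.0),  # zero distance
            (math.log(2), 0.0, 60.0, 1.0, 0.0, 2.0),  # pure main effect
            # hand-computed: exp((0.02 - 0.0002*60) * 10) = exp(0.08)
            (0.02, -0.0002, 60.0, 10.0, 0.0, math.exp(0.08)),
        ],
    )
    def test_examples(self, main, inter, age, x, m, expected):
        term = HazardTerm("sbp", main, inter)
        assert ct.term_hr(term, x, m, age) == pytest.approx(expected, rel=1e-12)

    def test_non_finite_input_names_the_factor(self):
        term = HazardTerm("total_chol", 0.5)
        with pytest.raises(InvalidInputError, match="total_chol"):
            ct.term_hr(term, float("nan"), 5.0, 60.0)

    @given(
        main=st.floats(-2, 2),
        inter=st.floats(-0.02, 0.02),
        age=st.floats(40, 84),
        dist=st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_positive(self, main, inter, age, dist):
        term = HazardTerm("sbp", main, inter)
        assert ct.term_hr(term, dist, 0.0, age) > 0


class TestJointHR:
    def test_profile_at_means_gives_one(self, lab_engine):
        models, table = lab_engine
        cell = table.lookup("female", 57)
        profile = _mean_profile(cell, "female", 57)
        assert ct.joint_hr(profile, models["female"]["chd"], cell, 57) == pytest.approx(1.0)

    def test_single_term_equals_term_hr(self):
        # degenerate product: a one-term model's joint HR is that term's HR
        term = HazardTerm("sbp", 0.03, -0.0002)
        model = ct.HazardModel.__new__(ct.HazardModel)  # bypass coverage check
        object.__setattr__(model, "outcome", "chd")
        object.__setattr__(model, "sex", "male")
        object.__setattr__(model, "variant", "laboratory")
        object.__setattr__(model, "algorithm", "who_style")
        object.__setattr__(model, "terms", (term,))
        cell = ct.RecalibrationCell(
            sex="male", age_lo=40, age_hi=85, mean_sbp=130, smoking_prev=0.2,
            diabetes_prev=0.05, mean_tc=5.5, mean_bmi=27, event_rates={"chd": 0.01},
        )
        p = ct.RiskFactorProfile(sex="male", age=60, sbp=150, current_smoker=False,
                                 diabetes=False, total_chol=5.5)
        assert ct.joint_hr(p, model, cell, 60) == pytest.approx(
            ct.term_hr(term, 150, 130, 60), rel=1e-14
        )

    def test_four_term_product_matches_bruteforce(self, lab_engine):
        models, table = lab_engine
        model = models["male"]["chd"]
        cell = table.lookup("male", 66)
        p = ct.RiskFactorProfile(sex="male", age=64, sbp=152, current_smoker=True,
                                 diabetes=True, total_chol=6.4)
        expected = 1.0
        for term in model.terms:
            expected *= ct.term_hr(term, p.value(term.risk_factor),
                                   cell.mean(term.risk_factor), 66)
        assert ct.joint_hr(p, model, cell, 66) == pytest.approx(expected, rel=1e-14)

    def test_missing_component_raises(self, lab_engine):
        models, table = lab_engine
        cell = table.lookup("male", 50)
        p = ct.RiskFactorProfile(sex="male", age=50, sbp=140, current_smoker=True,
                                 diabetes=None, total_chol=5.0)
        with pytest.raises(ScoringIneligibleError, match="diabetes"):
            ct.joint_hr(p, models["male"]["chd"], cell, 50)


class TestOneYearStep:
    def test_worked_example_survival(self):
        # a 1-year risk of 0.06 gives a 1-year survival of 0.942
        risk, survival = ct.one_year_step(1.0, 0.06)
        assert risk == pytest.approx(0.06)
        assert round(survival, 3) == 0.942

    @pytest.mark.parametrize(
        "jhr,rate,risk,surv",
        [(1.0, 0.0, 0.0, 1.0), (2.0, 0.01, 0.02, math.exp(-0.02))],
    )
    def test_arithmetic(self, jhr, rate, risk, surv):
        r, s = ct.one_year_step(jhr, rate)
        assert r == pytest.approx(risk) and s == pytest.approx(surv)

    def test_negative_rate_is_config_error(self):
        with pytest.raises(ConfigError):
            ct.one_year_step(1.0, -0.01)


class TestAccumulate:
    def test_all_ones_gives_zero_risk(self):
        _, cum_risk = ct.accumulate([1.0] * 10)
        assert cum_risk[-1] == 0.0

    def test_constant_survival_closed_form(self):
        s = 0.98
        _, cum_risk = ct.accumulate([s] * 10)
        assert cum_risk[-1] == pytest.approx(1 - s**10, rel=1e-14)

    def test_matches_explicit_loop(self, rng):
        survs = rng.uniform(0.9, 1.0, 10)
        cum_surv, cum_risk = ct.accumulate(list(survs))
        running = 1.0
        for t, s in enumerate(survs):
            running *= s
            assert cum_surv[t] == pytest.approx(running, rel=1e-14)
            assert cum_risk[t] == pytest.approx(1 - running, rel=1e-14)
        assert all(a >= b - 1e-15 for a, b in zip(cum_surv, cum_surv[1:]))

    def test_wrong_horizon_rejected(self):
        with pytest.raises(InvalidInputError):
            ct.accumulate([0.99] * 9)


class TestCategorize:
    @pytest.mark.parametrize(
        "risk,label",
        [
            (0.0, "very_low"), (0.049999, "very_low"),
            (0.05, "low"), (0.09, "low"),
            (0.10, "moderate"), (0.199, "moderate"),
            (0.20, "high"), (0.2999, "high"),
            (0.30, "very_high"), (1.0, "very_high"),
        ],
    )
    def test_boundaries_left_closed(self, risk, label):
        assert ct.categorize(risk) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            ct.categorize(1.5)


class TestTenYearRisk:
    def test_identity_closed_form(self, lab_engine):
        # profile at population means: joint HR 1 every year, so
        # risk = 1 - exp(-sum of combined annual rates along the age path)
        models, table = lab_engine
        age = 62.0
        # a flat table lets one profile sit at the means of every year's cell
        flat = ct.RecalibrationTable(
            region_label="flat", base_year=2020,
            cells=tuple(
                ct.RecalibrationCell(
                    sex=s, age_lo=40, age_hi=85, mean_sbp=135, smoking_prev=0.2,
                    diabetes_prev=0.06, mean_tc=5.5, mean_bmi=27,
                    event_rates={"chd": 0.007, "stroke": 0.004},
                )
                for s in ("male", "female")
            ),
        )
        p = ct.RiskFactorProfile(sex="male", age=age, sbp=135, current_smoker=0.2,
                                 diabetes=0.06, total_chol=5.5)
        score = ct.ten_year_risk(p, models["male"], flat)
        assert score.ten_year_risk == pytest.approx(1 - math.exp(-10 * 0.011), abs=1e-12)
        assert all(j == pytest.approx(1.0, abs=1e-12) for j in score.trajectory.joint_hr)

    def test_zero_rates_give_zero_risk(self, lab_engine, rng):
        models, table = random_table_and_models(rng)
        zero = ct.RecalibrationTable(
            region_label="zero", base_year=2020,
            cells=tuple(
                ct.RecalibrationCell(
                    sex=c.sex, age_lo=c.age_lo, age_hi=c.age_hi, mean_sbp=c.mean_sbp,
                    smoking_prev=c.smoking_prev, diabetes_prev=c.diabetes_prev,
                    mean_tc=c.mean_tc, mean_bmi=c.mean_bmi,
                    event_rates={"chd": 0.0, "stroke": 0.0},
                )
                for c in table.cells
            ),
        )
        p = ct.RiskFactorProfile(sex="female", age=55, sbp=160, current_smoker=True,
                                 diabetes=True, total_chol=7.0)
        score = ct.ten_year_risk(p, models["female"], zero)
        assert score.ten_year_risk == 0.0
        assert score.category == "very_low"

    def test_matches_independent_loop_oracle(self, rng):
        # independently coded 10-iteration loop over toy configurations
        models, table = random_table_and_models(rng)
        for _ in range(20):
            sex = "male" if rng.random() < 0.5 else "female"
            p = ct.RiskFactorProfile(
                sex=sex, age=float(rng.uniform(40, 74.9)), sbp=float(rng.uniform(100, 200)),
                current_smoker=bool(rng.random() < 0.3), diabetes=bool(rng.random() < 0.1),
                total_chol=float(rng.uniform(3.5, 8.0)),
            )
            cum_surv = 1.0
            for t in range(10):
                aa = p.age + t
                cell = table.lookup(sex, aa)
                r_tot = 0.0
                for outcome, model in models[sex].items():
                    jhr = 1.0
                    for term in model.terms:
                        jhr *= math.exp(
                            (term.main_log_hr + term.age_interaction_log_hr * aa)
                            * (p.value(term.risk_factor) - cell.mean(term.risk_factor))
                        )
                    r_tot += jhr * cell.event_rates[outcome]
                cum_surv *= math.exp(-r_tot)
            score = ct.ten_year_risk(p, models[sex], table)
            assert score.ten_year_risk == pytest.approx(1 - cum_surv, abs=1e-12)

    def test_monotone_in_each_factor(self, lab_engine, nonlab_engine):
        # positive main log-HRs, interactions zeroed: risk strictly increases
        # when any single component increases
        for engine, variant, bumps in (
            (random_table_and_models(np.random.default_rng(7), "laboratory"),
             "laboratory",
             dict(sbp=10, current_smoker=True, diabetes=True, total_chol=1.0)),
            (random_table_and_models(np.random.default_rng(8), "non_laboratory"),
             "non_laboratory",
             dict(sbp=10, current_smoker=True, bmi=2.0)),
        ):
            models, table = engine
            models = {
                sex: {
                    o: ct.HazardModel(
                        outcome=m.outcome, sex=m.sex, variant=m.variant,
                        algorithm=m.algorithm,
                        terms=tuple(
                            HazardTerm(t.risk_factor, abs(t.main_log_hr), 0.0)
                            for t in m.terms
                        ),
                    )
                    for o, m in per_outcome.items()
                }
                for sex, per_outcome in models.items()
            }
            base_kw = dict(sex="male", age=58.0, sbp=135.0, current_smoker=False)
            if variant == "laboratory":
                base_kw.update(diabetes=False, total_chol=5.2)
            else:
                base_kw.update(bmi=26.0)
            base = ct.ten_year_risk(
                ct.RiskFactorProfile(**base_kw), models["male"], table
            ).ten_year_risk
            for factor, bump in bumps.items():
                kw = dict(base_kw)
                kw[factor] = (kw[factor] + bump) if not isinstance(bump, bool) else bump
                bumped = ct.ten_year_risk(
                    ct.RiskFactorProfile(**kw), models["male"], table
                ).ten_year_risk
                assert bumped > base, factor

    def test_cumulative_risk_monotone_and_bounded(self, rng):
        models, table = random_table_and_models(rng)
        for _ in range(10):
            p = ct.RiskFactorProfile(
                sex="female", age=float(rng.uniform(40, 74.9)),
                sbp=float(rng.uniform(90, 220)), current_smoker=True,
                diabetes=True, total_chol=float(rng.uniform(2, 10)),
            )
            traj = ct.ten_year_risk(p, models["female"], table).trajectory
            risks = traj.cumulative_risk
            assert all(0 <= r <= 1 for r in risks)
            assert all(b >= a for a, b in zip(risks, risks[1:]))

    def test_combination_modes_agree(self, lab_engine):
        # summing cause-specific hazards and multiplying cause-specific
        # survivals coincide exactly under the exponential transform
        models, table = lab_engine
        p = ct.RiskFactorProfile(sex="male", age=60, sbp=150, current_smoker=True,
                                 diabetes=False, total_chol=6.0)
        a = ct.ten_year_risk(p, models["male"], table, combination="sum_hazards")
        b = ct.ten_year_risk(p, models["male"], table, combination="product_of_survivals")
        assert a.ten_year_risk == pytest.approx(b.ten_year_risk, abs=1e-15)

    def test_baseline_age_basis_holds_cell_fixed(self, lab_engine):
        models, table = lab_engine
        p = ct.RiskFactorProfile(sex="male", age=63, sbp=150, current_smoker=True,
                                 diabetes=False, total_chol=6.0)
        attained = ct.ten_year_risk(p, models["male"], table, age_basis="attained")
        baseline = ct.ten_year_risk(p, models["male"], table, age_basis="baseline")
        # crossing band edges changes the cell under attained-age lookup
        assert attained.ten_year_risk != pytest.approx(baseline.ten_year_risk, rel=1e-6)

    def test_coverage_error_names_the_year(self, lab_engine):
        models, table = lab_engine
        # age 74 + follow-up reaches 83 (covered); truncate the table to force failure
        short = ct.RecalibrationTable.__new__(ct.RecalibrationTable)
        object.__setattr__(short, "region_label", "short")
        object.__setattr__(short, "base_year", 2020)
        object.__setattr__(
            short, "cells", tuple(c for c in table.cells if c.age_hi <= 80)
        )
        p = ct.RiskFactorProfile(sex="male", age=74, sbp=150, current_smoker=False,
                                 diabetes=False, total_chol=5.0)
        with pytest.raises(CoverageError) as exc:
            ct.ten_year_risk(p, models["male"], short)
        assert exc.value.year == 6  # attained age 80 first falls outside


class TestBatchScorer:
    def test_matches_scalar_loop(self, lab_engine, rng):
        models, table = lab_engine
        n = 300
        df = pd.DataFrame(
            {
                "sex": np.where(rng.random(n) < 0.5, "male", "female"),
                "age": rng.uniform(40, 74.9, n),
                "sbp": rng.uniform(100, 200, n),
                "current_smoker": (rng.random(n) < 0.25).astype(float),
                "diabetes": (rng.random(n) < 0.08).astype(float),
                "total_chol": rng.uniform(3.5, 8.5, n),
            }
        )
        out = score_batch(df, models, table)
        for i in rng.choice(n, 40, replace=False):
            row = df.iloc[i]
            p = ct.RiskFactorProfile(
                sex=row["sex"], age=row["age"], sbp=row["sbp"],
                current_smoker=row["current_smoker"], diabetes=row["diabetes"],
                total_chol=row["total_chol"],
            )
            expected = ten_year_risk(p, models[row["sex"]], table).ten_year_risk
            assert out["ten_year_risk"].iloc[i] == pytest.approx(expected, abs=1e-10)
        assert (out["risk_pct"] == out["ten_year_risk"] * 100).all()

    def test_variant_separation(self, lab_engine, nonlab_engine):
        """Laboratory scoring never reads BMI; non-laboratory never reads
        diabetes or cholesterol (checked with instrumented frames)."""
        reads: set[str] = set()

        class Spy(pd.DataFrame):
            @property
            def _constructor(self):
                return Spy

            def __getitem__(self, key):
                if isinstance(key, str):
                    reads.add(key)
                return super().__getitem__(key)

        base = dict(
            sex=["male", "female"], age=[60.0, 55.0], sbp=[140.0, 130.0],
            current_smoker=[1.0, 0.0], diabetes=[0.0, 1.0],
            total_chol=[5.5, 6.0], bmi=[27.0, 25.0],
        )
        models, table = lab_engine
        reads.clear()
        score_batch(Spy(pd.DataFrame(base)), models, table)
        assert "bmi" not in reads

        models, table = nonlab_engine
        reads.clear()
        score_batch(Spy(pd.DataFrame(base)), models, table)
        assert "diabetes" not in reads and "total_chol" not in reads

    def test_incomplete_cases_rejected(self, lab_engine):
        models, table = lab_engine
        df = pd.DataFrame(
            dict(sex=["male"], age=[60.0], sbp=[np.nan], current_smoker=[1.0],
                 diabetes=[0.0], total_chol=[5.0])
        )
        with pytest.raises(ScoringIneligibleError):
            score_batch(df, models, table)
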