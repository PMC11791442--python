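# Methods

This note documents the models, estimators, defaults, and design choices
behind `cvdtrends`, and what the synthetic-data experiments do and do not
demonstrate.

## Recalibrated 10-year risk

The engine implements the standard recalibration arithmetic of global CVD
risk scores. Per follow-up year *t* = 0..9 with attained age *aₜ*:

1. distance of each component from the group mean at *aₜ*:
   *dⱼ = xⱼ − x̄ⱼ(aₜ)* (binaries 0/1 against the group prevalence);
2. log-HR contribution *(βⱼ + γⱼ·aₜ)·dⱼ* with the age-interaction γⱼ
   applied at the attained age;
3. factor HRs exponentiate and multiply into the joint HR;
4. one-year risk = joint HR × annual event rate, per outcome (CHD, stroke);
5. outcome risks combine; one-year survival = exp(−risk);
6. cumulative survival is the running product; 10-year risk is one minus
   the cumulative survival at *t* = 9, clipped to [0, 1] with a warning if
   the excursion exceeds 1e−9 (pure double-precision arithmetic otherwise;
   no intermediate clamping).

Choices where the procedure leaves room:

* **Outcome combination.** Cause-specific one-year hazards are summed
  before the survival transform (`sum_hazards`). The alternative
  `product_of_survivals` mode multiplies per-outcome survivals — under the
  exponential transform these are *algebraically identical*
  (exp(−(r₁+r₂)) = exp(−r₁)·exp(−r₂)), so the switch exists for interface
  clarity and is covered by an equality test rather than a tolerance.
* **Cell lookup during follow-up.** Recalibration cells are indexed by
  attained age each year (default), consistent with a 60-year-old reaching
  age 69 in year 9. A `baseline` mode holds the year-0 cell fixed for the
  whole horizon (some published implementations appear to do this for some
  inputs); the age interaction always uses attained age.
* **Category boundaries.** The conventional 5/10/20/30% labels are applied
  left-closed/right-open, so 5% is "low", 10% "moderate", 30% "very high".
* **Sex interactions.** Sex differences are realized as separate
  sex-specific coefficient tables rather than explicit interaction terms;
  no equivalence with any published software's internal parameterization is
  asserted.
* **Complete cases only.** A missing component raises a scoring-ineligible
  error; nothing is imputed.

Tables are validated on load: each variant's models must cover exactly its
component set, age bands must tile [40, 85) disjointly per sex (a
74-year-old reaches 83 in year 9), prevalences must be proportions, event
rates non-negative.

### Illustrative default tables

The shipped coefficients and recalibration inputs are invented
demonstration values with realistic magnitudes: positive main log-HRs with
negative age interactions (proportional effects attenuate with age), event
rates rising roughly exponentially with age and higher in men for CHD,
smoking and diabetes effects somewhat stronger in women in the
Globorisk-style set, and Globorisk-style event rates scaled lower so its
absolute scores sit below the WHO-style ones. Any substantive analysis
must supply real published tables through the YAML schema.

## Harmonization

All adjustments read raw columns and write new harmonized columns, gated on
era metadata — running the harmonizer on its own output changes nothing
(idempotence is tested).

* **BP device era.** Pre-2003 Dinamap readings convert to the Omron scale
  by the calibration-study regression (systolic 8.90 + 0.91·x, diastolic
  19.78 + 0.73·x).
* **SBP selection.** Mean of the second and third *valid* readings. The
  strict rule (default) requires at least three valid readings; a lenient
  rule averages the valid readings after the first and needs two. The
  strict rule re-ranks validity (an invalid first reading promotes the
  rest), which is one of two defensible readings of "second and third
  valid"; both are implemented.
* **Cholesterol eras.** 2011–2014 assay values shift down 0.1 mmol/L onto
  the pre-2010 scale; the post-2015 calibrator restored equivalence, so no
  shift outside that window.
* **HbA1c.** Percent values in [2.5, 24.9] convert to mmol/mol by the
  standard linear equation (10.93·NGSP − 23.50; constants recorded in
  `harmonize.py`); out-of-range percentages become missing. The
  post-calibrator-change correction adds +1/+2/+3 mmol/mol for values
  16–41/42–68/≥69; values below 16 pass unchanged.
* **Outlier bounds.** Exactly the printed strict inequalities — SBP <60 or
  >270 mm Hg, height <1.2 or >2.2 m, weight <35 kg (men) / <25 kg (women)
  or >250 kg, BMI <10 kg/m² (recomputed from post-filter height/weight),
  total cholesterol <1.8 or >20 mmol/L. Boundary values survive.
* **Age.** Continuous where released; otherwise the 5-year band midpoint
  (lo + 2); open-ended top bands resolve to missing (irrelevant within
  40–74).
* **Eligibility.** Per variant: survey year in the variant's series
  (laboratory: 1998, 2003, 2006, 2009–2017; non-laboratory: 1998,
  2001–2003, 2005–2017; 1999/2000/2004 are boost-only years), general
  population sample only, age 40–74, all components non-missing (2006
  records without the diabetes/CVD interview module are ineligible for the
  laboratory variant), and a non-missing stage weight in weighted years.
  One reason is recorded per excluded record in flowchart priority order,
  and the audit identity records_in = eligible + Σ excluded holds per year.
* **Weights.** Blood-sample weights for the laboratory variant, nurse
  weights for the non-laboratory variant, fixed at 1 before 2003, then
  rescaled to mean 1 within each year's analytic sample.

## Design-based estimation

Weighted means are ratio estimators with Taylor-linearized variances using
with-replacement PSU totals within strata; design df = ΣPSU − Σstrata.
The trend model is weighted least squares of the outcome on calendar year
(centered internally for conditioning; slope and SE are invariant) with the
cluster-robust sandwich over PSU score totals within strata. Wald tests
between two survey years assume independent samples (each cross-section
draws a fresh sample).

* **Reference distribution:** t with design df, switching to normal above
  200 df — standard survey practice; two-sided p-values, 0.05 threshold.
* **Lonely PSUs:** single-PSU strata contribute their squared deviation
  from the grand mean of PSU totals (certainty centering) with a warning;
  collapsing into the nearest multi-PSU stratum is available.
* **Stratification:** per-year estimates use the year's strata; pooled
  trend models use the region-like stratum.
* **Validation:** the linearized SE equals the textbook SRS formula in the
  degenerate design exactly, agrees with a stratified delete-one-PSU
  jackknife to ~5% on small instances, with a 10,000-replicate stratified
  (Rao–Wu) PSU bootstrap to 10%, and with statsmodels' cluster-robust WLS
  up to its known finite-sample correction factor.

## Synthetic data

The generator's defaults define the study conditions: 17 cross-sections
(1998, 2001–2003, 2005–2017), 9 region-like strata × 8 PSUs × 70 persons
(~5,000 interviewed adults/year), and linear drifts calibrated so the
1998→2017 changes approximate the observed component deltas — SBP −8/−10
mm Hg (men/women), total cholesterol −0.6/−0.5 mmol/L, BMI +1.1/+1.0
kg/m², smoking −5 points in women (−3 in men), diagnosed diabetes +6/+3
points. Baseline levels (e.g. male SBP 138 mm Hg, total cholesterol 6.0
mmol/L, smoking 28%) are plausible 1998 values for a high-income adult
population. A `risk_index` column carries a −0.09 units/year injected
drift for parameter recovery.

Structural features: truncated-normal ages (mean 52, SD 16, range 16–90);
age gradients around age 50 (e.g. +0.45 mm Hg SBP per year of age, logit
gradients for smoking and diabetes); PSU-level random effects on SBP
(SD 2 mm Hg) and the risk index (SD 0.5) to make clustering consequential;
logistic nurse/blood participation declining with age; weights as inverse
true participation probabilities rescaled to mean 1; pre-2003 readings
stored on the Dinamap scale by inverting the calibration regression;
banded-only ages in 2016–2017; a split diabetes module in 2006; boost
samples in 2002 and 2005; ~0.2% gross outliers and a few percent item
missingness rising with age. Per-year RNG substreams are derived
deterministically from (seed, year), so adding a year never perturbs
another.

Known simplifications: continuous factors are normal (real SBP, BMI, and
cholesterol distributions are right-skewed), household clustering below
PSU level is not simulated, participation depends only on age and sex, and
no socioeconomic gradients are generated. Passing tests therefore
demonstrate the correctness of the *pipeline arithmetic and estimator
calibration* under a known truth, not the behaviour of the method on any
real survey series.

## Experiment sizes

The validation experiments run at sizes chosen to exercise the estimators
meaningfully on a single CPU: the trend-recovery experiment uses 100
replicates of the full default scenario (~85,000 records each); the
bootstrap variance check uses 10,000 replicates on a 500-record clustered
design; oracle-equivalence checks use 1,000 random profiles. The end-to-end
trend-direction check runs the default scenario once per algorithm ×
variant.

## Limitations

* Shipped tables are illustrative; absolute risk levels computed from them
  are demonstrations, not estimates of any real population's risk.
* Complete-case analysis matches the upstream design but can bias trend
  estimates if missingness patterns drift over time.
* The Wald and trend tests treat years as independent samples; any shared
  PSU frames across years would induce covariance the estimator ignores.
* No replicate-weight (BRR/Fay) variance methods and no multiple
  imputation, by design.
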