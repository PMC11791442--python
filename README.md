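# cvdtrends

Tools for estimating population trends in predicted 10-year cardiovascular
disease (CVD) risk from repeated cross-sectional health-examination surveys.

Annual surveys such as health examination series measure blood pressure,
cholesterol, smoking, diagnosed diabetes, and body size on fresh samples of
the population each year. Pooling two decades of such cross-sections lets
epidemiologists ask whether *predicted* absolute CVD risk — the summary a
clinician would compute for each participant — has been rising or falling,
and which components drive the change. Doing that defensibly requires three
things this package provides:

1. **Harmonization** (`cvdtrends.harmonize`): raw yearly extracts differ by
   measurement device (Dinamap vs Omron BP monitors), laboratory calibrators
   (total cholesterol, HbA1c), age release format (continuous vs 5-year
   bands), boost samples, and staged nonresponse weighting. The harmonizer
   applies era-gated conversions, strict printed outlier bounds, component
   derivations, variant eligibility with full audit counts, and stage-weight
   selection.
2. **Risk scoring** (`cvdtrends.risk_engine`): a fully table-driven engine
   for recalibrated 10-year total (fatal plus nonfatal) CVD risk in the
   style of the WHO and Globorisk global risk scores, in laboratory
   (SBP, smoking, diabetes, total cholesterol) and non-laboratory
   (SBP, smoking, BMI) variants.
3. **Design-based estimation** (`cvdtrends.survey_stats`): weighted means
   and proportions with Taylor-linearized standard errors for stratified
   PSU samples, Wald tests between survey years, and survey-weighted linear
   trend regression with a cluster-robust sandwich variance.

A synthetic-data generator (`cvdtrends.synthgen`) reproduces the structural
features of such a survey series — two-stage design, staged nonresponse
with scaled weights, device eras, secular trends, item missingness — so the
whole pipeline is testable end to end without any restricted-access data.

## The model

For a participant with risk-factor vector $x$ and baseline age $a$, each
follow-up year $t = 0,\dots,9$ uses the attained age $a_t = a + t$ to look
up sex- and age-band-specific population means $\bar x(a_t)$ and annual
event rates $\lambda_o(a_t)$ for each outcome $o \in \{\text{CHD},
\text{stroke}\}$. The risk-factor-specific hazard ratio is

$$\mathrm{HR}_j(t) = \exp\!\big[(\beta_j + \gamma_j a_t)\,(x_j - \bar x_j(a_t))\big],$$

with $\beta_j$ the main log hazard ratio and $\gamma_j$ its age
interaction (binary factors are coded 0/1 with the group prevalence as the
mean). The joint HR is $\prod_j \mathrm{HR}_j(t)$; the one-year risk is
$r_o(t) = \mathrm{HR}(t)\,\lambda_o(a_t)$, summed across outcomes; the
one-year survival is $e^{-r(t)}$ (a one-year risk of 0.06 gives survival
$e^{-0.06} = 0.942$); and the predicted absolute 10-year risk is

$$R_{10} = 1 - \prod_{t=0}^{9} e^{-r(t)} .$$

Risks are categorized as very low (<5%), low (5%–10%), moderate (10%–20%),
high (20%–30%), and very high (≥30%), with left-closed bands.

**Coefficients and recalibration inputs are inputs, never fitted.** The
engine consumes a validated YAML schema of log-HR terms and recalibration
cells. The shipped defaults (`cvdtrends.tables.illustrative_tables`) are
clearly-labelled *illustrative* values with plausible epidemiologic
magnitudes; they are not the published WHO or Globorisk coefficients.

## Worked example

```python
import cvdtrends as ct

models_by_sex, table = ct.default_engine("who_style", "laboratory")
profile = ct.RiskFactorProfile(sex="male", age=60, sbp=152,
                               current_smoker=True, diabetes=False,
                               total_chol=6.2)
score = ct.ten_year_risk(profile, models_by_sex["male"], table)
print(f"{score.ten_year_risk:.1%} ({score.category})")
```

prints `26.6% (high)`: a 60-year-old male smoker with SBP 152 mm Hg and
total cholesterol 6.2 mmol/L has, under the illustrative tables, a 26.6%
predicted probability of a first fatal or nonfatal CVD event within 10
years — in the 20%–30% "high" band. His joint hazard ratio starts at 5.13
at age 60 and attenuates to 3.47 by age 69 as the age interactions shrink
the proportional effects and the group means shift under him.

Running the full synthetic pipeline (`examples/04_survey_estimates.py`)
scores a generated laboratory-variant sample and prints, for men, a mean
10-year risk of 13.96% (SE 0.48%) in 1998 falling to 11.79% (SE 0.38%) in
2017, a first-vs-last Wald test of z = −3.54 (p = 0.00063), and a fitted
linear trend near −0.1 percentage points per calendar year: predicted risk
declines significantly as the injected component trends (falling SBP,
cholesterol, and smoking, despite rising BMI and diabetes) play through the
score.

Each script in `examples/` is a short narrative of one capability:
individual scoring, harmonization edge cases, generation and audit,
design-based estimation, and the one-call pipeline. The same pipeline is
available as a thin CLI:

```bash
cvdtrends run-all --out-dir out/ --seed 1
```

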