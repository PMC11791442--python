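"""Generate a small synthetic survey series and audit variant eligibility.

The generator reproduces the structural quirks the pipeline must survive:
staged nonresponse with scaled weights, a pre-2003 device era, banded ages
in the last two years, a split diabetes module in 2006, and boost samples.
The audit table shows where records leave the flow for each score variant.
"""

from cvdtrends import harmonize as hz
from cvdtrends.synthgen import DesignParams, TrendScenario, generate_pooled

scenario = TrendScenario(
    design=DesignParams(n_strata=9, psus_per_stratum=4, persons_per_psu=30), seed=7
)
raw = generate_pooled(scenario)
print(f"raw records: {len(raw)} over {raw.survey_year.nunique()} survey years")

harmonized = hz.harmonize_records(raw)
for variant in ("laboratory", "non_laboratory"):
    analytic, audit = hz.build_analytic(harmonized, variant)
    print(f"\n{variant}: analytic n = {len(analytic)}")
    print(audit.groupby("status")["count"].sum().to_string())
    assert audit["count"].sum() == len(raw)  # flowchart conservation
# Exclusions are dominated by the 40-74 age window and missing components
# (nurse/blood nonresponse), mirroring the structure of real survey flows.
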