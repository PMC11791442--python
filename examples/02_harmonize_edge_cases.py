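"""Harmonization edge cases: device conversion, reading selection, outliers.

Feeds the canned ``edge_bp`` fixture through the harmonizer and shows which
blood-pressure values survive: boundary readings (exactly 60 or 270 mm Hg)
are kept because the outlier bounds are strict inequalities, a missing
second valid reading defeats the strict selection rule, and Dinamap-era
readings come back on the Omron scale.
"""

from cvdtrends import harmonize as hz
from cvdtrends.synthgen import make_fixture

raw = make_fixture("edge_bp")
harmonized = hz.harmonize_records(raw)

for _, row in harmonized.iterrows():
    print(
        f"{row['psu']}: device={row['bp_device']:8s} readings="
        f"({row['sbp1']:.1f}, {row['sbp2']:.1f}, {row['sbp3']:.1f}) "
        f"-> SBP = {row['sbp']}"
    )
print("\nper-field outlier removals:", harmonized.attrs["outlier_counts"])
# P1/P3 keep boundary values; P2/P4 are nulled; P5 fails the strict
# second-and-third-valid rule; P7 recovers 125.0 from Dinamap storage.
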