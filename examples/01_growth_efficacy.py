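"""Tumor growth efficacy: volume, T/C, TGI and the resistance call.

Builds a small two-arm caliper table for one passage (3 treated and 3
vehicle mice) and summarizes antitumor efficacy at the endpoint day.
"""

from clonaltraj import (
    GrowthRecord,
    comparison_from_records,
    efficacy,
    group_summary,
    resistance_call,
    tumor_volume,
)

# caliper length/width -> hemi-ellipsoid volume (L x W^2)/2
print(f"volume of a 10 x 10 mm tumor: {tumor_volume(10, 10):.0f} mm^3")

records = []
for i, (t_end, v_end) in enumerate(zip((780, 640, 995), (1180, 1550, 1115))):
    records += [
        GrowthRecord(f"t{i}", "treatment", 0, 190.0 + 10 * i),
        GrowthRecord(f"t{i}", "treatment", 21, float(t_end)),
        GrowthRecord(f"v{i}", "vehicle", 0, 200.0 + 10 * i),
        GrowthRecord(f"v{i}", "vehicle", 21, float(v_end)),
    ]

mean, sd, n = group_summary(records, "treatment", 21)
print(f"treatment day 21: {mean:.0f} [{sd:.0f}] mm^3 (n={n})")

comp = comparison_from_records(records, baseline_day=0, day=21)
eff = efficacy(comp)
call = resistance_call(eff)
print(f"T/C = {eff.t_over_c_percent:.2f}%  TGI = {eff.tgi_percent:.2f}%  -> {call}")

# T/C is the treatment-to-vehicle growth ratio in percent and TGI its
# complement (100 - T/C): a TGI above the 30% convention means the drug
# still suppresses growth in this passage; negative TGI means treated
# tumors grew faster than vehicle.
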