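"""End-organ perfusion: relative differences vs pump alone, oxygen-vs-work axis.

Reads the estimated cohort records from the metrics driver and writes the
tidy plot data: per-stage paired relative differences (with t-based 95% CIs)
for the venous saturations and lactate, and the stage-mean SvO2 vs cardiac
work pairs for the delivery-versus-work scatter.
"""

import pandas as pd
from _common import RESULTS

from pvshock.perfusion import oxygen_axis_summary, relative_difference_vs_reference

records = pd.read_csv(RESULTS / "cohort_records_estimated.csv")

rel = pd.concat([
    relative_difference_vs_reference(records, var, "impella")
    for var in ("SvO2", "renal_vO2", "cerebral_vO2", "arterial_lactate",
                "venous_lactate")
], ignore_index=True)
rel.to_csv(RESULTS / "fig2_relative_differences.csv", index=False,
           float_format="%.6g")

ox = oxygen_axis_summary(records)
ox.to_csv(RESULTS / "fig3_oxygen_vs_work.csv", index=False, float_format="%.6g")

print("relative difference vs pump alone (mean %, [95% CI]):")
for var, grp in rel.groupby("variable", sort=False):
    print(f"  {var}:")
    for _, r in grp[grp.stage.str.startswith("impella_")].iterrows():
        print(f"    {r.stage.removeprefix('impella_'):8s} "
              f"{100 * r.estimate:+6.1f}% [{100 * r.ci_lo:+6.1f}, {100 * r.ci_hi:+6.1f}]")

print("\noxygen delivery vs cardiac work (stage means):")
for _, r in ox.iterrows():
    print(f"  {r.stage:16s} SvO2 {r.SvO2:5.1f}%   HRxPVA {r.cardiac_work / 1e3:6.1f}e3")
print(f"\nwrote {RESULTS / 'fig2_relative_differences.csv'} and fig3_oxygen_vs_work.csv")
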