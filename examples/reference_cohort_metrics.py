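"""Recompute headline detection metrics from the packaged reference table.

The packaged CSV lists, per lesional hemisphere of an 11-patient surgical-
epilepsy cohort, whether thickness, gray/white contrast and their union
detected the traced lesion at z > 4, plus the extra-lesional cluster burden.
"""
from surfmorph.evaluation import sensitivity
from surfmorph.reference import (extra_lesional_fraction_pct,
                                 load_reference_cohort,
                                 union_sensitivity_pct)

table = load_reference_cohort()
print(table.to_string(index=False))
print()
for measure in ("thickness", "gwc", "union"):
    flags = [v == "yes" for v in table[f"{measure}_detected"]]
    print(f"{measure:10s} sensitivity: {sensitivity(flags):5.1f}% "
          f"({sum(flags)}/{len(flags)} hemispheres)")
print()
print(f"union sensitivity (whole %):            {union_sensitivity_pct(table)}")
print(f"patients with extra-lesional clusters:  "
      f"{extra_lesional_fraction_pct(table)}%")
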