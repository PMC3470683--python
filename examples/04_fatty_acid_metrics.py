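"""O/L ratios and unsaturation from the packaged composition table.

The oleate/linoleate (O/L) percentage ratio tracks desaturase activity:
knockdown of desaturase mRNA moves mass from linoleate into oleate.  Bands
of the ratio mimic desaturase genotypes, from the wild type (low-normal)
toward the ol1ol1ol2ol2 double mutant (high-normal, the PK treatment).
"""

from permutome import classify_ol, ol_ratio, percent_saturated, percent_unsaturated
from permutome.io import load_table2_profiles

for profile in load_table2_profiles():
    ratio = ol_ratio(profile)
    band = classify_ol(ratio.value)
    print(f"{profile.treatment:8s} O/L={ratio.rounded:4.2f} "
          f"unsat={percent_unsaturated(profile):4.1f}% "
          f"sat={percent_saturated(profile):4.1f}%  {band.name:11s} "
          f"({band.genotype_label})")
print("-> total unsaturation stays near 83 % under every treatment while")
print("   the O/L ratio shifts from ~1.3 (control) to 3.31 (PK).")
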