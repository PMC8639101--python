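"""Limit of detection by the hit-rate approach, and coverage power.

A dilution series (neat to 1:32) with replicate testing per level yields a
percent-detection table; the LoD is the most dilute level with a 100% hit
rate, requiring every more concentrated level to be perfect too.
"""

from cgpval import (
    DilutionLevel,
    DilutionSeries,
    binomial_power,
    hit_rate_lod,
    min_coverage,
)

series = DilutionSeries(
    analyte="EGFR_T790M_vaf",
    levels=(
        DilutionLevel(0.10, (True,) * 6),
        DilutionLevel(0.05, (True,) * 6),
        DilutionLevel(0.025, (True,) * 5 + (False,)),
        DilutionLevel(0.0125, (True, False, True, False, True, False)),
    ),
)
table, lod = hit_rate_lod(series)
print(table.round(3).to_string(index=False))
print(f"hit-rate LoD (100% detection): VAF {lod}")

print(f"\npower to see >=4 mutant reads at 2% VAF with 400x depth: "
      f"{binomial_power(400, 0.02):.3f}")
print(f"minimum depth for 95% power at 2% VAF: {min_coverage(0.02)}x")
print(f"minimum depth for 95% power at 5% VAF: {min_coverage(0.05)}x")
# 400x is a round safe minimum for 2% VAF calling; the exact binomial
# answer sits slightly below it.
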