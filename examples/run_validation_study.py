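"""The full synthetic validation study in one call.

Runs accuracy (per-class PPA/NPA vs planted truth), precision (replicate
APA/ANA and TMB %CV) and limit-of-detection (dilution series) stages on a
seeded synthetic cohort and prints the headline numbers.
"""

import json

from cgpval import RunConfig, run_validation_study

report = run_validation_study(RunConfig(seed=1))

print("provenance:", report["provenance"])
print("\naccuracy (per variant class):")
for name, block in report["accuracy"].items():
    parts = []
    for key in ("ppa", "npa"):
        if key in block:
            parts.append(f"{key.upper()} {block[key]['percent']:.1f}% "
                         f"({block[key]['fraction']})")
    print(f"  {name:15s} {'  '.join(parts)}")

precision = report["precision"]
overall = precision["apa_ana_overall"][0]
print(f"\nprecision: APA {overall['apa']:.1f}%  ANA {overall['ana']:.1f}%  "
      f"TMB CV {precision['tmb_cv_percent']:.1f}% "
      f"(<=12.5%: {precision['tmb_cv_acceptance']})")

print(f"\nLoD: Tier I small variant at VAF {report['lod']['small_variant_vaf']['lod']}, "
      f"MSI at tumor purity {report['lod']['msi_purity']['lod']}")
print(json.dumps(report["lod"]["msi_purity"]["table"], indent=2)[:400], "...")
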