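"""Copy-number fold change as a function of tumor purity.

A tumor specimen is a mixture of tumor and normal diploid cells, so the
observed per-gene fold change is pulled toward 1 as purity drops. This
script evaluates the mixture model at its two anchor points, classifies a
few observed fold changes, and inverts the model to ask how much tumor
content a call needs.
"""

from cgpval import GeneRole, classify_copy_number, expected_fold_change, min_purity_for_call

print("FC for 10 copies at 30% purity:", expected_fold_change(0.30, 10))
print("FC for 0 copies (homozygous deletion) at 50% purity:", expected_fold_change(0.50, 0))
print("FC for a diploid gene at any purity:", expected_fold_change(0.42, 2))

for fc in (3.73, 2.2, 1.8):
    print(f"oncogene FC {fc}:", classify_copy_number(fc, GeneRole.ONCOGENE_GAIN).value)
for fc in (0.45, 0.62, 0.77):
    print(f"tumor-suppressor FC {fc}:", classify_copy_number(fc, GeneRole.TSG_LOSS).value)

print("minimum purity to detect homozygous loss:",
      min_purity_for_call(0, GeneRole.TSG_LOSS))
print("minimum purity to reach the gain-indeterminate cut with 10 copies:",
      min_purity_for_call(10, GeneRole.ONCOGENE_GAIN))
print("4 copies:", min_purity_for_call(4, GeneRole.ONCOGENE_GAIN),
      "(inf = below the cut at every purity)")
# The FC >= 2.2 cut means modest gains are only callable in high-purity
# specimens, while homozygous deletions need >= 50% tumor content.
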