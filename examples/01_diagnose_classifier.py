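"""Diagnose a binary classification model from its 2x2 contingency table.

The published logBB classifier's training-set table (recovered from its
summary statistics) is pushed through the full diagnostic battery.
"""

from predictivity import ContingencyTable, diagnose, render_report

# training set of the 4-descriptor logBB model: 25 true positives,
# 11 false positives, 14 false negatives, 31 true negatives
table = ContingencyTable(tp=25, fp=11, fn=14, tn=31)
report = diagnose(table)

print(render_report({"training": report}))
print()
print(
    f"The model classifies {report.ac:.1f}% of the {table.n} compounds "
    f"correctly; it is better at recognizing non-penetrating compounds "
    f"(specificity {report.sp:.1f}%) than penetrating ones (sensitivity "
    f"{report.se:.1f}%), and the odds of a correct call in the active "
    f"group are {report.or_:.1f}x the odds of an incorrect call in the "
    f"inactive group."
)
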