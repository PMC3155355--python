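"""Summarize the packaged 122-compound blood-brain-barrier dataset.

Prints descriptive statistics and normality diagnostics for the training
and test subsets of the built-in logBB property table.
"""

from predictivity import load_property_table, summarize_set

records = load_property_table("table4")
print(f"{len(records)} compounds "
      f"({sum(r.set_label == 'training' for r in records)} training, "
      f"{sum(r.set_label == 'test' for r in records)} test)\n")

for which in ("training", "test", "all"):
    s = summarize_set(records, which)
    print(f"{which:9s} n={s.n:3d}  mean={s.mean:8.4f}  sd={s.stdev:.4f}  "
          f"range=[{s.min:.2f}, {s.max:.2f}]  KS={s.ks_stat:.4f} "
          f"(p={s.ks_p:.3f})")

print(
    "\nlogBB is the log10 brain:blood concentration ratio; a KS p-value "
    "above 0.05 means normality of the property is not rejected, which "
    "both subsets satisfy."
)
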