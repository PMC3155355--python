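# predictivity

Contingency-table predictivity diagnostics for binary QSPR/QSAR
classification models, with the supporting machinery of a full
model-identification study.

## The problem

A quantitative structure–property model estimates a continuous property —
here logBB, the log10 brain-to-blood concentration ratio that measures
blood-brain-barrier permeation — but is often *used* as a classifier:
a compound with logBB ≥ 0 penetrates the barrier (BBB+, "active"), one
with logBB < 0 does not. Goodness-of-fit statistics (R², F) say nothing
about how well the dichotomized predictions agree with the dichotomized
observations. This package diagnoses that agreement and lets you compare
competing models on it.

Observed and estimated classes are cross-tabulated:

|                    | predicted active | predicted inactive |
|--------------------|------------------|--------------------|
| **observed active**   | TP               | FN                 |
| **observed inactive** | FP               | TN                 |

and summarized by fifteen parameters — accuracy `AC = 100(TP+TN)/n`,
error rate, class prior probabilities `nᵢ/n`, sensitivity
`Se = 100·TP/(TP+FN)`, specificity `Sp = 100·TN/(TN+FP)`, the
false-negative/-positive rates, positive/negative predictivity, the
post-test classification probabilities `(TP+FP)/n` and `(FN+TN)/n`, the
probabilities of wrong classification `FP/(FP+TP)` and `FN/(FN+TN)`, and
the odds ratio `OR = TP·TN/(FP·FN)` — each with a 95% binomial confidence
interval (Clopper-Pearson by default, Wilson optional), plus the
Yates-corrected χ² and the association coefficient Φ = √(χ²/n).

Around this core the package provides the rest of the workflow: a packaged
122-compound logBB dataset (81 training / 41 test), descriptor validity
filters (Jarque-Bera normality, identity analysis, inter-correlation
pruning), OLS subset search with `F = (R²/k)/((1−R²)/(n−k−1))`,
leave-one-out cross-validation (q² statistics), the seven-coefficient
correlation battery (Pearson r, semi-quantitative r_sQ, Spearman ρ,
Kendall τa/τb/τc, Goodman-Kruskal Γ), Durbin-Watson autocorrelation, and
Fisher-z comparison of two models' correlation coefficients. Real
fragment-family descriptor values are not redistributable, so a seeded
synthetic generator with controlled signal strength and collinearity
stands in for them.

## Worked example

```python
from predictivity import ContingencyTable, diagnose, render_report

table = ContingencyTable(tp=25, fp=11, fn=14, tn=31)  # training set, n=81
print(render_report({"training": diagnose(table)}))
```

prints (abridged):

```
Parameter                                   training (n=81)
---------------------------------------------------------------
Chi-squared (p)                             10.29 (0.0013)
Phi                                         0.3564
Accuracy (AC)                               69.14 [57.89-78.93]
Sensitivity (Se)                            64.10 [47.18-78.80]
Specificity (Sp)                            73.81 [57.96-86.14]
Positive predictivity (PP)                  69.44 [51.89-83.65]
Odds ratio (OR)                             5.03 [1.95-13.00]
```

The model classifies 69% of compounds correctly and is better at
recognizing non-penetrating compounds (Sp ≈ 74%) than penetrating ones
(Se ≈ 64%); the χ² p-value of 0.0013 shows the classification is
genuinely associated with the observed classes. A published table that
prints only `(n, prevalence, Se, Sp)` can be turned back into exact cell
counts with `reconstruct_table(81, 0.482, 64.10, 73.81)`.

The `examples/` directory holds one short script per capability
(diagnosis, dataset summaries, model search with leave-one-out,
the correlation battery, model comparison). A thin CLI mirrors the
library, e.g.:

```sh
predictivity diagnose --tp 25 --fp 11 --fn 14 --tn 31
predictivity compare-r --r1 0.7816 --n1 81 --r2 0.8425 --n2 88
predictivity pipeline --seed 1 --out bundle.json
```

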