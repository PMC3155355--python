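# Methods

## Model and scope

The package treats a continuous structure–property model as a binary
classifier. The property (logBB, the log10 brain:blood steady-state
concentration ratio) is dichotomized at a threshold (default 0.0, the
boundary value counting as active): a compound with logBB ≥ 0 penetrates
the blood-brain barrier. Observed and estimated labels are cross-tabulated
into a 2×2 contingency table and summarized by the fifteen-parameter
diagnostic battery, χ² and Φ. Everything else in the package — dataset
handling, descriptor filtering, regression with leave-one-out validation,
the correlation battery and model comparison — exists to produce,
validate or compare the models whose predictions feed that table.

## Diagnostic conventions

* **Scales.** AC, ER, Se, FNR, Sp, FPR, PP and NP are percentages; the
  prior and post-test probabilities and the probabilities of wrong
  classification are plain probabilities. This mirrors how such tables
  are conventionally printed.
* **χ² with Yates correction, clamped at zero.** The uncorrected
  statistic on the reference training table is 11.77; the corrected one,
  10.29, is what published tables of this kind report, and the corrected
  form is retained for all tables. Φ is defined as √(χ²/n) — note this is
  the continuity-corrected association measure, not the determinant-based
  phi coefficient (which gives 0.3812 on the same table).
* **Binomial CIs.** Clopper-Pearson (beta quantiles, via statsmodels) by
  default, Wilson optionally. Published intervals of this kind are often
  produced by bespoke methods; Clopper-Pearson agrees with typical
  printed bounds to within about two percentage points, which is the
  agreement asserted in the tests, never exact equality.
* **Odds-ratio CI.** Log-scale Wald:
  exp(ln OR ± z·√(1/TP + 1/FP + 1/FN + 1/TN)).
* **Zero cells.** Parameters whose denominator is zero, and the odds
  ratio when FP·FN = 0, are reported as undefined (`None`, rendered
  "n.a.") rather than propagating NaN; all other parameters are still
  computed.

## Table reconstruction

`reconstruct_table` inverts a printed summary `(n, prevalence, Se, Sp)`
into integer cell counts. The three summaries constrain disjoint cells —
prevalence fixes the observed-active margin, Se then fixes TP, Sp fixes
TN — so each is searched independently in O(n). A candidate matches when
Se and Sp agree within half a unit in the last printed place (±0.005 on a
2-decimal percent) and the prevalence within one unit (±0.001 on a
3-decimal proportion): printed priors are occasionally mis-rounded in
their final digit, and the wider band never costs uniqueness because
consecutive candidate margins differ by at least 1/n ≥ 0.0025 for the
n ≤ 400 range the identity tests cover. A 1e-9 epsilon guards printed
values that sit exactly on a half-ulp boundary (e.g. 15.625 → "15.62").
When nothing matches, the error lists the nearest candidate instead of
silently returning it.

## Dataset module

The packaged property table has 122 compounds with measured logBB, split
81 training / 41 test. Summaries use the sample (n−1) standard deviation
and a t-interval for the mean. Normality diagnostics are computed against
a normal with the subset's own moment estimates: the Kolmogorov-Smirnov
statistic on the fitted CDF, the Anderson-Darling A², and a chi-squared
goodness-of-fit on Sturges-count (⌈log₂ n⌉ + 1) *equal-probability* bins
with k − 3 degrees of freedom. Equal-probability bins were chosen over
equal-width because a single extreme value (the dataset contains a
logBB of −4.10) otherwise dominates the statistic through near-empty
tail bins; published chi-squared GOF values are highly sensitive to the
binning convention and are only sanity-checked, while KS and AD
reproduce reference values to four decimals. `random_split` partitions
at round(n·fraction) deterministically per seed; with
`require_normal=True` it redraws (cap 1000) until both subsets pass KS
at α = 0.05, emulating a randomization constrained to preserve
normality in both subsets.

## Synthetic descriptors

Fragment-family descriptor values for the packaged compounds are computed
by external proprietary tooling and are not redistributable, so the
generator produces standardized Gaussian stand-ins: `k_signal` columns
share a latent factor giving pairwise correlation `collinearity`
(equicorrelated block), the rest are independent noise, and the response
is the unit-weight sum of the signal columns plus Gaussian noise scaled
so the *population* R² equals `r2_target`. Defaults (n = 81, m = 10,
k_signal = 4, r2_target = 0.61, collinearity = 0.2) match the scale of
the logBB study: 81 training compounds, four retained descriptors, R²
near 0.61. What the synthetic data deliberately does not emulate:
non-normal marginal descriptor distributions, the heavy mutual
correlation structure of real fragment-count descriptors, and
heteroscedastic measurement error in logBB — so passing recovery tests
demonstrate correctness of the estimation machinery, not real-data
performance of any descriptor family.

### Validity filters

Three screens, applied in order and idempotent as a whole:

1. **Normality relative to the activity.** A descriptor passes if its
   Jarque-Bera statistic `n(S²/6 + (K−3)²/24)` does not exceed
   max(JB of the response, χ²₂ critical value at `jb_alpha`). The
   statistic-vs-statistic comparison implements "no less normal than the
   activity"; the conventional JB test acts as a floor because when the
   activity sample happens to be unusually close to normal the bare
   comparison would reject roughly half of all genuinely normal
   descriptors, which no screening step should do.
2. **Identity analysis.** Columns identical after z-score
   standardization (which also catches affine duplicates aX+b) are
   reduced to their first occurrence.
3. **Inter-correlation pruning.** Of any pair with |r| > `corr_max`
   (default 0.95), the column more correlated with the response
   survives; residual ties fall to column order, keeping the result
   deterministic.

## Regression

OLS is computed directly via least squares on the augmented design
matrix, with R defined as the Pearson correlation between observed and
fitted values, residual standard error on n−k−1 degrees of freedom,
coefficient CIs as estimate ± t₀.₉₇₅,ₙ₋ₖ₋₁·SE, and
F = (R²/k)/((1−R²)/(n−k−1)) — the convention that reproduces the
reference F values (30, 22, 9) from their printed (R², n, k) triples.
The implementation is deliberately lightweight because the subset search
and leave-one-out run thousands of fits; statsmodels OLS serves as an
independent cross-check in the test suite rather than as the
implementation.

Leave-one-out predictions use the exact hat-matrix identity
ŷ₋ᵢ = yᵢ − eᵢ/(1−hᵢᵢ); the test suite verifies it against an explicit
n-refit loop. `r_loo` is the Pearson correlation of observed values with
held-out predictions and `s_loo = √(PRESS/(n−k−1))` — the same
denominator as the fit standard error, consistent with s_loo > s_est on
reference outputs.

`search_models` is exhaustive over subsets of size ≤ max_k when the pool
has ≤ 25 columns (deterministic, and cheap at the package's intended
scale), greedy forward selection beyond that. Ranking is lexicographic:
R rounded to 4 decimals (descending), then fewer descriptors, lower
standard error, smaller |R − R_loo|. Rounding R first prevents float
noise from reordering effectively tied candidates and gives the
smallest-subset-wins behavior on exact ties.

## Correlation battery

Pearson, Spearman and Kendall τb/τc (with their p-values) come from
scipy. τa = (C−D)/(n(n−1)/2) and Γ = (C−D)/(C+D) are computed from an
O(n²) pair count (no installed implementation provides them); τa's
p-value uses the no-tie normal approximation, Γ's the Goodman-Kruskal
asymptotic normal approximation — rank-test p-values vary across
software by approximation variant and are not held to reference values.
The semi-quantitative coefficient r_sQ has no authoritative definition;
the default strategy is the Pearson correlation between observed values
and mid-ranks of the estimates (a value intermediate between r and ρ),
and the strategy table `RSQ_STRATEGIES` accepts alternates. r_sQ is
excluded from all exact checks.

Model comparison uses the two-independent-samples Fisher-z test,
Z = (atanh r₂ − atanh r₁)/√(1/(n₁−3) + 1/(n₂−3)), reporting the
one-sided upper-tail p of |Z| — the form that reproduces both reference
comparisons (Z = 1.15 and 1.65). The dependent-correlations variant for
two correlations sharing a variable on one sample is provided separately
(`compare_dependent_correlations`) but is not used by the pipeline.

## Pipeline and reproducibility

`run_full_pipeline` chains load → split → generate/load descriptors →
filter → search → fit → LOO → correlate → dichotomize → diagnose →
render, with every random draw seeded from `RunConfig.seed`; a rerun
with the same configuration is byte-identical (asserted in the tests).
Stage failures propagate with the stage name attached.

## Problem sizes in the test and acceptance suites

Oracle-equivalence suites run on small random instances (n ≤ 30,
k ≤ 4, 25–100 repetitions); the generator's R² calibration uses 200
Monte-Carlo replicates at n = 81; the F-test size check uses 2000
null simulations at n = 30; reconstruction identity uses random tables
up to n = 400; the acceptance script's subset-search recovery uses 25
planted-signal trials at n = 50, m = 8. These sizes make every property
estimate stable at the asserted tolerances while keeping the whole suite
in tens of seconds on one CPU.

## Known limitations

* The diagnostic battery is strictly binary; multi-class confusion
  matrices and ROC/threshold sweeps are out of scope.
* Reconstruction assumes the printed summaries are internally consistent
  at their stated precision; grossly inconsistent inputs fail with the
  nearest candidate rather than a best guess.
* The synthetic generator's Gaussian design understates the difficulty
  of real descriptor selection (see above).
* Printed confidence intervals produced by non-standard binomial methods
  can differ from Clopper-Pearson by up to ~2 percentage points at these
  sample sizes; the package makes no attempt to reverse-engineer such
  methods.
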