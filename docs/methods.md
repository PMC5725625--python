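# Methods

## Cycle and phase derivation

A woman's record is a sequence of menstruation-onset dates (stored
most-recent-first; recency index `j = 1` is the newest cycle) and a
set of dated ovulation records, each labelled with its basis
(`clinical`, `test_kit`, `other`). Cycle `j` spans onset `j+1` to
onset `j`; its length `c` is the elapsed-day difference. Derivation
order is: compute cycles → screen → attach ovulations. Since
attachment never alters `c`, screening before or after attachment
yields the same output; screening first is simply cheaper.

**Screening.** Cycles with `c < 20` or `c > 45` days are removed as
implausible input; the bounds are inclusive on the keep side (20 and
45 survive). Screening preserves each survivor's recency index, so a
removed cycle leaves a gap that disqualifies later cycles from
trailing-mean analyses that would span it.

**Phases.** An ovulation record qualifies for a cycle when its basis
is allowed (default: clinical and test-kit only; `other` is treated as
unreliable) and its date lies strictly between the two onsets. Then
`f = ovulation − start_onset` (days) and `l = c − f − 1`, i.e. the
luteal phase runs from the day after ovulation through the day before
the next onset. The identity `c = f + l + 1` is exact and is asserted
throughout. Records dated exactly on an onset are contradictory input
and are discarded with a warning. When two qualifying records fall in
one cycle the default is to leave the cycle unannotated (with a
warning); `duplicate_policy="earliest"` keeps the earlier record.
Dates are handled at day resolution only — what a user calls "day
one" is their subjective choice, and no sub-day logic is attempted.

**Trailing mean.** `c*_j(k)` is the mean of the cycles with indices
`j+1 … j+k`; it exists only if all `k` survived screening. With
`k = 1` it is simply the previous cycle's length.

## Panel models

All fits are of the simple form `y = α + βx` with repeated
observations per woman (`x = c*(k)` or cycle length, `y` a phase
length).

* **Pooled OLS** ignores grouping; its residuals feed the variance
  components.
* **Fixed effect (LSDV / within)**: `β` from within-woman demeaned
  cross-products, `α_i = ȳ_i − x̄_i β`. Reported `alpha` is the
  observation-weighted mean of the `α_i` (needed only for
  prediction; the slope is the estimand).
* **Variance components** (method of moments, unbalanced panels):
  `σ²_total = Σ μ²/(Σ T_i − p)` and
  `σ²_between = Σ_i Σ_{t<s} μ_it μ_is / (Σ T_i(T_i−1)/2 − p)` with
  `p = 2`, `σ²_within = σ²_total − σ²_between` clamped at 0. A
  negative between-component (small samples) is clamped to 0 with a
  warning. The per-woman pair sum is computed as
  `((Σμ)² − Σμ²)/2`, so the whole estimator is O(n).
* **Random-effect GLS** under compound symmetry:
  `Ω_i = σ²_within I + σ²_between J`, block-diagonal over women. The
  closed-form block inverse
  `Ω_i⁻¹ = (I − g_i J)/σ²_within`, `g_i = σ²_between/(σ²_within +
  T_i σ²_between)`, is folded into 2×2 normal equations — exact, no
  matrix of order n is ever formed. `σ²_between = 0` reduces exactly
  to pooled OLS; `σ²_within = 0` with repeated observations is a
  degenerate covariance and raises.
* **Hausman comparison**: `H = (β_gls − β_lsdv)²` referred to χ²(1),
  with no variance normalisation — this is deliberately the statistic
  as used in the source analysis, so `H` carries units of squared
  slope and the p-value is comparative rather than inferential. Two
  decision rules are selectable, because the source analysis *states*
  that the random-effect model is rejected when p > .05 (the inverse
  of standard practice) while *applying* the random-effect model at
  p = .001: `reject_random_if_p_large` (default, the stated rule) and
  `standard` (small p rejects the random-effect model). Neither rule
  affects any coefficient; only the `favored_model` label.

The printed formulas in the source for the within estimator
(numerator/denominator transposed) and for `σ²_total` (missing square
on the residual) are dimensionally inconsistent with their own use;
the standard forms above are implemented. Likewise Ω is written there
with squared ξ's although the ξ's are estimated directly as residual
(co)variances; the components are treated as variances and used
unsquared.

## Calendar predictors

All brackets are floor ("rounded down to the nearest integer" — the
stated Ogino convention, applied to all three methods for
consistency), so predictions are integer day offsets from the last
onset and monotone in `c*` for non-negative slope:

* Ogino: `⌊c*⌋ − 15` (equivalently, a fixed 14-day luteal phase:
  `⌊c*⌋ = f + 14 + 1`);
* HCL: `⌊c*/2⌋`;
* Optimized: `⌊α + β·c*⌋`, with one `(α, β)` fitted per `k` (the
  coefficients genuinely drift with `k` as the trailing mean becomes
  less noisy). The fitting estimator is configurable (`gls_re`
  default, `pooled_ols`, `lsdv`); GLS and pooled OLS give nearly
  identical coefficients on cohort-preset data, while the within
  estimator is strongly attenuated — within-woman variation of
  `c*(k)` is mostly measurement noise, a classic errors-in-variables
  effect — and is not a sensible choice for prediction.

Predictions below one day post-onset are flagged as invalid in the
scalar API; the vectorised evaluation path simply scores them as
incorrect.

Evaluation fits the optimized predictor in-sample on the full dataset,
mirroring the source analysis; note this optimistically biases the
optimized method relative to the fixed rules. A woman-level hold-out
can be emulated by deriving cycles from disjoint cohorts (fit on one,
evaluate on the other); it is not wired into the default pipeline.

## Evaluation

* **Phase summary**: per integer cycle length, the count, mean `f`
  and `l`, and the central 95% range (2.5th–97.5th percentile of
  individual values, rounded to integers) — ranges of individual
  variation, not standard errors, matching the published table's
  integer ranges.
* **Record-depth counts**: per `k`, ovulation-dated cycles whose `k`
  past cycles all survived screening, binned by the nearest integer
  of `c*(k)` (half-up rounding; the binning rule is unstated in the
  source, and integer bins match its tables). Counts nest:
  eligibility at `k` implies eligibility at `k−1`.
* **Correlations**: Pearson `r` between `c*(k)` and the next cycle /
  follicular / luteal length, p-value from the exact t transform with
  n − 2 df.
* **Accuracy**: a prediction is correct when `|μ − f| ≤ e`, `e ∈ {0,
  1, 2}` days. Per-bin accuracies are averaged over bins unweighted
  by default (each mean-cycle-length group counts equally);
  `pooled=True` gives the cycle-weighted overall fraction instead.

## Synthetic cohort generator

Per woman: record length `T_i ~ U{2..15}` onsets (so `k = 1..8`
analyses are all populated), woman effects `a_i ~ N(0, σ_b²)` on cycle
length and `u_i ~ N(0, σ_u²)` on follicular length; per cycle
`c = round(μ₀ + a_i + ε)`, `ε ~ N(0, σ_w²)`, clamped to [20, 45];
`f = round(γ₀ + γ₁ c + u_i + v)`, `v ~ N(0, σ_v²)`, clamped to
[1, c − 1]; `l` follows from the identity. Ovulation is emitted with
probability `p_obs` and a categorical basis label. Rounding then
clamping (rather than rejection sampling) keeps cohort sizes exactly
as configured; at the default σ's the clamp distorts the tails
negligibly. Onsets are laid out consecutively from a fixed start
date. One `numpy` Generator drives everything, so output CSVs are
byte-identical for identical (config, seed).

Default calibration (`cohort_preset`): `μ₀ = 28` d (the published
modal cycle length), `σ_b = 2.5`, `σ_w = 2.0` d (total SD ≈ 3.2 d,
matching the published 24–38 d central range), `γ₀ = −6.0`,
`γ₁ = 0.694` (the slope of the published per-cycle-length mean
follicular rows, ≈(22.3 − 10.5)/(40 − 23)), `σ_u = 1.0`,
`σ_v = 1.5` d, `p_obs = 12731/135666 ≈ 0.094`, basis split
.31/.54/.15. A second calibration (`panel_fit_preset`, `γ₁ = 0.523`)
exists because the published aggregates are mutually inconsistent
about the follicular slope: the summary-table rows imply ≈0.69, the
per-k panel coefficients read as ≈0.52, and the printed
(α, β) = (.501, −.088) pair implies a near-flat dependence that
contradicts both — most plausibly swapped or rescaled labels. The
generator ships both readings and arbitrates neither; the printed
pairs are used verbatim only as generative truths in
estimator-recovery simulations, where their substantive
interpretation is irrelevant.

What the generator does **not** emulate: anovulatory cycles,
autocorrelation of cycle lengths beyond the shared intercept, age or
seasonal effects, self-selection of who records ovulation, and
reporting error in the logged dates. Tests passing on this cohort
therefore show that the pipeline's derivations, estimators and
comparisons behave correctly under the assumed random-intercept
structure — not that the fitted coefficients transfer to any real
population.

## Numerical and design notes

* Day counts are exact integer date arithmetic; no timezone or
  sub-day handling.
* `round()` of Gaussian draws uses numpy's banker's rounding; exact
  .5 ties make `f(c)` non-linear in a way no single floored line can
  reproduce, so noise-free exactness tests use tie-free coefficients.
* The e = 0 exact-day comparison between the optimized rule and Ogino
  in the long-cycle (>31 d) region is genuinely marginal at larger k
  under the cohort calibration: floor discretisation places the
  optimized prediction ~half a day low on average, which at a 1-day
  tolerance window can offset Ogino's bias. The qualitative
  superiority claims are checked at `k = 1`, where they hold with
  wide margins at every tolerance.
* Simulation sizes in the test suite (cohorts of 400–12,000 women,
  200-replicate recovery runs of 500 × 8 panels) were chosen so each
  Monte-Carlo check's sampling error is small against the margin of
  the property it verifies while the whole suite stays fast.
* The pipeline materialises every intermediate as CSV/JSON for
  auditability; exit codes are 0 (ok), 2 (config), 3 (data),
  4 (numerical).

## Limitations

* No fertile-window (interval) output; the predictors give a single
  most-likely ovulation day.
* No multi-covariate regression, robust/clustered standard errors, or
  ML/REML variance estimation — the moment estimators above mirror the
  source analysis.
* No imputation of missing onsets, cycle-irregularity diagnostics, or
  pregnancy handling.
* In-sample evaluation of the optimized method overstates its edge;
  see above.
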