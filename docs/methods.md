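# Methods

## Scope and model

The package audits a *corpus* of meta-analyses of ratio-scale effects
(RR/OR/HR) for evidence of reporting bias. All computation happens on the
natural-log scale under the normal approximation: a primary study reporting
effect R with 95% CI (L, U) is represented by y = ln R and
s = (ln U − ln L)/(2·z), z = Φ⁻¹(0.975) = 1.959964 (computed, not
hard-coded). Different ratio measures are pooled as reported — the source
reviews themselves mix measures, and converting OR to RR would require
baseline risks that published meta-analyses rarely provide. CIs are assumed
to be 95% unless a `ci_level` is supplied; the field exists because sources
occasionally report 90% or 99% intervals.

The point estimate is required to lie inside its CI after widening the bounds
by 1%: published effects are rounded to two decimals, and a strict
containment check rejects legitimately rounded rows. Values outside the
widened interval fail hard.

## Random-effects pooling

Pooling uses the DerSimonian–Laird moment estimator of the between-study
variance,

τ̂² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),  w = 1/s²,

with random-effects weights 1/(s² + τ̂²), a normal reference for the pooled
CI and p-value, and I² = 100·max(0, (Q − (k−1))/Q) (defined as 0 at Q = 0).
DL-plus-z is chosen over REML or Knapp–Hartung because it is what the
mainstream review software of the audited era used by default, and the point
of re-pooling is to reproduce, not improve, the source syntheses. Every
meta-analysis is re-pooled with random effects regardless of what the
original review used; the run log records this choice. The implementation is
cross-validated in the test suite against both an independently coded formula
oracle (1e−10 agreement on random instances) and `metafor::rma(method="DL")`
in R.

## Egger small-study-effect test

The classic regression form: OLS of the standardized effect tᵢ = yᵢ/sᵢ on
precision 1/sᵢ, with the intercept's t statistic referred to k−2 degrees of
freedom and a two-sided p < 0.10 flag threshold. This is algebraically the
weighted regression of y on s with 1/s² weights; the standardized form is
used because its intercept is the quantity with the funnel-asymmetry
interpretation. Requires k ≥ 3; a constant-precision design (all sᵢ equal)
is singular and is recorded as ineligible rather than fitted. The OLS fit
itself is delegated to statsmodels; tests verify it against closed-form
least-squares arithmetic.

## Excess-significance test

Per-study significance is recomputed from y/s under normality rather than
taken from published p-values, because CIs are the only uniformly available
evidence. O counts studies with two-sided p strictly below α = 0.05 in either
direction by default; counting only the direction of the plausible effect is
available as a configuration switch (`direction_restricted`) since the
convention is genuinely ambiguous, and the either-direction default is the
more common reading.

The plausible effect θ\* is the log effect of the most precise study
(smallest s); precision ties break toward the effect nearest the null, then
input order — the conservative choice, since a smaller |θ\*| lowers every
power and therefore E. Study power is the exact two-sided Wald power
1 − Φ(z₀.₉₇₅ − |θ\*|/s) + Φ(−z₀.₉₇₅ − |θ\*|/s), which is bounded below by α,
so E ∈ [kα, k].

O vs E is referred to χ² = (O−E)²/E + (O−E)²/(k−E) with 1 df. A chi-square
is preferred to a binomial with mean power because powers differ per study;
the exact reference distribution is Poisson-binomial, and the test suite
checks that the χ² accept/reject decision agrees with full 2^k enumeration of
that distribution on ≥95% of random small instances (the χ² form is kept as
the default because enumeration costs 2^k). E exactly 0 or k would make the
statistic undefined; it is clamped just inside (0, k) and the clamp logged.
The flag requires *both* O > E and one-sided p < 0.05 (two-sided p < 0.10):
a significance *deficit* is never evidence of reporting bias. All threshold
comparisons are strict (<).

## Pipeline conventions

- Bias tests require k ≥ 3; meta-analyses with k < 2 are excluded from every
  denominator and logged with reason `k_lt_2`. Eligibility reasons
  (`k_lt_min`, `degenerate_design`) are recorded per meta-analysis.
- Area tables report integer-rounded percentages (half away from zero) with
  eligibility-aware denominators — test percentages over the test-eligible
  count, significance over the area total — plus raw proportions and the
  excess-flag share of the area total, since both bases appear in practice.
- Sensitivity filters: (a) keep meta-analyses with ≥ `min_k` (default 10)
  studies; (b) drop primary studies with a *known* death count below
  `min_deaths` (default 200), dropping meta-analyses left with fewer than two
  studies. Studies with missing death counts are retained with a warning —
  excluding a study for an unknown size would conflate missingness with
  smallness. When both filters are combined the order is: drop small
  studies, recount k, then apply the minimum-k filter; the order is logged,
  not asserted to commute.
- ROBIS judgments are data, never computed: the overall call is a human
  phase-3 judgment. The packaged 49-review table carries the four domain
  judgments; no per-review overall judgment was published for that set, so
  the `overall` field is optional and its distribution is tallied only over
  reviews where it is recorded.
- Report writing is deterministic (no timestamps); identical inputs yield
  byte-identical outputs.

## Synthetic corpora

The generator draws s log-uniform on (se_min, se_max) = (0.05, 0.5) by
default — a long-tailed mix of study sizes of the kind seen in funnel plots —
then θᵢ = θ + N(0, τ²) and y ~ N(θᵢ, s²). Defaults are chosen once to
emulate a behavior-mortality literature: nine published studies per
meta-analysis, θ = ln 0.8 (a modest protective association), τ = 0.15
(moderate heterogeneity, I² typically 30–60% at these standard errors), and
no selection (p_publish_nonsig = 1).

Selection is the simplest file-drawer mechanism: a study with two-sided
p < 0.05 always publishes; otherwise it publishes with probability
p_publish_nonsig. Candidates are drawn until the target k survives (cap 10⁶,
after which generation aborts); the suppressed count is kept in the record
metadata. Death counts are tied to precision by deaths = round(c/s²) with
c = 1 — an arbitrary but documented link whose only purpose is to make the
<200-deaths filter exercisable; participants are 25× deaths. Per-meta
generators come from spawned substreams of a single seed, so corpora are
reproducible and independent of generation order.

What the simulator does *not* emulate: real corpora mix effect measures,
contain correlated studies (shared cohorts), non-normal small-study
likelihoods, and heterogeneity that correlates with study size. Passing
calibration tests therefore shows the statistics behave as designed under
their own assumptions, not that the assumptions hold in any given literature.

## Operating characteristics and problem sizes

Monte-Carlo checks in the test suite use sizes chosen to keep Monte-Carlo
error well below the tolerances being asserted: null calibration uses 2000
replicates of k = 20 (binomial MC se ≈ 0.007 on a 0.10 rate), monotonicity
in selection severity uses 1000 replicates per grid point with a 2·mc_se
slack, and parameter recovery uses 1000 meta-analyses of k = 30. Under the
null the Egger flag rate is empirically ≈ 0.10 and the per-study significance
rate ≈ 0.05; under θ = θ\* truth without selection, mean(O) tracks mean(E),
which is the design property of the expected count. E is computed from an
*estimated* θ\*, so it is noisy but approximately unbiased in these designs;
with very small k the estimation noise in θ\* inflates E slightly under the
null, which makes the excess test conservative there.

## Known limitations

- The Egger test inherits its well-known false-positive behavior under high
  heterogeneity and when effects correlate with variances by construction;
  flags are screening signals, not proof of suppression.
- Both tests have low power at small k; area-level percentages over few
  eligible meta-analyses are unstable, which is exactly why the ≥10-study
  sensitivity view exists.
- The χ² form of the excess test is a large-sample approximation; its
  decisions disagree with the exact Poisson-binomial tail in a few percent of
  small-k instances (measured in the test suite).
- No dose–response, subgroup, or meta-regression re-analysis; the audit
  re-pools each meta-analysis exactly as a flat study list.
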