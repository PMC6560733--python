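# Methods

## Effect measure

For a composite endpoint with `k` event types under competing risks, the
cause-specific hazard `λ_EPj(t)` is the instantaneous rate of a type-`j`
first event.  Given relevance weights `w = (w_1, ..., w_k)`, `w_j ≥ 0`, at
least one positive, the weighted all-cause hazard is
`λ^w(t) = Σ_j w_j λ_EPj(t)` and the weighted all-cause hazard ratio (WHR)
between intervention and control is `θ^w(t) = λ^{I,w}(t) / λ^{C,w}(t)`.
The package evaluates `θ^w` at the end of the observational period `t = τ`
(the time-averaged variant `(1/τ)∫θ^w` is available separately as
`integrated_weighted_hr`).  Multiplying all weights by a constant leaves
θ^w unchanged; all-ones weights recover the standard all-cause hazard
ratio.  θ^w is constant in time exactly when the components share one
baseline hazard shape.

## Estimators

**Non-parametric.**  `θ̃^w(τ) = Σ_j w_j Λ̂^I_j(τ) / Σ_j w_j Λ̂^C_j(τ)` with
cause-specific Nelson-Aalen estimators `Λ̂^g_j(t) = Σ_{t_l ≤ t}
d^g_{j,l} / n^g_l`.  Competing events and censorings deplete the risk set
but never the numerator.  The ratio of weighted cumulative hazards equals
the ratio of weighted hazards exactly under equal cause-specific baseline
hazards; otherwise θ̃^w estimates a biased version of θ^w(τ), and the
simulation machinery quantifies that bias.  A subject's own cumulative
hazard cannot exceed the harmonic number H_n of the group size, so with
very large true cumulative hazards (nearly all subjects failing well before
τ) the estimator saturates; estimates at such late times should not be
trusted, and the test suite's simulator validation therefore checks
marginals only where a non-trivial fraction of subjects is still at risk.

**Parametric (Weibull).**  Per event type `j` the package fits a Weibull
proportional-hazards model with hazard `κ_g ν t^{ν−1}`: one shape `ν`
shared by both groups and group-specific scales, all other outcomes
treated as right-censored at their observed time.  The fitted hazards at
τ are plugged into θ^w.  The shared shape is the model form that encodes
the approach's proportional-cause-specific-hazards assumption.  A variant
with fully separate per-group fits (4 independent fits for k = 2, exposed
via `fit_weibull_mle`) estimates the same quantity, but its ratio contains
the factor `τ^{ν̂_I − ν̂_C}`, a noisy exponent that inflates the sampling
standard deviation by roughly half again as much in the benchmark
scenarios and, through the wider permutation null, costs the permutation
test most of its power.  The shared-shape fit was therefore adopted as the
package's parametric estimator.

Both log-likelihood maximizations profile the scale(s) out in closed form
(`κ_g(ν) = d_g / Σ_{i∈g} t_i^ν`) and solve the one-dimensional profile
score in ν by bracketed Brent iteration (`xtol = 1e-12`), after rescaling
times by their maximum for numerical stability; the score at the solution
is verified below 1e-6.  Fits are refused (never clipped) when a group has
no event, fewer than two events exist overall, or the profile score has no
root; an estimate with any refused component is flagged non-estimable and
excluded from simulation summaries, with counts reported.

Neither estimator has a usable closed-form variance; standard errors come
from the permutation distribution (below).

## Tests

All tests address `H0: θ^w ≥ 1` against one-sided superiority (fewer
events under intervention); negative statistics favour the intervention
and the normal-approximation tests reject when the statistic is at most
`−z_{1−α}`, default one-sided `α = 0.025`.

**Log-rank.**  Observed-minus-expected group-I event counts over the
distinct pooled event times, standardized by the summed hypergeometric
variances.  At-risk counts are left-continuous ("just before t_l"), so a
subject censored exactly at an event time is still at risk there — the
standard convention, adopted because the data model itself does not
prescribe one.  Risk sets of size one contribute no variance.

**Weight-based log-rank.**  Per-type observed counts `d^I_{j,l}` and
expectations enter weighted by `w_j`, variances by `w_j²`, from the exact
moments of `Hyp(n_l, d_{j,l}, ·)`.  With unit weights and no cross-type
ties the statistic reduces to the log-rank statistic exactly.  The
variance formula assumes that events of different types never share a time
point — automatic with continuous data; if user data do contain cross-type
ties the formula is applied as printed and a warning is emitted (no
jittering).  The statistic is Wald-type, not a Cox score test.  Under an
exchangeable null (both groups generated identically) its simulated
standard deviation is 1.00 and its one-sided size at α = 0.025 is about
0.03 at n = 100 per group — a small finite-sample inflation.

**Permutation test.**  Group labels are reshuffled without replacement
(group sizes preserved; times and causes ride along), the chosen
estimator's log value is recomputed per permutation, and the one-sided
Monte-Carlo p-value uses the add-one convention `(1 + #{permuted ≤
observed}) / (n_perm + 1)`, which guarantees validity.  A complete
enumeration mode replaces sampling by all `C(n, n_I)` assignments with the
exact proportion as p-value.  Non-estimable permutations are dropped from
the null sample with a count; fewer than 10 estimable Monte-Carlo
permutations refuse inference.  The standard deviation of the permuted log
estimates serves as the standard error; 95% confidence intervals are
`observed ± 1.959964 · SE` on the log scale (normal-theory, not
percentile).

## Trial simulator

Each subject of a group draws one latent time per component by inversion
of the cause-specific cumulative hazard, `T_j = Λ_j^{-1}(−ln U_j)` with
independent uniforms; the observed outcome is the earliest latent time and
its cause, and subjects event-free at τ are administratively censored
there.  This latent-failure-time construction is distributionally
equivalent to drawing the composite time from the all-cause hazard and
assigning the cause multinomially with probabilities proportional to the
cause-specific hazards.  Weibull inverses are closed form; Gompertz-Makeham
inverses use safeguarded Newton iteration from an upper bracket (the
cumulative hazard is convex), tolerance 1e-12 in Λ-space.  Randomness uses
the Mersenne-Twister generator; `run_study` spawns per-replicate child
seeds from the root seed via `SeedSequence`, so replicates are reproducible
individually and independently of execution order.

The ten preset scenarios pair Weibull and Gompertz-Makeham cause-specific
hazards chosen to cover all combinations of: proportional hazards holding
for the components and/or the composite, and equal versus unequal
cause-specific baseline hazards — the regimes in which each estimator's
assumptions hold or fail.  Defaults are 100 subjects per group, 1000
replicates, 1000 permutations, one-sided α = 0.025, τ ∈ {1, 2}.

What the generator does *not* emulate: staggered accrual, random
(non-administrative) dropout, covariates, recurrent events, discrete or
tied event times, and more than two arms.  Conclusions from passing tests
therefore apply to clean, continuously measured, administratively censored
two-arm data; real trials with informative censoring or heavy ties are
outside the validated envelope.

## Performance measures

On the log scale, over estimable replicates: bias (mean minus true log
WHR, the true value computed analytically from the scenario's hazards at
τ), sample SD with the n−1 denominator, standardized bias (bias/SD, NaN
when SD = 0), `MSE = bias² + SD²` reported as its square root, relative
efficiency `MSE_parametric / MSE_nonparametric` (values above 1 favour the
non-parametric estimator), coverage as the percentage of replicates with
`|log estimate − true| ≤ 1.959964 · SE_perm` (replicates lacking an SE are
excluded from the denominator, with counts), and empirical power as the
rejection fraction — the empirical type-I error under null scenarios.

## Numerical and design choices

* Closed-form cumulative hazards are used for both families; an adaptive
  quadrature fallback (`scipy.integrate.quad`, relative tolerance 1e-10)
  covers arbitrary hazard callables and agrees with the closed forms to
  1e-8 relative.
* Weibull hazards with ν < 1 diverge at t = 0: evaluation there raises a
  domain error rather than returning infinity; cumulative quantities
  remain defined.
* Severity-equivalence weights: the reference type gets weight exactly 1,
  type j gets `r_j/m_j`; implied weights above 1 warn (comparability with
  the unweighted analysis is lost) but are not errors, since exploring
  such schemes is legitimate in planning.
* Dataset I/O writes floats with `%.17g` and reads with round-trip float
  parsing, so write-then-read reproduces a dataset bit-exactly.
* Cause codes are 1-based with 0 = censored; records beyond τ are
  truncated to administrative censoring at τ on input.

## Problem sizes used by the test suite

Estimator means and test operating characteristics are checked at the full
study size (1000 replicates, n = 100 per group).  The permutation-test
power check runs 200 replicates × 500 permutations and the coverage check
200 replicates × 200 permutations — sizes chosen so the three-standard-
error Monte-Carlo bands around the benchmark values remain informative
while the whole suite stays interactive; the corresponding binomial
tolerances are computed at the sizes actually run.  Simulator marginals
are validated at n = 50,000 per group against analytic cumulative hazards.

## Known limitations

* The weight-based log-rank variance is anti-conservative in small samples
  (size ~0.03 at nominal 0.025) and undefined under heavy cross-type ties.
* The parametric estimator is only as good as the Weibull form: under
  Gompertz-Makeham data with strongly time-varying shape it is biased, and
  with nearly-exhausted risk sets both estimators degrade (Nelson-Aalen
  saturation; extrapolated fitted hazards).
* Confidence intervals require the permutation distribution; no analytic
  variance is provided for either estimator.
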