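# wahr — the weighted all-cause hazard ratio for composite endpoints

Clinical trials often combine several event types (death, myocardial
infarction, hospitalization, ...) into a composite time-to-first-event
endpoint.  The standard effect measure is the all-cause hazard ratio, built
on the all-cause hazard `λ_CE(t) = Σ_j λ_EPj(t)` — the sum of the
cause-specific hazards.  Its drawback is well known: frequent but less
relevant event types dominate the composite.  The *weighted* all-cause
hazard ratio (WHR) fixes relevance weights `w_EPj ≥ 0` per event type and
compares

```
            Σ_j w_EPj · λ^I_EPj(t)
θ^w(t)  =  ────────────────────────        (I = intervention, C = control)
            Σ_j w_EPj · λ^C_EPj(t)
```

With all weights equal to 1 this is the usual all-cause hazard ratio.
`wahr` is a toolbox for planning and analysing two-arm trials with this
effect measure.  It provides:

* **Point estimators** — the original parametric estimator (per-cause
  Weibull proportional-hazards fits, hazards `κ̂_g ν̂ t^{ν̂−1}` plugged into
  θ^w at the evaluation time τ) and the non-parametric estimator
  `θ̃^w(τ) = Σ_j w_j Λ̂^I_j(τ) / Σ_j w_j Λ̂^C_j(τ)` built from cause-specific
  Nelson-Aalen cumulative hazards.
* **Tests** of the one-sided superiority hypothesis `H0: θ^w ≥ 1` — the
  standard log-rank test, the *weight-based* log-rank test (per-type event
  counts and hypergeometric variances weighted by `w_j`; not the classical
  "weighted log-rank" that weights time points), and a permutation test
  with permutation-based standard errors and confidence intervals.
* **A trial simulator** that draws competing-risks data from parametric
  cause-specific hazards (Weibull `κνt^{ν−1}` and Gompertz-Makeham
  `κe^{νt}+ε`) by inverse-cumulative-hazard sampling, with administrative
  censoring at τ, plus a registry of ten benchmark scenarios.
* **Performance evaluation** — bias, standardized bias, root-MSE, relative
  efficiency, coverage and empirical power across simulation replicates.
* **Weight-choice guidance** — severity equivalences ("5 events of type 2
  are as harmful as 1 reference event" → weights (1, 0.2)), modified
  hazards, and weighted event-time-distribution curves for plotting.

## Worked example

Simulate one trial from the first benchmark scenario (cause-specific
hazards 0.24 and 0.24t under intervention, 0.4 and 0.8t under control,
τ = 1, 100 subjects per group), then estimate and test with weights
(1, 0.1):

```python
import wahr
from wahr import SimConfig, WeightScheme

w = WeightScheme((1, 0.1))
cfg = SimConfig("scenario_1", tau=1.0, weights=w, n_per_group=100, seed=42)
data = wahr.simulate_trial(cfg)

np_est = wahr.estimate_whr_nonparametric(data, w, 1.0)
wb = wahr.weight_based_logrank_test(data, w)
perm, inf = wahr.permutation_test(data, w, 1.0, "nonparametric_na",
                                  n_perm=1000, seed=42)
print(f"nonparametric: value={np_est.value:.4f} log={np_est.log_value:.4f}")
print(f"weight-based log-rank: statistic={wb.statistic:.4f} p={wb.p_value:.4f}")
print(f"permutation: p={perm.p_value:.4f} se={inf.se:.4f} "
      f"CI=({inf.ci_low:.4f}, {inf.ci_high:.4f})")
```

prints

```
nonparametric: value=0.4762 log=-0.7418
weight-based log-rank: statistic=-3.1804 p=0.0007
permutation: p=0.0020 se=0.2576 CI=(-1.2468, -0.2369)
```

The estimated weighted hazard ratio 0.48 (log −0.74) favours the
intervention; the true value under these hazards is θ^w(1) = 0.55
(log −0.60), and both tests reject the one-sided null at α = 0.025.  The
95% interval on the log scale uses the permutation standard error.

The same workflow is available from the shell:

```sh
wahr simulate --scenario scenario_1 --tau 1 --weights 1,0.1 \
     --reps 1000 --n-perm 0 --seed 1
wahr estimate --data trial.csv --k 2 --tau 1 --weights 1,0.1
wahr test --data trial.csv --k 2 --tau 1 --weights 1,0.1 --method weight-based
wahr list-scenarios
```

Datasets are plain CSV with columns `time,cause,group` (cause 0 = censored,
1..k = event type of the first event; group `I` or `C`).

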