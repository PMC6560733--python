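"""Hypothesis tests for composite endpoints: log-rank, weight-based log-rank,
and the permutation test with permutation-based standard errors.

All tests address the one-sided superiority problem: fewer events under the
intervention, i.e. ``H0: theta >= 1`` versus ``H1: theta < 1``.  Negative
statistics favour the intervention, so the normal-approximation tests reject
when the statistic falls at or below ``-z_{1-alpha}``.

The *weight-based* log-rank test weights the per-event-type observed counts
and hypergeometric moments by the component relevance weights (this differs
from the classical "weighted log-rank" which weights time points).  With all
weights 1 and no cross-type ties it reduces exactly to the standard log-rank
statistic.  Its variance formula assumes no two event types share an event
time; with continuous data such ties have probability zero, and if they do
occur in user data the formula is applied as printed with a warning.

The permutation test rebuilds the null distribution of a WHR estimator by
reshuffling group labels without replacement; its standard deviation serves
as the standard error behind normal-theory confidence intervals.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateTestError, NonEstimableError, ValidationError
from .estimators import (
    NONPARAMETRIC,
    PARAMETRIC,
    _na_log_ratio_sorted,
    _parametric_log_ratio,
    _prepare_sorted,
    estimate_whr_nonparametric,
    estimate_whr_parametric,
)
from .hazards import WeightScheme
from .trial_data import TrialDataset, build_event_table

__all__ = [
    "TestResult",
    "PermutationInference",
    "logrank_test",
    "hypergeometric_moments",
    "weight_based_logrank_test",
    "permutation_test",
    "two_sided_p",
]

Z_95 = 1.959964  # normal 97.5% quantile used for 95% intervals


@dataclass(frozen=True)
class TestResult:
    """Outcome of a one-sided test at level ``alpha``."""

    method: str
    statistic: float
    p_value: float
    alpha: float
    reject: bool
    n_permutations: int | None = None

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "reject": self.reject,
            "n_permutations": self.n_permutations,
        }


@dataclass(frozen=True)
class PermutationInference:
    """Permutation distribution summary: SE and 95% CI on the log scale.

    The interval is ``observed +/- 1.959964 * se`` and therefore always
    contains the observed value; ``n_dropped`` counts permutations whose
    re-estimate was non-estimable and was excluded from the null sample.
    """

    observed_log: float
    permutation_logs: np.ndarray
    se: float
    ci_low: float
    ci_high: float
    n_dropped: int = 0

    def to_record(self) -> dict:
        return {
            "observed_log": self.observed_log,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_permutations": int(len(self.permutation_logs)),
            "n_dropped": self.n_dropped,
        }


def hypergeometric_moments(nI: int, nC: int, d_cell: int) -> tuple[float, float]:
    """Exact mean and variance of the group-I share of ``d_cell`` events.

    Under the null, the events at one time are distributed over the pooled
    risk set at random without replacement, so the group-I count follows
    ``Hyp(nI + nC, d_cell, nI)``.
    """
    n = nI + nC
    if not (0 <= d_cell <= n):
        raise ValidationError(f"d_cell must be in 0..{n}, got {d_cell}")
    if nI < 0 or nC < 0:
        raise ValidationError("risk-set sizes must be non-negative")
    if n < 2:
        raise DegenerateTestError("hypergeometric variance undefined for risk sets below 2")
    expectation = nI * d_cell / n
    variance = nI * nC * (n - d_cell) * d_cell / (n**2 * (n - 1))
    return expectation, variance


def _zcrit(alpha: float) -> float:
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return float(stats.norm.ppf(1 - alpha))


def logrank_test(data: TrialDataset, alpha: float = 0.025) -> TestResult:
    """Standard one-sided log-rank test on the composite (all causes pooled)."""
    if not data.testable:
        raise DegenerateTestError("both groups must be non-empty")
    table = build_event_table(data)
    if table.n_rows == 0:
        raise DegenerateTestError("no events observed")
    nI = table.n_I.astype(float)
    nC = table.n_C.astype(float)
    n = nI + nC
    d = table.d_total.astype(float)
    numerator = float(np.sum(table.d_group_I - nI * d / n))
    ok = n > 1  # singleton risk sets carry no hypergeometric variance
    variance = float(
        np.sum(nI[ok] * nC[ok] * (n[ok] - d[ok]) * d[ok] / (n[ok] ** 2 * (n[ok] - 1)))
    )
    if variance <= 0:
        raise DegenerateTestError("total hypergeometric variance is zero")
    statistic = numerator / math.sqrt(variance)
    p_value = float(stats.norm.cdf(statistic))
    return TestResult("logrank", statistic, p_value, alpha, statistic <= -_zcrit(alpha))


def weight_based_logrank_test(
    data: TrialDataset, w: WeightScheme, alpha: float = 0.025
) -> TestResult:
    """Weight-based log-rank test of the weighted all-cause hazard ratio."""
    if not data.testable:
        raise DegenerateTestError("both groups must be non-empty")
    w.check_length(data.k)
    table = build_event_table(data)
    if table.n_rows == 0:
        raise DegenerateTestError("no events observed")
    if np.any(np.count_nonzero(table.d_cause > 0, axis=1) > 1):
        warnings.warn(
            "events of different types share a time point; the weight-based "
            "variance formula assumes no cross-type ties",
            stacklevel=2,
        )
    warr = w.as_array()
    nI = table.n_I.astype(float)
    nC = table.n_C.astype(float)
    n = nI + nC
    d_cause = table.d_cause.astype(float)
    dIw = table.d_I.astype(float) @ warr
    dw = d_cause @ warr
    w2d = d_cause @ warr**2
    w2d2 = d_cause**2 @ warr**2
    numerator = float(np.sum(dIw - nI / n * dw))
    ok = n > 1
    variance = float(
        np.sum(
            nI[ok] * nC[ok] * (n[ok] * w2d[ok] - w2d2[ok]) / (n[ok] ** 2 * (n[ok] - 1))
        )
    )
    if variance <= 0:
        raise DegenerateTestError("total weighted hypergeometric variance is zero")
    statistic = numerator / math.sqrt(variance)
    p_value = float(stats.norm.cdf(statistic))
    return TestResult(
        "weight_based_logrank", statistic, p_value, alpha, statistic <= -_zcrit(alpha)
    )


def two_sided_p(result: TestResult) -> float:
    """Two-sided companion p-value obtained by doubling the one-sided one."""
    return min(1.0, 2.0 * min(result.p_value, 1.0 - result.p_value))


def permutation_test(
    data: TrialDataset,
    w: WeightScheme,
    t: float,
    estimator_method: str = PARAMETRIC,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.025,
    complete: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[TestResult, PermutationInference]:
    """Permutation test of the WHR based on either point estimator.

    Group labels are reshuffled without replacement (group sizes preserved);
    the one-sided Monte-Carlo p-value uses the add-one correction
    ``(1 + #{permuted <= observed}) / (n_perm + 1)``.  With
    ``complete=True`` all label assignments are enumerated instead and the
    p-value is the exact proportion ``#{<= observed} / #assignments``.
    Permutations with a non-estimable re-estimate are dropped from the null
    sample (counted in the returned inference); fewer than 10 estimable
    permutations refuse inference.
    """
    if estimator_method not in (PARAMETRIC, NONPARAMETRIC):
        raise ValidationError(f"unknown estimator method {estimator_method!r}")
    if not complete and n_perm < 1:
        raise ValidationError("n_perm must be at least 1")
    estimate = (
        estimate_whr_parametric(data, w, t)
        if estimator_method == PARAMETRIC
        else estimate_whr_nonparametric(data, w, t)
    )
    if not estimate.converged:
        raise NonEstimableError(f"observed estimate is non-estimable: {estimate.reason}")
    observed = estimate.log_value
    warr = w.as_array()
    n = data.n
    z_obs = data.group_mask("I")
    n_I = int(z_obs.sum())

    if estimator_method == NONPARAMETRIC:
        ts, cs, pos_first = _prepare_sorted(data.times, data.causes)
        in_window = ts <= t
        is_event = (cs > 0) & in_window
        wsub = np.where(cs > 0, warr[np.maximum(cs - 1, 0)], 0.0)

        def stat_for(z: np.ndarray) -> float:
            return _na_log_ratio_sorted(wsub, pos_first, is_event, z)

        base_indices = np.argsort(data.times, kind="stable")

        def relabel(members: np.ndarray) -> np.ndarray:
            z = np.zeros(n, dtype=bool)
            z[members] = True
            return z[base_indices]  # align with the time-sorted arrays

    else:

        def stat_for(z: np.ndarray) -> float:
            return _parametric_log_ratio(data.times, data.causes, z, warr, data.k, t)

        def relabel(members: np.ndarray) -> np.ndarray:
            z = np.zeros(n, dtype=bool)
            z[members] = True
            return z

    perm_stats: list[float] = []
    n_dropped = 0
    if complete:
        for members in itertools.combinations(range(n), n_I):
            s = stat_for(relabel(np.asarray(members, dtype=np.intp)))
            if math.isnan(s):
                n_dropped += 1
            else:
                perm_stats.append(s)
        m = len(perm_stats)
        if m < 2:
            raise NonEstimableError("fewer than 2 estimable assignments; inference refused")
        arr = np.asarray(perm_stats)
        p_value = float(np.count_nonzero(arr <= observed) / m)
        n_perm_used = m
    else:
        if rng is None:
            rng = np.random.Generator(np.random.MT19937(seed))
        for _ in range(n_perm):
            members = rng.permutation(n)[:n_I]
            s = stat_for(relabel(members))
            if math.isnan(s):
                n_dropped += 1
            else:
                perm_stats.append(s)
        m = len(perm_stats)
        if m < 10:
            raise NonEstimableError("fewer than 10 estimable permutations; inference refused")
        arr = np.asarray(perm_stats)
        p_value = float((1 + np.count_nonzero(arr <= observed)) / (m + 1))
        n_perm_used = m
    se = float(np.std(arr, ddof=1))
    inference = PermutationInference(
        observed_log=observed,
        permutation_logs=arr,
        se=se,
        ci_low=observed - Z_95 * se,
        ci_high=observed + Z_95 * se,
        n_dropped=n_dropped,
    )
    result = TestResult(
        "permutation", observed, p_value, alpha, p_value <= alpha, n_permutations=n_perm_used
    )
    return result, inference
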