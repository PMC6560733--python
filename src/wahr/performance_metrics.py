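"""Replicate-level aggregation into simulation performance measures.

For log-scale estimates the measures are: bias (mean estimate minus true
value), standardized bias (bias over the replicate standard deviation),
root mean square error with MSE = bias^2 + SD^2, relative efficiency
MSE(parametric) / MSE(non-parametric) — values above 1 favour the
non-parametric estimator — coverage of the normal-theory 95% interval built
from permutation standard errors (reported as a percentage), and empirical
power (rejection proportion; under a null scenario this is the empirical
type-I error).  Standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NonEstimableError
from .hazards import WeightScheme

__all__ = [
    "bias_and_sd",
    "mse_and_relative_efficiency",
    "coverage",
    "empirical_power",
    "MethodSummary",
    "StudyReport",
    "summarize_study",
]

Z_95 = 1.959964


def bias_and_sd(log_estimates, true_log: float) -> tuple[float, float, float]:
    """Bias, sample SD and standardized bias of log-scale estimates.

    Non-finite entries (non-estimable replicates) are ignored; fewer than
    two estimable replicates raise.  With zero SD the standardized bias is
    undefined and returned as NaN.
    """
    x = np.asarray(log_estimates, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise NonEstimableError("need at least 2 estimable replicates")
    bias = float(np.mean(x) - true_log)
    sd = float(np.std(x, ddof=1))
    standardized = bias / sd if sd > 0 else math.nan
    return bias, sd, standardized


def mse_and_relative_efficiency(
    bias_p: float, sd_p: float, bias_np: float, sd_np: float
) -> tuple[float, float, float]:
    """Root-MSEs of both estimators and their MSE ratio (parametric over
    non-parametric); a zero non-parametric MSE yields a NaN ratio."""
    mse_p = bias_p**2 + sd_p**2
    mse_np = bias_np**2 + sd_np**2
    rel_eff = mse_p / mse_np if mse_np > 0 else math.nan
    return math.sqrt(mse_p), math.sqrt(mse_np), rel_eff


def coverage(log_estimates, permutation_ses, true_log: float) -> float:
    """Percentage of replicates whose interval ``estimate +/- 1.959964*SE``
    contains the true log effect.

    Replicates with a non-finite estimate or SE are excluded from the
    denominator (their count is ``len(input) - n_used`` with
    ``n_used = count of finite pairs``).
    """
    est = np.asarray(log_estimates, dtype=float)
    ses = np.asarray(permutation_ses, dtype=float)
    if est.shape != ses.shape:
        raise ValueError("estimates and SEs must be paired")
    ok = np.isfinite(est) & np.isfinite(ses)
    if not np.any(ok):
        raise NonEstimableError("no replicate with both an estimate and an SE")
    covered = np.abs(est[ok] - true_log) <= Z_95 * ses[ok]
    return float(100.0 * np.mean(covered))


def empirical_power(rejection_flags) -> float:
    """Fraction of replicates that rejected; NaN flags are excluded."""
    x = np.asarray(rejection_flags, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise NonEstimableError("no replicate with a defined test decision")
    return float(np.mean(x))


@dataclass(frozen=True)
class MethodSummary:
    """Per-estimator summary across replicates (all on the log scale)."""

    method: str
    n_estimable: int
    mean_log: float
    sd_log: float
    bias: float
    standardized_bias: float
    rmse: float
    coverage_percent: float  # NaN when no permutation SEs were computed
    n_covered_denominator: int


@dataclass(frozen=True)
class StudyReport:
    """Aggregated results of one simulation study configuration."""

    scenario: str
    tau: float
    weights: WeightScheme
    true_log_whr: float
    alpha: float
    reps: int
    n_perm: int
    parametric: MethodSummary
    nonparametric: MethodSummary
    relative_efficiency: float
    power_permutation: float  # permutation test on the parametric estimator
    power_permutation_np: float
    power_weight_based: float
    power_logrank: float
    mean_event_counts: tuple[float, ...]
    sd_event_counts: tuple[float, ...]

    def effect_table(self) -> pd.DataFrame:
        """One-row table with the effect/power columns of the simulation
        summary (mean estimated log WHR, SDs, power values)."""
        return pd.DataFrame(
            [
                {
                    "scenario": self.scenario,
                    "tau": self.tau,
                    "w_EP1": self.weights.weights[0],
                    "w_EP2": self.weights.weights[-1],
                    "ln_true_whr": self.true_log_whr,
                    **{
                        f"mean_events_EP{j + 1}": m
                        for j, m in enumerate(self.mean_event_counts)
                    },
                    "mean_ln_parametric": self.parametric.mean_log,
                    "sd_ln_parametric": self.parametric.sd_log,
                    "mean_ln_nonparametric": self.nonparametric.mean_log,
                    "sd_ln_nonparametric": self.nonparametric.sd_log,
                    "power_permutation": self.power_permutation,
                    "power_weight_based": self.power_weight_based,
                }
            ]
        )

    def performance_table(self) -> pd.DataFrame:
        """One-row table with the performance columns (bias, standardized
        bias, root-MSE, relative efficiency, coverage)."""
        return pd.DataFrame(
            [
                {
                    "scenario": self.scenario,
                    "n_estimable_parametric": self.parametric.n_estimable,
                    "n_estimable_nonparametric": self.nonparametric.n_estimable,
                    "bias_parametric": self.parametric.bias,
                    "bias_nonparametric": self.nonparametric.bias,
                    "std_bias_parametric": self.parametric.standardized_bias,
                    "std_bias_nonparametric": self.nonparametric.standardized_bias,
                    "rmse_parametric": self.parametric.rmse,
                    "rmse_nonparametric": self.nonparametric.rmse,
                    "relative_efficiency": self.relative_efficiency,
                    "coverage_parametric": self.parametric.coverage_percent,
                    "coverage_nonparametric": self.nonparametric.coverage_percent,
                }
            ]
        )

    def to_json(self, **dump_kwargs) -> str:
        payload = {
            "scenario": self.scenario,
            "tau": self.tau,
            "weights": list(self.weights),
            "true_log_whr": self.true_log_whr,
            "alpha": self.alpha,
            "reps": self.reps,
            "n_perm": self.n_perm,
            "relative_efficiency": self.relative_efficiency,
            "power": {
                "permutation_parametric": self.power_permutation,
                "permutation_nonparametric": self.power_permutation_np,
                "weight_based_logrank": self.power_weight_based,
                "logrank": self.power_logrank,
            },
            "mean_event_counts": list(self.mean_event_counts),
            "sd_event_counts": list(self.sd_event_counts),
            "methods": {
                m.method: {
                    "n_estimable": m.n_estimable,
                    "mean_log": m.mean_log,
                    "sd_log": m.sd_log,
                    "bias": m.bias,
                    "standardized_bias": m.standardized_bias,
                    "rmse": m.rmse,
                    "coverage_percent": m.coverage_percent,
                }
                for m in (self.parametric, self.nonparametric)
            },
        }
        return json.dumps(payload, indent=2, allow_nan=True, **dump_kwargs)


def _summarize_method(
    method: str, logs: np.ndarray, ses: np.ndarray, true_log: float
) -> tuple[MethodSummary, float, float]:
    ok = np.isfinite(logs)
    n_est = int(ok.sum())
    if n_est >= 2:
        bias, sd, std_bias = bias_and_sd(logs, true_log)
        mean_log = bias + true_log
        rmse = math.sqrt(bias**2 + sd**2)
    else:
        bias = sd = std_bias = mean_log = rmse = math.nan
    pair_ok = ok & np.isfinite(ses)
    if np.any(pair_ok):
        cov = coverage(logs, ses, true_log)
    else:
        cov = math.nan
    summary = MethodSummary(
        method=method,
        n_estimable=n_est,
        mean_log=mean_log,
        sd_log=sd,
        bias=bias,
        standardized_bias=std_bias,
        rmse=rmse,
        coverage_percent=cov,
        n_covered_denominator=int(pair_ok.sum()),
    )
    return summary, bias, sd


def summarize_study(
    *,
    scenario: str,
    tau: float,
    weights: WeightScheme,
    true_log_whr: float,
    alpha: float,
    reps: int,
    n_perm: int,
    log_param: np.ndarray,
    log_np: np.ndarray,
    se_param: np.ndarray,
    se_np: np.ndarray,
    reject_perm_param: np.ndarray,
    reject_perm_np: np.ndarray,
    reject_weight_based: np.ndarray,
    reject_logrank: np.ndarray,
    event_counts: np.ndarray,
) -> StudyReport:
    """Assemble a :class:`StudyReport` from replicate-level arrays."""
    param, bias_p, sd_p = _summarize_method("parametric_weibull", log_param, se_param, true_log_whr)
    nonp, bias_np, sd_np = _summarize_method("nonparametric_na", log_np, se_np, true_log_whr)
    if all(math.isfinite(v) for v in (bias_p, sd_p, bias_np, sd_np)):
        _, _, rel_eff = mse_and_relative_efficiency(bias_p, sd_p, bias_np, sd_np)
    else:
        rel_eff = math.nan

    def _power(flags: np.ndarray) -> float:
        try:
            return empirical_power(flags)
        except NonEstimableError:
            return math.nan

    counts_sd = (
        tuple(float(s) for s in np.std(event_counts, axis=0, ddof=1))
        if len(event_counts) > 1
        else tuple(math.nan for _ in event_counts[0])
    )
    return StudyReport(
        scenario=scenario,
        tau=tau,
        weights=weights,
        true_log_whr=true_log_whr,
        alpha=alpha,
        reps=reps,
        n_perm=n_perm,
        parametric=param,
        nonparametric=nonp,
        relative_efficiency=rel_eff,
        power_permutation=_power(reject_perm_param),
        power_permutation_np=_power(reject_perm_np),
        power_weight_based=_power(reject_weight_based),
        power_logrank=_power(reject_logrank),
        mean_event_counts=tuple(float(m) for m in np.mean(event_counts, axis=0)),
        sd_event_counts=counts_sd,
    )
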