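"""Point estimators of the weighted all-cause hazard ratio.

Two estimators are provided:

* ``parametric_weibull`` — the original proposal: per event type, fit a
  right-censored Weibull proportional-hazards model with a treatment term
  (one shape ``nu`` shared by both groups, group-specific scales; competing
  events and censorings enter as right-censored observations), then plug
  the fitted hazards ``kappa_g * nu * t**(nu - 1)`` into the weighted
  hazard ratio at the evaluation time.  The shared shape is what encodes
  the approach's proportional-cause-specific-hazards assumption; fully
  separate per-group fits (available via :func:`fit_weibull_mle`) estimate
  the same quantity but with a markedly heavier-tailed sampling
  distribution, because the ratio then multiplies ``t`` to the power of a
  noisy shape difference.
* ``nonparametric_na`` — the ratio of relevance-weighted sums of
  cause-specific Nelson-Aalen cumulative hazards, which requires no model
  choice and is exact under equal cause-specific baseline hazards.

Neither estimator has a closed-form variance; standard errors come from the
permutation distribution (see :mod:`wahr.significance_tests`).  Replicates
where an estimator is undefined (no events in a group, a failed Weibull fit)
are flagged ``converged=False`` and excluded from simulation summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import NonEstimableError, ValidationError
from .hazards import WeightScheme
from .trial_data import TrialDataset

__all__ = [
    "WhrEstimate",
    "nelson_aalen",
    "estimate_whr_nonparametric",
    "fit_weibull_mle",
    "fit_weibull_ph",
    "estimate_whr_parametric",
]

PARAMETRIC = "parametric_weibull"
NONPARAMETRIC = "nonparametric_na"


@dataclass(frozen=True)
class WhrEstimate:
    """A weighted hazard ratio point estimate with per-component ingredients.

    ``components`` maps ``(group, cause)`` to the fitted ``(kappa, nu)`` pair
    (parametric) or the Nelson-Aalen cumulative hazard at the evaluation time
    (non-parametric).  ``converged=False`` marks a non-estimable result;
    ``reason`` records why.
    """

    method: str
    eval_time: float
    weights: WeightScheme
    value: float = math.nan
    log_value: float = math.nan
    components: dict = field(default_factory=dict)
    converged: bool = True
    reason: str | None = None

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "eval_time": self.eval_time,
            "weights": list(self.weights),
            "value": self.value,
            "log_value": self.log_value,
            "converged": self.converged,
            "reason": self.reason,
            "components": {f"{g}.EP{j}": v for (g, j), v in self.components.items()},
        }


def nelson_aalen(data: TrialDataset, group: str, cause: int, t: float) -> float:
    """Cause-specific Nelson-Aalen estimate ``sum_{t_l <= t} d_{j,l}^g / n_l^g``.

    Competing causes and censorings deplete the group's risk set but never
    the numerator.  Right-continuous step function of ``t``.
    """
    if not (1 <= cause <= data.k):
        raise ValidationError(f"cause must be in 1..{data.k}, got {cause}")
    mask = data.group_mask(group)
    if not np.any(mask):
        raise NonEstimableError(f"group {group} has no subjects")
    ts = np.sort(data.times[mask], kind="stable")
    cs = data.causes[mask][np.argsort(data.times[mask], kind="stable")]
    # at-risk just before each time: subjects with time >= t_i (ties share one count)
    n_at = len(ts) - np.searchsorted(ts, ts, side="left")
    sel = (cs == cause) & (ts <= t)
    return float(np.sum(1.0 / n_at[sel]))


def estimate_whr_nonparametric(data: TrialDataset, w: WeightScheme, t: float) -> WhrEstimate:
    """Non-parametric WHR estimate: ratio of weighted Nelson-Aalen sums at ``t``."""
    w.check_length(data.k)
    if not data.testable:
        return WhrEstimate(NONPARAMETRIC, t, w, converged=False, reason="a group is empty")
    comps = {
        (g, j): nelson_aalen(data, g, j, t) for g in ("I", "C") for j in range(1, data.k + 1)
    }
    warr = w.as_array()
    num = float(sum(warr[j - 1] * comps[("I", j)] for j in range(1, data.k + 1)))
    den = float(sum(warr[j - 1] * comps[("C", j)] for j in range(1, data.k + 1)))
    if den == 0.0 or num == 0.0:
        which = "control" if den == 0.0 else "intervention"
        return WhrEstimate(
            NONPARAMETRIC, t, w, components=comps, converged=False,
            reason=f"weighted {which} cumulative hazard is zero at t={t}",
        )
    value = num / den
    return WhrEstimate(NONPARAMETRIC, t, w, value=value, log_value=math.log(value), components=comps)


def fit_weibull_mle(
    times: Sequence[float], event_flags: Sequence[bool]
) -> tuple[float, float]:
    """Maximum-likelihood Weibull fit (hazard ``kappa*nu*t**(nu-1)``) with
    right censoring.

    The scale profiles out in closed form, ``kappa(nu) = d / sum_i t_i**nu``,
    and the one-dimensional profile score in ``nu`` is solved by bracketed
    Brent iteration (times are rescaled by their maximum for numerical
    stability).  The profile score at the solution is verified below 1e-6 so
    a returned fit always satisfies the stationarity condition; failures
    raise :class:`NonEstimableError` rather than returning clipped values.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if t.shape != e.shape:
        raise ValidationError("times and event_flags must have equal length")
    d = int(e.sum())
    if d < 2:
        raise NonEstimableError(f"need at least 2 events for a Weibull fit, got {d}")
    if np.any(t[e] <= 0):
        raise NonEstimableError("event times must be strictly positive")
    if np.all(t == t[0]):
        raise NonEstimableError("all observation times identical")
    tmax = float(t.max())
    u = t / tmax
    pos = u > 0
    lu = np.log(u[pos])
    sum_lue = float(np.log(t[e] / tmax).sum())

    def score(nu: float) -> float:
        p = np.exp(nu * lu)
        return d / nu + sum_lue - d * float(p @ lu) / float(p.sum())

    lo, hi = 1e-6, 1.0
    f_hi = score(hi)
    n_double = 0
    while f_hi > 0 and n_double < 60:
        hi *= 2.0
        f_hi = score(hi)
        n_double += 1
    if f_hi > 0:
        raise NonEstimableError("Weibull shape estimate diverges (profile score has no root)")
    nu_hat = float(optimize.brentq(score, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=500))
    if abs(score(nu_hat)) > 1e-6:
        raise NonEstimableError("Weibull profile score did not converge below tolerance")
    kappa_hat = d / (tmax**nu_hat * float(np.exp(nu_hat * lu).sum()))
    return float(kappa_hat), nu_hat


def fit_weibull_ph(
    times: Sequence[float], event_flags: Sequence[bool], in_group_I: Sequence[bool]
) -> tuple[float, float, float]:
    """Weibull proportional-hazards fit with a binary group term.

    Maximizes the right-censored likelihood of the model with hazard
    ``kappa_g * nu * t**(nu - 1)`` where the shape ``nu`` is common to both
    groups and the scale ``kappa_g`` is group-specific (equivalently, a
    Weibull regression with a treatment covariate acting proportionally on
    the hazard).  Returns ``(kappa_I, kappa_C, nu)``.

    Both scales profile out in closed form, ``kappa_g(nu) = d_g /
    sum_{i in g} t_i**nu``, and the profile score in ``nu`` is solved by
    bracketed Brent iteration after rescaling times by their maximum.
    Requires at least one event per group and two events overall.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    z = np.asarray(in_group_I, dtype=bool)
    if not (t.shape == e.shape == z.shape):
        raise ValidationError("times, event_flags and in_group_I must have equal length")
    d_I = int(e[z].sum())
    d_C = int(e[~z].sum())
    d = d_I + d_C
    if d_I < 1 or d_C < 1:
        raise NonEstimableError(
            f"need at least 1 event in each group, got I={d_I}, C={d_C}"
        )
    if d < 2:
        raise NonEstimableError("need at least 2 events overall")
    if np.any(t[e] <= 0):
        raise NonEstimableError("event times must be strictly positive")
    tmax = float(t.max())
    u = t / tmax
    pos = u > 0
    lu_I = np.log(u[z & pos])
    lu_C = np.log(u[~z & pos])
    if lu_I.size == 0 or lu_C.size == 0:
        raise NonEstimableError("all observation times are zero in one group")
    sum_lue = float(np.log(t[e] / tmax).sum())

    def score(nu: float) -> float:
        p_I = np.exp(nu * lu_I)
        p_C = np.exp(nu * lu_C)
        return (
            d / nu
            + sum_lue
            - d_I * float(p_I @ lu_I) / float(p_I.sum())
            - d_C * float(p_C @ lu_C) / float(p_C.sum())
        )

    hi = 1.0
    f_hi = score(hi)
    n_double = 0
    while f_hi > 0 and n_double < 60:
        hi *= 2.0
        f_hi = score(hi)
        n_double += 1
    if f_hi > 0:
        raise NonEstimableError("Weibull shape estimate diverges (profile score has no root)")
    nu_hat = float(optimize.brentq(score, 1e-6, hi, xtol=1e-12, rtol=8.9e-16, maxiter=500))
    if abs(score(nu_hat)) > 1e-6:
        raise NonEstimableError("Weibull profile score did not converge below tolerance")
    kappa_I = d_I / (tmax**nu_hat * float(np.exp(nu_hat * lu_I).sum()))
    kappa_C = d_C / (tmax**nu_hat * float(np.exp(nu_hat * lu_C).sum()))
    return float(kappa_I), float(kappa_C), nu_hat


def estimate_whr_parametric(data: TrialDataset, w: WeightScheme, t: float) -> WhrEstimate:
    """Parametric WHR estimate: per-cause Weibull proportional-hazards fits,
    fitted hazards evaluated at ``t`` and combined into the weighted ratio.

    A failed component fit renders the whole estimate non-estimable (the
    replicate is excluded downstream rather than imputed).
    """
    w.check_length(data.k)
    if not data.testable:
        return WhrEstimate(PARAMETRIC, t, w, converged=False, reason="a group is empty")
    if t <= 0:
        raise ValidationError("evaluation time must be positive for the parametric estimator")
    comps: dict = {}
    hazards = {}
    z_I = data.group_mask("I")
    for j in range(1, data.k + 1):
        try:
            kappa_I, kappa_C, nu = fit_weibull_ph(data.times, data.causes == j, z_I)
        except NonEstimableError as exc:
            return WhrEstimate(
                PARAMETRIC, t, w, components=comps, converged=False,
                reason=f"Weibull fit failed for EP{j}: {exc}",
            )
        comps[("I", j)] = (kappa_I, nu)
        comps[("C", j)] = (kappa_C, nu)
        hazards[("I", j)] = kappa_I * nu * t ** (nu - 1.0)
        hazards[("C", j)] = kappa_C * nu * t ** (nu - 1.0)
    warr = w.as_array()
    num = float(sum(warr[j - 1] * hazards[("I", j)] for j in range(1, data.k + 1)))
    den = float(sum(warr[j - 1] * hazards[("C", j)] for j in range(1, data.k + 1)))
    if den == 0.0 or num == 0.0:
        return WhrEstimate(
            PARAMETRIC, t, w, components=comps, converged=False,
            reason="weighted fitted hazard is zero in one group",
        )
    value = num / den
    return WhrEstimate(PARAMETRIC, t, w, value=value, log_value=math.log(value), components=comps)


# ---------------------------------------------------------------------------
# fast array-level paths shared by the permutation test and the simulator
# ---------------------------------------------------------------------------


def _prepare_sorted(times: np.ndarray, causes: np.ndarray):
    """Sort once; return (sorted times, sorted causes, first-index-of-tie)."""
    order = np.argsort(times, kind="stable")
    ts = times[order]
    cs = causes[order]
    pos_first = np.searchsorted(ts, ts, side="left")
    return ts, cs, pos_first


def _na_log_ratio_sorted(
    wsub: np.ndarray, pos_first: np.ndarray, is_event: np.ndarray, z_I: np.ndarray
) -> float:
    """Log of the non-parametric WHR from time-sorted arrays.

    ``wsub`` holds the weight of each subject's event type (0 for censored),
    ``z_I`` the group-I membership after any label permutation.  Returns NaN
    when non-estimable.  Exactly equivalent to
    :func:`estimate_whr_nonparametric` at ``t = tau``.
    """
    zf = z_I.astype(np.float64)
    # at-risk counts just before each subject's time = suffix sums from the
    # first index of its tie block
    suff_I = np.cumsum(zf[::-1])[::-1]
    n_tot = len(zf)
    idx = np.flatnonzero(is_event)
    nI_at = suff_I[pos_first[idx]]
    nC_at = (n_tot - pos_first[idx]) - nI_at
    wi = wsub[idx]
    zi = zf[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        num = float(np.sum(np.where(zi > 0, wi / nI_at, 0.0)))
        den = float(np.sum(np.where(zi > 0, 0.0, wi / nC_at)))
    if num <= 0.0 or den <= 0.0 or not (math.isfinite(num) and math.isfinite(den)):
        return math.nan
    return math.log(num) - math.log(den)


def _parametric_log_ratio(
    times: np.ndarray, causes: np.ndarray, z_I: np.ndarray, warr: np.ndarray, k: int, t: float
) -> float:
    """Log of the parametric WHR from raw arrays; NaN when non-estimable."""
    num = den = 0.0
    for j in range(1, k + 1):
        try:
            kappa_I, kappa_C, nu = fit_weibull_ph(times, causes == j, z_I)
        except NonEstimableError:
            return math.nan
        num += warr[j - 1] * kappa_I * nu * t ** (nu - 1.0)
        den += warr[j - 1] * kappa_C * nu * t ** (nu - 1.0)
    if num <= 0.0 or den <= 0.0:
        return math.nan
    return math.log(num) - math.log(den)
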