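"""Choosing relevance weights: severity equivalences, modified hazards and
event-time-distribution curve data.

The recommended procedure fixes the weight of the clinically most relevant
event type (the *reference*, often death) to 1 and derives the other weights
from severity-equivalence judgements of the form "m events of type EP_j are
as harmful as r reference events", giving ``w_j = r / m``.  Weights above 1
are possible but discouraged (they break comparability with the unweighted
analysis), so they trigger a warning rather than an error.

To visualise the consequence of a weighting scheme, the weighted composite
survival function ``S_w(t) = exp(-sum_j w_j * Lambda_j(t))`` can be tabled
over a time grid per group and scheme and compared with the unweighted
curve: down-weighting a component flattens the event-time distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hazards import (
    CauseHazardSet,
    HazardModel,
    WeightScheme,
    cumulative_hazard,
    hazard_value,
    weighted_survival,
)

__all__ = ["SeverityEquivalence", "severity_to_weights", "modified_hazard", "weight_scheme_curves"]


@dataclass(frozen=True)
class SeverityEquivalence:
    """Severity judgements relative to a reference event type.

    ``equivalences[j] = (m_j, r_j)`` states that ``m_j`` events of type ``j``
    (1-based) are as harmful as ``r_j`` reference events.  Types without an
    entry other than the reference are not allowed: every non-reference type
    needs a judgement.
    """

    k: int
    reference: int  # 1-based index of the most relevant event type
    equivalences: Mapping[int, tuple[float, float]]

    def __post_init__(self) -> None:
        if not 1 <= self.reference <= self.k:
            raise ValidationError(f"reference must be in 1..{self.k}, got {self.reference}")
        expected = set(range(1, self.k + 1)) - {self.reference}
        if set(self.equivalences) != expected:
            raise ValidationError(
                f"severity equivalences must cover exactly the non-reference types {sorted(expected)}"
            )
        for j, (m, r) in self.equivalences.items():
            if m < 1 or r < 1:
                raise ValidationError(f"equivalence counts for EP{j} must be >= 1, got ({m}, {r})")


def severity_to_weights(eq: SeverityEquivalence) -> WeightScheme:
    """Translate severity equivalences into a weight scheme.

    The reference type gets weight exactly 1 and type ``j`` gets
    ``r_j / m_j``.  Implied weights above 1 violate the recommendation that
    all non-reference weights stay at or below 1 and produce a warning.
    """
    weights = []
    for j in range(1, eq.k + 1):
        if j == eq.reference:
            weights.append(1.0)
        else:
            m, r = eq.equivalences[j]
            weights.append(r / m)
    above = [j + 1 for j, w in enumerate(weights) if w > 1 and j + 1 != eq.reference]
    if above:
        warnings.warn(
            f"implied weight above 1 for event type(s) {above}; the guidance "
            "recommends non-reference weights at or below 1",
            stacklevel=2,
        )
    return WeightScheme(tuple(weights))


class ModifiedHazard:
    """A cause-specific hazard scaled by its relevance weight.

    Callable like a hazard function; :meth:`cumulative` gives the matching
    cumulative hazard ``weight * Lambda(t)``.
    """

    def __init__(self, model: HazardModel, weight: float) -> None:
        if weight < 0:
            raise ValidationError("weight must be non-negative")
        self.model = model
        self.weight = float(weight)

    def __call__(self, t):
        return self.weight * hazard_value(self.model, t)

    def cumulative(self, t):
        return self.weight * cumulative_hazard(self.model, t)


def modified_hazard(model: HazardModel, weight: float) -> ModifiedHazard:
    """Pointwise product ``w * lambda(t)`` as a hazard callable."""
    return ModifiedHazard(model, weight)


def weight_scheme_curves(
    hazards: CauseHazardSet,
    schemes: Sequence[WeightScheme],
    grid: Sequence[float],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Weighted composite survival curves per scheme, group and grid point.

    Returns a tidy table with columns ``scheme``, ``group``, ``time`` and
    ``survival``, always including the unweighted (all-ones) curve under the
    scheme label ``"unweighted"``.  Intended for plotting when comparing
    candidate weighting schemes in the planning stage.
    """
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0:
        raise ValidationError("time grid must be non-empty")
    if np.any(grid_arr < 0):
        raise ValidationError("time grid must be non-negative")
    if labels is None:
        labels = [f"scheme_{i + 1}" for i in range(len(schemes))]
    if len(labels) != len(schemes):
        raise ValidationError("labels and schemes must have equal length")
    all_schemes = [("unweighted", WeightScheme.ones(hazards.k))]
    all_schemes += list(zip(labels, schemes))
    rows = []
    for label, scheme in all_schemes:
        for group in ("I", "C"):
            surv = weighted_survival(hazards, group, scheme, grid_arr)
            for t, s in zip(grid_arr, np.atleast_1d(surv)):
                rows.append({"scheme": label, "group": group, "time": t, "survival": s})
    return pd.DataFrame(rows)
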