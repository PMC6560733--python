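"""Subject-level competing-risks trial data and the event/risk-set table.

The unit of data is one row per subject with a follow-up time, a cause code
(0 = censored, 1..k = type of the first event) and a group label (``I`` for
intervention, ``C`` for control).  Datasets are exchanged as comma-separated
text with header ``time,cause,group``.

:func:`build_event_table` derives from a dataset the risk-set and event-count
quantities at the distinct ordered event times of the pooled sample — the
``n_l``/``d_l`` ingredients of both log-rank statistics and of the
Nelson-Aalen estimators.  At-risk counts are evaluated *just before* each
event time (left-continuous convention), so a subject censored exactly at an
event time is still at risk there.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SubjectRecord", "TrialDataset", "EventTable", "read_dataset", "write_dataset", "build_event_table"]

GROUP_LABELS = ("I", "C")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: follow-up time, cause of the first event (0 = censored), group."""

    time: float
    cause: int
    group: str


class TrialDataset:
    """Container for a two-arm time-to-first-event dataset with ``k`` event types.

    All record times are at most ``tau`` (the end of the observational
    period); construction truncates later times to administrative censoring
    at ``tau`` when ``truncate=True`` (the default for file input).
    """

    def __init__(
        self,
        times: Sequence[float],
        causes: Sequence[int],
        groups: Sequence[str],
        k: int,
        tau: float,
        truncate: bool = False,
    ) -> None:
        times_arr = np.asarray(times, dtype=float).copy()
        causes_arr = np.asarray(causes, dtype=np.int64).copy()
        groups_arr = np.asarray(groups, dtype=object)
        if not (len(times_arr) == len(causes_arr) == len(groups_arr)):
            raise ValidationError("times, causes and groups must have equal length")
        if k < 1:
            raise ValidationError("k must be at least 1")
        if tau <= 0:
            raise ValidationError("tau must be positive")
        for i, g in enumerate(groups_arr):
            if g not in GROUP_LABELS:
                raise ValidationError(f"row {i}: unknown group label {g!r}; expected 'I' or 'C'")
        bad = np.flatnonzero(times_arr < 0)
        if bad.size:
            raise ValidationError(f"row {bad[0]}: negative time {times_arr[bad[0]]}")
        bad = np.flatnonzero((causes_arr < 0) | (causes_arr > k))
        if bad.size:
            raise ValidationError(
                f"row {bad[0]}: cause {causes_arr[bad[0]]} outside 0..{k}"
            )
        late = times_arr > tau
        if np.any(late):
            if not truncate:
                raise ValidationError(
                    f"row {np.flatnonzero(late)[0]}: time exceeds tau={tau} "
                    "(pass truncate=True to censor administratively)"
                )
            times_arr[late] = tau
            causes_arr[late] = 0
        self.times = times_arr
        self.causes = causes_arr
        self.groups = np.asarray([str(g) for g in groups_arr], dtype="U1")
        self.k = int(k)
        self.tau = float(tau)

    @classmethod
    def from_records(
        cls, records: Iterable[SubjectRecord], k: int, tau: float, truncate: bool = False
    ) -> "TrialDataset":
        recs = list(records)
        return cls(
            [r.time for r in recs],
            [r.cause for r in recs],
            [r.group for r in recs],
            k,
            tau,
            truncate=truncate,
        )

    @property
    def records(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(float(t), int(c), str(g))
            for t, c, g in zip(self.times, self.causes, self.groups)
        ]

    @property
    def n(self) -> int:
        return len(self.times)

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUP_LABELS:
            raise ValidationError(f"unknown group label {group!r}; expected 'I' or 'C'")
        return self.groups == group

    def n_events(self) -> int:
        return int(np.count_nonzero(self.causes > 0))

    @property
    def testable(self) -> bool:
        """Both groups non-empty — precondition of all estimation/test operations."""
        return bool(np.any(self.groups == "I") and np.any(self.groups == "C"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "cause": self.causes, "group": self.groups})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nI = int(np.count_nonzero(self.groups == "I"))
        return (
            f"TrialDataset(n={self.n} [I={nI}, C={self.n - nI}], k={self.k}, "
            f"tau={self.tau}, events={self.n_events()})"
        )


def read_dataset(source, k: int, tau: float) -> TrialDataset:
    """Read a dataset from delimited text (header ``time,cause,group``).

    Records with time beyond ``tau`` are administratively censored at ``tau``.
    Malformed rows raise :class:`ValidationError` naming the offending row.
    """
    frame = pd.read_csv(source, float_precision="round_trip")
    missing = {"time", "cause", "group"} - set(frame.columns)
    if missing:
        raise ValidationError(f"missing required column(s): {sorted(missing)}")
    try:
        times = frame["time"].astype(float).to_numpy()
        causes = frame["cause"].astype(int).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric time or cause column: {exc}") from exc
    groups = frame["group"].astype(str).to_numpy()
    return TrialDataset(times, causes, groups, k=k, tau=tau, truncate=True)


def write_dataset(data: TrialDataset, sink) -> None:
    """Write a dataset as comma-separated text; round-trips exactly through
    :func:`read_dataset` (full float precision, order preserving)."""
    # %.17g guarantees bit-exact float round trips
    data.to_frame().to_csv(sink, index=False, float_format="%.17g")


@dataclass(frozen=True)
class EventTable:
    """Risk sets and per-group, per-cause event counts at distinct event times.

    Row ``l`` corresponds to the ``l``-th distinct ordered event time of the
    pooled sample.  ``n_I[l]``/``n_C[l]`` are the numbers at risk just before
    that time and ``d_I[l, j - 1]``/``d_C[l, j - 1]`` the numbers of type-``j``
    events occurring at it.
    """

    times: np.ndarray  # (d,)
    n_I: np.ndarray  # (d,)
    n_C: np.ndarray  # (d,)
    d_I: np.ndarray  # (d, k)
    d_C: np.ndarray  # (d, k)

    @property
    def k(self) -> int:
        return self.d_I.shape[1]

    @property
    def n_rows(self) -> int:
        return len(self.times)

    @property
    def d_group_I(self) -> np.ndarray:
        """All-cause event counts per time in group I."""
        return self.d_I.sum(axis=1)

    @property
    def d_group_C(self) -> np.ndarray:
        return self.d_C.sum(axis=1)

    @property
    def d_total(self) -> np.ndarray:
        return self.d_group_I + self.d_group_C

    @property
    def d_cause(self) -> np.ndarray:
        """Pooled per-cause event counts, shape (d, k)."""
        return self.d_I + self.d_C

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "n_I": self.n_I, "n_C": self.n_C}
        for j in range(self.k):
            data[f"d_I_EP{j + 1}"] = self.d_I[:, j]
            data[f"d_C_EP{j + 1}"] = self.d_C[:, j]
        return pd.DataFrame(data)


def build_event_table(data: TrialDataset) -> EventTable:
    """Construct the :class:`EventTable` of a dataset.

    All subjects (events and censorings) deplete the risk set after their
    follow-up time; at-risk counts at ``t_l`` include every subject whose
    time is ``>= t_l``.  With zero events an empty table is returned; test
    statistics treat that as degenerate.
    """
    event = data.causes > 0
    times = np.unique(data.times[event])
    d = len(times)
    k = data.k
    is_I = data.groups == "I"
    n_I = np.empty(d, dtype=np.int64)
    n_C = np.empty(d, dtype=np.int64)
    # at-risk just before t_l: time >= t_l
    tI = np.sort(data.times[is_I])
    tC = np.sort(data.times[~is_I])
    n_I[:] = len(tI) - np.searchsorted(tI, times, side="left")
    n_C[:] = len(tC) - np.searchsorted(tC, times, side="left")
    d_I = np.zeros((d, k), dtype=np.int64)
    d_C = np.zeros((d, k), dtype=np.int64)
    if d:
        row = np.searchsorted(times, data.times[event])
        col = data.causes[event] - 1
        grp_I = is_I[event]
        np.add.at(d_I, (row[grp_I], col[grp_I]), 1)
        np.add.at(d_C, (row[~grp_I], col[~grp_I]), 1)
    return EventTable(times=times, n_I=n_I, n_C=n_C, d_I=d_I, d_C=d_C)
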