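"""Independent brute-force oracles used to validate the implementation.

Each oracle is deliberately naive (exhaustive enumeration, double loops,
exact rational arithmetic) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def hypergeometric_moments_enumerated(nI: int, nC: int, d: int) -> tuple[Fraction, Fraction]:
    """Exact mean/variance of the group-I event count by enumerating all
    ways to place d events among nI + nC subjects (rational arithmetic)."""
    n = nI + nC
    total = math.comb(n, d)
    mean = Fraction(0)
    second = Fraction(0)
    for x in range(0, d + 1):
        ways = math.comb(nI, x) * math.comb(nC, d - x) if d - x <= nC and x <= nI else 0
        if ways:
            p = Fraction(ways, total)
            mean += p * x
            second += p * x * x
    return mean, second - mean * mean


def nelson_aalen_double_loop(times, causes, cause: int, t: float) -> float:
    """Cause-specific Nelson-Aalen by an O(n^2) double loop over subjects."""
    times = list(map(float, times))
    causes = list(map(int, causes))
    out = 0.0
    for ti, ci in zip(times, causes):
        if ci == cause and ti <= t:
            at_risk = sum(1 for tj in times if tj >= ti)
            out += 1.0 / at_risk
    return out


def logrank_by_hand(times, causes, groups) -> float:
    """Standard log-rank statistic via explicit per-time risk-set recounts."""
    times = np.asarray(times, float)
    causes = np.asarray(causes, int)
    gI = np.asarray([g == "I" for g in groups])
    event_times = sorted(set(times[causes > 0]))
    num = 0.0
    var = 0.0
    for tl in event_times:
        nI = int(np.sum((times >= tl) & gI))
        nC = int(np.sum((times >= tl) & ~gI))
        n = nI + nC
        d = int(np.sum((times == tl) & (causes > 0)))
        dI = int(np.sum((times == tl) & (causes > 0) & gI))
        num += dI - nI * d / n
        if n > 1:
            var += nI * nC * (n - d) * d / (n**2 * (n - 1))
    return num / math.sqrt(var)


def permutation_pvalue_enumerated(stat_fn, n: int, n_I: int, observed: float) -> float:
    """Exact permutation p-value: proportion of all C(n, n_I) group-label
    assignments whose statistic is <= the observed one (NaNs dropped)."""
    stats = []
    for members in itertools.combinations(range(n), n_I):
        z = np.zeros(n, dtype=bool)
        z[list(members)] = True
        s = stat_fn(z)
        if not math.isnan(s):
            stats.append(s)
    arr = np.asarray(stats)
    return float(np.count_nonzero(arr <= observed) / len(arr))


def random_small_dataset(rng: np.random.Generator, k: int = 2, max_n: int = 12):
    """A random small competing-risks dataset (times, causes, groups)."""
    n = int(rng.integers(4, max_n + 1))
    times = np.round(rng.uniform(0.1, 3.0, n), 2)  # rounded to provoke ties
    causes = rng.integers(0, k + 1, n)
    groups = np.where(rng.random(n) < 0.5, "I", "C")
    # ensure both groups present and at least one event
    groups[0], groups[1] = "I", "C"
    if not np.any(causes > 0):
        causes[0] = 1
    return times, causes, groups
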