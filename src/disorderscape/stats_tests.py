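"""Nonparametric statistics used throughout the pipeline.

The Mann-Whitney U test is implemented here from first principles because it
is the workhorse significance test for every group comparison in the
analysis (family disorder contrasts, E2-binding vs remainder regions, hub
vs non-hub connectivity classes). Small samples are handled by exact
enumeration of all ``C(n1+n2, n1)`` group labelings; larger samples use the
normal approximation with tie-corrected variance and a continuity
correction.

Pearson correlation and percentage histogram binning are provided alongside
because the report modules need them with precise, documented boundary
semantics.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "Tail",
    "Method",
    "TestResult",
    "mann_whitney",
    "pearson_r",
    "bin_distribution",
    "DEFAULT_EXACT_LIMIT",
]

#: Exact enumeration is used when max(n1, n2) <= this limit.
DEFAULT_EXACT_LIMIT = 8


class Tail(str, enum.Enum):
    ONE_GREATER = "one_greater"  # alternative: x tends to exceed y
    ONE_LESS = "one_less"        # alternative: x tends to fall below y
    TWO = "two"


class Method(str, enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"


@dataclass(frozen=True)
class TestResult:
    U: float
    n1: int
    n2: int
    p_value: float
    tail: Tail
    method: Method


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..n with midranks (tied values share the average rank)."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        # ranks i+1 .. j+1 averaged; sums of half-integers stay exact in floats
        ranks[order[i : j + 1]] = (i + j + 2) / 2.0
        i = j + 1
    return ranks


@lru_cache(maxsize=64)
def _combination_index(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets as an array of shape (C, k). Cached."""
    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: rank-sum form, ties handled by midranks."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    tail: Tail | str = Tail.TWO,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> TestResult:
    """Mann-Whitney U test of two independent samples.

    ``U`` counts pairs where x exceeds y (ties count one half), computed
    from midranked rank sums. With ``max(n1, n2) <= exact_limit`` the
    p-value is obtained by enumerating every assignment of the pooled
    values to the two groups; otherwise the normal approximation with
    tie-corrected variance and a 0.5 continuity correction is used.

    Tails: ``one_greater`` tests the alternative that x is stochastically
    greater than y; ``one_less`` the reverse; ``two`` is two-sided.
    """
    tail = Tail(tail)
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values in samples")

    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if max(n1, n2) <= exact_limit:
        pooled = np.concatenate([x, y])
        ranks = _midranks(pooled)
        idx = _combination_index(n1 + n2, n1)
        u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        # U values are half-integers, so these comparisons are exact.
        if tail is Tail.ONE_LESS:
            p = float(np.mean(u_all <= u_obs))
        elif tail is Tail.ONE_GREATER:
            p = float(np.mean(u_all >= u_obs))
        else:
            p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu)))
        return TestResult(u_obs, n1, n2, p, tail, Method.EXACT)

    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values tied: no evidence either way
        return TestResult(u_obs, n1, n2, 1.0, tail, Method.NORMAL_APPROX)
    sd = math.sqrt(var)

    def phi(z: float) -> float:
        return 0.5 * math.erfc(-z / math.sqrt(2.0))

    p_less = phi((u_obs - mu + 0.5) / sd)
    p_greater = phi((mu - u_obs + 0.5) / sd)
    if tail is Tail.ONE_LESS:
        p = p_less
    elif tail is Tail.ONE_GREATER:
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return TestResult(u_obs, n1, n2, p, tail, Method.NORMAL_APPROX)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; constant input is an error, not NaN."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two points")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(dx @ dy / math.sqrt(sxx * syy))


def bin_distribution(
    values: Sequence[float], bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of percentages on [0, 100].

    Bins are left-closed right-open, ``[0, w), [w, 2w), ...``, except that
    the final bin is closed at 100 so the counts always sum to ``len(values)``.
    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1``.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size and (values.min() < 0 or values.max() > 100):
        raise ValueError("values must lie in [0, 100]")
    n_bins = math.ceil(100.0 / bin_width)
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 100.0)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts
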