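"""Temporal change rates and natural-breaks classification of ESV change.

Change between two periods is expressed two ways: as a percentage rate
for county/structure tables, and as an absolute per-cell difference
map classified into k intervals by Jenks natural breaks. The breaks
are the exact Fisher–Jenks dynamic-programming optimum of the
within-class sum of squared deviations over contiguous partitions of
the sorted values — not a heuristic — with ties broken toward the
earlier split so output is deterministic. Intervals follow the
(a, b] half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DegenerateInputError, DomainError


def change_rate(v_start: float, v_end: float) -> float:
    """Percent change 100·(v_end − v_start)/v_start.

    Raises :class:`DomainError` on a zero baseline, where the rate is
    undefined.
    """
    if v_start == 0:
        raise DomainError("change rate is undefined for a zero baseline")
    return 100.0 * (v_end - v_start) / v_start


@njit(cache=True)
def _fisher_jenks_dp(x: np.ndarray, k: int) -> np.ndarray:
    """DP over sorted data x; returns the k-1 split indices (exclusive ends).

    cost[i] for class (a..i) uses prefix sums; D[i, j] = minimal
    within-class SS of x[0..i] split into j classes. Ties prefer the
    earlier split index.
    """
    n = x.shape[0]
    s1 = np.empty(n + 1)
    s2 = np.empty(n + 1)
    s1[0] = 0.0
    s2[0] = 0.0
    for i in range(n):
        s1[i + 1] = s1[i] + x[i]
        s2[i + 1] = s2[i] + x[i] * x[i]

    # ssm(a, b): within-class SS of x[a..b] inclusive
    D = np.full((n, k + 1), np.inf)
    split = np.zeros((n, k + 1), dtype=np.int64)
    for i in range(n):
        m = i + 1
        D[i, 1] = s2[m] - s1[m] * s1[m] / m
    for j in range(2, k + 1):
        for i in range(j - 1, n):
            best = np.inf
            best_m = -1
            # last class is x[m..i]; previous classes cover x[0..m-1]
            for m in range(j - 1, i + 1):
                left = D[m - 1, j - 1]
                cnt = i - m + 1
                seg1 = s1[i + 1] - s1[m]
                seg2 = s2[i + 1] - s2[m]
                cost = left + (seg2 - seg1 * seg1 / cnt)
                if cost < best:  # strict: earliest split wins ties
                    best = cost
                    best_m = m
            D[i, j] = best
            split[i, j] = best_m
    # backtrack split starts
    starts = np.empty(k - 1, dtype=np.int64)
    i = n - 1
    for j in range(k, 1, -1):
        m = split[i, j]
        starts[j - 2] = m
        i = m - 1
    return starts


def jenks_breaks(values, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact Fisher–Jenks natural breaks.

    Parameters
    ----------
    values : array-like of real
    k : int
        Number of classes, ≥ 2; requires at least k distinct values.

    Returns
    -------
    boundaries : (k-1,) array
        Upper boundaries of classes 1..k−1 (data values); strictly
        increasing. Class c is (boundaries[c-1], boundaries[c]] with
        open ends below the minimum and above the maximum.
    labels : int array, same shape as ``values``
        Class index 0..k−1 per element.
    """
    vals = np.asarray(values, dtype=float)
    flat = vals.ravel()
    if not np.all(np.isfinite(flat)):
        raise DomainError("values must be finite")
    if k < 2:
        raise DegenerateInputError("k must be at least 2")
    if np.unique(flat).size < k:
        raise DegenerateInputError(
            f"need at least {k} distinct values, got {np.unique(flat).size}"
        )
    order = np.sort(flat)
    starts = _fisher_jenks_dp(order, k)
    # boundary between class c and c+1 = last value of class c
    boundaries = order[starts - 1]
    labels = np.searchsorted(boundaries, flat, side="left").reshape(vals.shape)
    return boundaries, labels


@dataclass
class ChangeMap:
    """Classified per-cell ESV change between two years."""

    delta: np.ndarray  # yuan per cell
    labels: np.ndarray  # class index 0..k-1
    boundaries: np.ndarray  # k-1 increasing break values
    year_start: str = ""
    year_end: str = ""

    @property
    def k(self) -> int:
        return len(self.boundaries) + 1

    def intervals(self) -> list[str]:
        """Printable (a, b] interval strings, one per class."""
        lo = float(self.delta.min())
        hi = float(self.delta.max())
        edges = [lo, *map(float, self.boundaries), hi]
        return [f"({edges[c]:.2f}, {edges[c + 1]:.2f}]" for c in range(self.k)]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.k)


def classify_change(delta: np.ndarray, k: int = 7, year_start: str = "", year_end: str = "") -> ChangeMap:
    """Classify a per-cell ESV difference map into k natural-breaks classes."""
    delta = np.asarray(delta, dtype=float)
    boundaries, labels = jenks_breaks(delta, k)
    return ChangeMap(
        delta=delta,
        labels=labels,
        boundaries=boundaries,
        year_start=year_start,
        year_end=year_end,
    )
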