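"""One-dimensional classification of terrain variables.

Continuous variables (slope, ruggedness, solar gain) are cut into ordered
classes at natural breaks (Jenks optimization): the contiguous partition of
the sorted values minimizing the total within-class sum of squared
deviations from class means, found by exact dynamic programming.  Aspect is
classified into the four cardinal quadrants.

All intervals are half-open ``[lo, hi)`` except the last, which is closed
above; a value exactly at a breakpoint therefore falls in the upper class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ClassificationScheme",
    "jenks_breaks",
    "classify_value",
    "classify_aspect",
    "DEFAULT_CLASS_LABELS",
]

#: Ordered labels used for k-class schemes, following common cartographic usage.
DEFAULT_CLASS_LABELS = {
    1: ("uniform",),
    2: ("low", "high"),
    3: ("low", "medium", "high"),
    4: ("low", "medium-low", "medium-high", "high"),
}

SLOPE_LABELS_4 = ("low", "medium", "high", "very high")


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered class intervals for one variable.

    ``breakpoints`` are the k-1 strictly increasing thresholds separating k
    classes; ``labels`` names the classes from lowest to highest.
    """

    variable: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one more label than breakpoints")
        if any(b >= c for b, c in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")


def jenks_breaks(
    values: Sequence[float],
    k: int,
    labels: Sequence[str] | None = None,
    variable: str = "",
) -> ClassificationScheme:
    """Exact natural-breaks classification of ``values`` into ``k`` classes.

    Dynamic programming (Fisher's algorithm, O(k n^2)) over the sorted
    values guarantees the global optimum; ties between equally good
    partitions are broken toward the smallest first breakpoint.  The
    breakpoint between two classes is the smallest value of the upper
    class, consistent with the half-open interval rule of
    :func:`classify_value`.
    """
    raw = np.sort(np.asarray(values, dtype=float))
    if not 1 <= k <= raw.size:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={raw.size}")
    # a threshold scheme assigns equal values to one class, so the search
    # runs over distinct values weighted by multiplicity
    vals, wts = np.unique(raw, return_counts=True)
    n = vals.size
    if n < k:
        raise ValueError(f"need at least k={k} distinct values to form k classes")

    # weighted prefix sums for O(1) within-class SSD of vals[i:j]; centering
    # avoids catastrophic cancellation when values are large and close
    centered = vals - np.average(vals, weights=wts)
    cw = np.concatenate([[0.0], np.cumsum(wts)])
    csum = np.concatenate([[0.0], np.cumsum(wts * centered)])
    csq = np.concatenate([[0.0], np.cumsum(wts * centered**2)])

    def ssd(i: int, j: int) -> float:
        """Weighted sum of squared deviations of vals[i:j] from their mean."""
        m = cw[j] - cw[i]
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / m

    INF = float("inf")
    # cost[c][j]: best total SSD splitting vals[:j] into c classes
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = INF, c - 1
            for i in range(c - 1, j):
                cand = cost[c - 1][i] + ssd(i, j)
                # strict '<' keeps the smallest feasible split index on ties,
                # i.e. the smallest first breakpoint
                if cand < best:
                    best, best_i = cand, i
            cost[c][j] = best
            split[c][j] = best_i

    # recover class boundaries
    bounds = []
    j = n
    for c in range(k, 0, -1):
        i = split[c][j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1][1:]  # drop the leading 0
    breakpoints = tuple(float(vals[i]) for i in bounds)

    if labels is None:
        labels = DEFAULT_CLASS_LABELS.get(k, tuple(f"class_{c+1}" for c in range(k)))
    return ClassificationScheme(variable=variable, breakpoints=breakpoints, labels=tuple(labels))


def classify_value(x: float, scheme: ClassificationScheme) -> str:
    """Label of the interval containing ``x`` (half-open ``[lo, hi)`` rule).

    Values below the first breakpoint take the first label and values at or
    above the last take the last label.
    """
    if not np.isfinite(x):
        raise ValueError(f"cannot classify non-finite value {x!r}")
    idx = int(np.searchsorted(scheme.breakpoints, x, side="right"))
    return scheme.labels[idx]


def classify_aspect(aspect: float) -> str | None:
    """Cardinal quadrant of a downslope aspect in degrees.

    N = [315, 360) u [0, 45), E = [45, 135), S = [135, 225), W = [225, 315).
    Undefined aspect (NaN, flat terrain) returns ``None``: a flat cell has
    no defensible facing.
    """
    if aspect is None or (isinstance(aspect, float) and np.isnan(aspect)):
        return None
    a = float(aspect) % 360.0
    if a < 45 or a >= 315:
        return "N"
    if a < 135:
        return "E"
    if a < 225:
        return "S"
    return "W"
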