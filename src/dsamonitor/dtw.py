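"""Dynamic time warping (DTW) between two numeric sequences.

DTW is the similarity measure behind the nearest-centroid pattern
classifier: the distance is the minimum, over all monotone alignments of
the two sequences, of the accumulated local cost.  The default local cost
is the absolute difference ``|a_i - b_j|``; squared difference is exposed
as an option.  No warping window is imposed (series here are at most 50
points) and the accumulated distance is not path-length normalised by
default — compared series always have equal length, so normalisation
would not change nearest-centroid rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from numba import njit

#: admissible warping steps (delta i, delta j)
_STEPS = ((1, 1), (1, 0), (0, 1))


@dataclass(frozen=True)
class DtwResult:
    """Accumulated DTW cost and the optimal warping path.

    ``path`` is a list of 1-based index pairs from ``(1, 1)`` to
    ``(n, m)`` with steps in {(+1,0), (0,+1), (+1,+1)}; ``distance`` is
    the sum of local costs along it.
    """

    distance: float
    path: Tuple[Tuple[int, int], ...]


def _as_sequence(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _local_cost(a: np.ndarray, b: np.ndarray, cost: str) -> np.ndarray:
    diff = np.abs(a[:, None] - b[None, :])
    if cost == "absolute":
        return diff
    if cost == "squared":
        return diff**2
    raise ValueError(f"unknown cost {cost!r}; use 'absolute' or 'squared'")


@njit(cache=True)
def _dtw_cost_matrix(local: np.ndarray) -> np.ndarray:  # pragma: no cover - jitted
    n, m = local.shape
    acc = np.empty((n, m))
    acc[0, 0] = local[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + local[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + local[i, 0]
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = local[i, j] + best
    return acc


@njit(cache=True)
def dtw_distance_fast(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover
    """Distance-only DTW with absolute cost; the classifier's hot path."""
    n = a.shape[0]
    m = b.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = abs(a[0] - b[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        cur[0] = prev[0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = abs(a[i] - b[j]) + best
        prev, cur = cur, prev
    return prev[m - 1]


def dtw_distance(
    a: Sequence[float],
    b: Sequence[float],
    cost: str = "absolute",
    normalize: bool = False,
) -> DtwResult:
    """DTW distance and optimal warping path between two sequences.

    Parameters
    ----------
    a, b : sequence of float
        Non-empty sequences of finite values.
    cost : {"absolute", "squared"}
        Local cost between aligned elements.
    normalize : bool
        Divide the accumulated distance by the path length.  Off by
        default; see the module docstring.

    Returns
    -------
    DtwResult
        Minimal accumulated cost and one optimal path (ties among
        equal-cost predecessors are broken in favour of the diagonal
        step, which affects the path but never the distance).
    """
    av = _as_sequence(a, "a")
    bv = _as_sequence(b, "b")
    local = _local_cost(av, bv, cost)
    acc = _dtw_cost_matrix(local)
    # backtrack, preferring the diagonal on ties
    i, j = av.size - 1, bv.size - 1
    rev: List[Tuple[int, int]] = [(i + 1, j + 1)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        rev.append((i + 1, j + 1))
    path = tuple(reversed(rev))
    dist = float(acc[-1, -1])
    if normalize:
        dist /= len(path)
    return DtwResult(distance=dist, path=path)


_BRUTE_FORCE_MAX = 10


def dtw_brute_force(
    a: Sequence[float], b: Sequence[float], cost: str = "absolute"
) -> DtwResult:
    """Exhaustive-enumeration DTW for short sequences — a test oracle.

    Recursively enumerates every admissible warping path and returns the
    cheapest one.  Refuses sequences longer than 10 points each; use
    :func:`dtw_distance` for real work.
    """
    av = _as_sequence(a, "a")
    bv = _as_sequence(b, "b")
    if av.size > _BRUTE_FORCE_MAX or bv.size > _BRUTE_FORCE_MAX:
        raise ValueError(
            f"brute-force enumeration is limited to {_BRUTE_FORCE_MAX} points per sequence"
        )
    local = _local_cost(av, bv, cost)
    n, m = local.shape

    def best_from(i: int, j: int) -> Tuple[float, Tuple[Tuple[int, int], ...]]:
        here = local[i, j]
        if i == n - 1 and j == m - 1:
            return here, ((i + 1, j + 1),)
        cand = []
        for di, dj in _STEPS:
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                sub_cost, sub_path = best_from(ni, nj)
                cand.append((here + sub_cost, ((i + 1, j + 1),) + sub_path))
        return min(cand, key=lambda t: t[0])

    dist, path = best_from(0, 0)
    return DtwResult(distance=float(dist), path=path)
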