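"""Nearest-centroid DTW classification of DSA dynamic patterns.

The model follows the usual fit/results split: :class:`DsaPatternModel`
holds a labelled cohort of daily total-DSA series; ``fit()`` computes the
per-group mean trajectory (the *centroid*) and returns a
:class:`DsaPatternResults` that predicts the pattern of new or reduced
series by smallest DTW distance to the centroids, and scores accuracy
``C = Ncp / Np * 100`` on any monitoring-day subset.

By default the classification universe is the four dynamic patterns 1-4
(fast/slow modulation, rise to sustained, sustained); the flat
"no response" group 0 can be included with a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numba import njit

from .dtw import dtw_distance_fast
from .trajectories import (
    FULL_GRID,
    GROUP_NAMES,
    TrajectorySeries,
    _validate_day_subset,
    interpolate_daily,
)


@dataclass(frozen=True)
class CentroidSet:
    """Per-group mean daily trajectory, the classifier's reference."""

    centroids: Mapping[int, TrajectorySeries]

    def __post_init__(self) -> None:
        if len(self.centroids) < 2:
            raise ValueError("need at least 2 groups to classify against")
        for g, c in self.centroids.items():
            if not c.is_daily:
                raise ValueError(f"centroid for group {g} is not a daily series")

    @property
    def group_ids(self) -> Tuple[int, ...]:
        return tuple(sorted(self.centroids))

    def as_matrix(self, days: Optional[np.ndarray] = None) -> np.ndarray:
        """(n_groups, n_days) value matrix, rows ordered by group id."""
        idx = slice(None) if days is None else np.asarray(days) - 1
        return np.stack([self.centroids[g].mfi[idx] for g in self.group_ids])


def compute_centroids(
    cohort: Sequence[TrajectorySeries], groups: Optional[Iterable[int]] = None
) -> CentroidSet:
    """Arithmetic per-day mean trajectory of each labelled group."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    keep = None if groups is None else set(groups)
    by_group: Dict[int, List[np.ndarray]] = {}
    for s in cohort:
        if s.group is None:
            raise ValueError(f"series {s.patient_id}/{s.dsa_label} is unlabelled")
        if not s.is_daily:
            raise ValueError(
                f"series {s.patient_id}/{s.dsa_label} is not daily; interpolate first"
            )
        if keep is None or s.group in keep:
            by_group.setdefault(s.group, []).append(s.mfi)
    if not by_group:
        raise ValueError("no series in the requested groups")
    cents = {
        g: TrajectorySeries(
            patient_id=f"centroid-{g}",
            dsa_label="total",
            days=FULL_GRID.copy(),
            mfi=np.mean(vals, axis=0),
            group=g,
        )
        for g, vals in by_group.items()
    }
    return CentroidSet(cents)


@njit(cache=True)
def _nearest_centroid(X: np.ndarray, C: np.ndarray) -> np.ndarray:  # pragma: no cover
    """Index of the DTW-nearest centroid row for each series row.

    Strict comparison keeps the first (lowest) index on exact ties, which
    with rows ordered by group id realises the smallest-group-id tie rule.
    """
    out = np.empty(X.shape[0], dtype=np.int64)
    for s in range(X.shape[0]):
        best = np.inf
        arg = 0
        for c in range(C.shape[0]):
            d = dtw_distance_fast(X[s], C[c])
            if d < best:
                best = d
                arg = c
        out[s] = arg
    return out


def classify(
    series: TrajectorySeries,
    centroids: CentroidSet,
    days: Optional[Iterable[int]] = None,
) -> int:
    """Assign one series to the group with the shortest DTW distance.

    Both the series and every centroid are reduced to ``days`` first
    (default: the series' own days).  Exact distance ties go to the
    smallest group id.
    """
    if days is None:
        day_arr = series.days
    else:
        day_arr = _validate_day_subset(days)
        series = series.restrict(day_arr)
    C = centroids.as_matrix(day_arr)
    idx = _nearest_centroid(series.mfi[None, :], C)[0]
    return centroids.group_ids[idx]


@dataclass
class ClassificationOutcome:
    """Predicted labels and the accuracy C = Ncp / Np * 100."""

    predictions: np.ndarray
    truths: np.ndarray
    days: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions)
        self.truths = np.asarray(self.truths)
        if self.predictions.size != self.truths.size:
            raise ValueError("predictions and truths lengths differ")
        if self.predictions.size == 0:
            raise ValueError("need at least one prediction")

    @property
    def ncp(self) -> int:
        """Number of correct predictions."""
        return int(np.sum(self.predictions == self.truths))

    @property
    def np_(self) -> int:
        """Number of all predictions."""
        return int(self.predictions.size)

    @property
    def accuracy(self) -> float:
        """Classification accuracy C in percent."""
        return self.ncp / self.np_ * 100.0

    def to_dict(self) -> dict:
        return {
            "Ncp": self.ncp,
            "Np": self.np_,
            "C": round(self.accuracy, 1),
            "days": list(self.days) if self.days is not None else None,
        }


def accuracy(
    predictions: Sequence[int], truths: Sequence[int]
) -> ClassificationOutcome:
    """Classification outcome from predicted and true group labels."""
    return ClassificationOutcome(np.asarray(predictions), np.asarray(truths))


class DsaPatternModel:
    """Nearest-centroid DTW pattern classifier over a labelled cohort.

    Parameters
    ----------
    cohort : sequence of TrajectorySeries
        Labelled series; sparse series are linearly interpolated onto the
        daily grid.
    include_group0 : bool
        Include the flat "no response" group in the classification
        universe (default False: groups 1-4 only, group 0 membership is
        assumed known from a low, flat MFI course).
    """

    def __init__(
        self, cohort: Sequence[TrajectorySeries], include_group0: bool = False
    ) -> None:
        universe = (0, 1, 2, 3, 4) if include_group0 else (1, 2, 3, 4)
        kept = []
        for s in cohort:
            if s.group is None:
                raise ValueError(f"series {s.patient_id}/{s.dsa_label} is unlabelled")
            if s.group not in universe:
                continue
            kept.append(s if s.is_daily else interpolate_daily(s))
        if not kept:
            raise ValueError("no labelled series in the classification universe")
        self.include_group0 = include_group0
        self.cohort: List[TrajectorySeries] = kept
        self.group_ids: Tuple[int, ...] = tuple(sorted({s.group for s in kept}))
        if len(self.group_ids) < 2:
            raise ValueError("need at least 2 groups to classify")
        self.X = np.stack([s.mfi for s in kept])  # (n_series, 50)
        self.y = np.array([s.group for s in kept])

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, include_group0: bool = False
    ) -> "DsaPatternModel":
        """Build from a long-format frame (patient_id, dsa_label, group, day, mfi)."""
        from .io import trajectories_from_frame

        return cls(trajectories_from_frame(df), include_group0=include_group0)

    def fit(self) -> "DsaPatternResults":
        """Compute group centroids and return the results object."""
        centroids = compute_centroids(self.cohort, groups=self.group_ids)
        return DsaPatternResults(self, centroids)


class DsaPatternResults:
    """Fitted centroids plus prediction, scoring and reporting."""

    def __init__(self, model: DsaPatternModel, centroids: CentroidSet) -> None:
        self.model = model
        self.centroids = centroids
        self._gids = np.array(centroids.group_ids)

    def predict(
        self,
        series: Union[TrajectorySeries, Sequence[TrajectorySeries], None] = None,
        days: Optional[Iterable[int]] = None,
    ) -> np.ndarray:
        """Predicted group id(s); default: the training cohort."""
        if isinstance(series, TrajectorySeries):
            return np.array([classify(series, self.centroids, days)])
        if series is None:
            X = self.model.X
        else:
            X = np.stack([
                (s if s.is_daily else interpolate_daily(s)).mfi for s in series
            ])
        day_arr = FULL_GRID if days is None else _validate_day_subset(days)
        idx = _nearest_centroid(
            np.ascontiguousarray(X[:, day_arr - 1]), self.centroids.as_matrix(day_arr)
        )
        return self._gids[idx]

    def score(
        self,
        days: Optional[Iterable[int]] = None,
        mode: str = "resubstitution",
    ) -> ClassificationOutcome:
        """Accuracy of the training cohort on a monitoring-day subset.

        ``mode="resubstitution"`` scores against the fitted centroids
        (each series contributes to its own group mean); ``mode="loo"``
        rebuilds the series' own-group centroid without it before
        classifying, for an honest generalisation estimate.
        """
        day_arr = FULL_GRID if days is None else _validate_day_subset(days)
        Xr = np.ascontiguousarray(self.model.X[:, day_arr - 1])
        if mode == "resubstitution":
            preds = self._gids[_nearest_centroid(Xr, self.centroids.as_matrix(day_arr))]
        elif mode == "loo":
            preds = self._score_loo(day_arr, Xr)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return ClassificationOutcome(preds, self.model.y, days=tuple(int(d) for d in day_arr))

    def _score_loo(self, day_arr: np.ndarray, Xr: np.ndarray) -> np.ndarray:
        y = self.model.y
        base = self.centroids.as_matrix(day_arr)
        sums = {g: Xr[y == g].sum(axis=0) for g in self._gids}
        counts = {g: int((y == g).sum()) for g in self._gids}
        preds = np.empty(y.size, dtype=np.int64)
        for i in range(y.size):
            g = y[i]
            if counts[g] < 2:
                raise ValueError(f"leave-one-out needs >= 2 members in group {g}")
            C = base.copy()
            row = int(np.searchsorted(self._gids, g))
            C[row] = (sums[g] - Xr[i]) / (counts[g] - 1)
            preds[i] = self._gids[_nearest_centroid(Xr[i : i + 1], C)[0]]
        return preds

    def summary(self) -> str:
        """Plain-text fit summary: group sizes, centroid levels, accuracy."""
        out = self.score()
        lines = [
            "DSA dynamic-pattern nearest-centroid DTW classifier",
            f"series: {self.model.y.size}   groups: {list(self.centroids.group_ids)}",
            f"resubstitution accuracy (all 50 days): C = {out.accuracy:.1f}% "
            f"(Ncp={out.ncp}, Np={out.np_})",
            "",
            f"{'group':>5} {'name':<18} {'n':>4} {'day-1 MFI':>10} {'peak MFI':>10} {'day-50 MFI':>11}",
        ]
        for g in self.centroids.group_ids:
            c = self.centroids.centroids[g].mfi
            n = int((self.model.y == g).sum())
            lines.append(
                f"{g:>5} {GROUP_NAMES[g]:<18} {n:>4} {c[0]:>10.0f} {c.max():>10.0f} {c[-1]:>11.0f}"
            )
        return "\n".join(lines)


def summarize_bands(
    counts: Union[pd.DataFrame, Mapping[str, Sequence[int]]],
) -> pd.DataFrame:
    """Per-band pattern percentages from a band-by-group count table.

    ``counts`` maps each baseline-MFI band to five non-negative integer
    counts (groups 0-4).  Returns per-group percentages (rounded to
    integers, half up) plus broader-category percentages computed from
    summed counts *before* rounding: no response = group 0, modulated =
    groups 1+2, sustained = groups 3+4.  Bands with zero total are
    flagged with NaN percentages and a warning.
    """
    if isinstance(counts, pd.DataFrame):
        table = counts.copy()
        table.columns = [int(c) for c in table.columns]
    else:
        table = pd.DataFrame.from_dict(
            {b: list(v) for b, v in counts.items()}, orient="index", columns=range(5)
        )
    arr = table.to_numpy(dtype=float)
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("counts must be non-negative integers")

    def _pct(x: np.ndarray, total: float) -> np.ndarray:
        return np.floor(x / total * 100.0 + 0.5)  # round half up

    rows = {}
    for band, row in zip(table.index, arr):
        total = row.sum()
        if total == 0:
            warnings.warn(f"band {band!r} has zero total; percentages undefined")
            rows[band] = [np.nan] * 8 + [0]
            continue
        pct = _pct(row, total)
        broader = _pct(
            np.array([row[0], row[1] + row[2], row[3] + row[4]]), total
        )
        rows[band] = list(pct) + list(broader) + [int(total)]
    cols = [f"pct_group{g}" for g in range(5)] + [
        "pct_no_response",
        "pct_modulated",
        "pct_sustained",
        "n_total",
    ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
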