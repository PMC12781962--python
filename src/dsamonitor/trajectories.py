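"""Trajectory containers and preprocessing for post-transplant DSA series.

A trajectory is one donor-specific antibody (DSA) — or the per-patient
total-DSA — observed as Luminex MFI values on integer days 1..50 after
transplantation.  Raw clinical sampling is irregular (near-daily for two
weeks, sparser later); the classifier consumes *daily* total-DSA series, so
this module provides per-DSA summation and linear interpolation onto the
daily grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

DAY_MIN = 1
DAY_MAX = 50
#: the daily grid days 1..50 every dense series lives on
FULL_GRID = np.arange(DAY_MIN, DAY_MAX + 1)

#: pattern-group ids: 0 no response, 1 fast modulation, 2 slow modulation,
#: 3 rise to sustained, 4 sustained
GROUP_IDS = (0, 1, 2, 3, 4)
GROUP_NAMES = {
    0: "no response",
    1: "fast modulation",
    2: "slow modulation",
    3: "rise to sustained",
    4: "sustained",
}


@dataclass
class TrajectorySeries:
    """One DSA (or total-DSA) time course.

    Parameters
    ----------
    patient_id : str
        Patient identifier.
    dsa_label : str
        DSA identifier, or ``"total"`` for the summed total-DSA series.
    days : ndarray of int
        Strictly increasing observation days in ``[1, 50]``.
    mfi : ndarray of float
        Non-negative MFI values, one per day.
    group : int, optional
        Dynamic-pattern label 0-4 if known.
    baseline_mfi : float, optional
        Pre-desensitisation (pre-transplant) MFI; a covariate used for
        band summaries, not part of the post-transplant time course.
    """

    patient_id: str
    dsa_label: str
    days: np.ndarray
    mfi: np.ndarray
    group: Optional[int] = None
    baseline_mfi: Optional[float] = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.mfi = np.asarray(self.mfi, dtype=np.float64)
        if self.days.ndim != 1 or self.mfi.ndim != 1:
            raise ValueError("days and mfi must be one-dimensional")
        if self.days.size == 0:
            raise ValueError("a trajectory needs at least one observation")
        if self.days.size != self.mfi.size:
            raise ValueError(
                f"days ({self.days.size}) and mfi ({self.mfi.size}) lengths differ"
            )
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.days[0] < DAY_MIN or self.days[-1] > DAY_MAX:
            raise ValueError(f"days must lie within [{DAY_MIN}, {DAY_MAX}]")
        if not np.all(np.isfinite(self.mfi)):
            raise ValueError("MFI values must be finite")
        if np.any(self.mfi < 0):
            raise ValueError("MFI values must be non-negative")
        if self.group is not None and self.group not in GROUP_IDS:
            raise ValueError(f"group must be one of {GROUP_IDS}, got {self.group!r}")

    @classmethod
    def from_observations(
        cls,
        patient_id: str,
        dsa_label: str,
        days: Sequence[int],
        mfi: Sequence[float],
        group: Optional[int] = None,
        baseline_mfi: Optional[float] = None,
    ) -> "TrajectorySeries":
        """Build a series from possibly unsorted observations.

        Duplicate measurements on the same day are averaged (order
        independent), then days are sorted.
        """
        days = np.asarray(days, dtype=np.int64)
        mfi = np.asarray(mfi, dtype=np.float64)
        if days.size != mfi.size:
            raise ValueError("days and mfi lengths differ")
        uniq, inverse = np.unique(days, return_inverse=True)
        sums = np.zeros(uniq.size)
        counts = np.zeros(uniq.size)
        np.add.at(sums, inverse, mfi)
        np.add.at(counts, inverse, 1.0)
        return cls(patient_id, dsa_label, uniq, sums / counts, group, baseline_mfi)

    @property
    def is_daily(self) -> bool:
        """True when the series covers every day 1..50."""
        return self.days.size == FULL_GRID.size and np.array_equal(self.days, FULL_GRID)

    def restrict(self, days: Iterable[int]) -> "TrajectorySeries":
        """Return the series restricted to exactly ``days`` (sorted).

        Every requested day must be observed; reduce a sparse series by
        interpolating to daily first.
        """
        wanted = _validate_day_subset(days)
        present = np.isin(wanted, self.days)
        if not present.all():
            missing = wanted[~present].tolist()
            raise ValueError(f"days {missing} not observed in series")
        idx = np.searchsorted(self.days, wanted)
        return replace(self, days=wanted, mfi=self.mfi[idx])

    def __len__(self) -> int:
        return int(self.days.size)


def _validate_day_subset(days: Iterable[int]) -> np.ndarray:
    arr = np.unique(np.asarray(list(days), dtype=np.int64))
    if arr.size == 0:
        raise ValueError("day subset must be non-empty")
    if arr[0] < DAY_MIN or arr[-1] > DAY_MAX:
        raise ValueError(
            f"days must lie within [{DAY_MIN}, {DAY_MAX}]; got range "
            f"[{arr[0]}, {arr[-1]}] (days are 1-based)"
        )
    return arr


def interpolate_daily(series: TrajectorySeries) -> TrajectorySeries:
    """Linearly interpolate a sparse series onto the daily grid 1..50.

    Observed days keep their exact values; interior gaps are filled
    linearly; days before the first / after the last observation are
    filled by constant extension of the nearest observed value (linear
    extrapolation could produce negative MFI).
    """
    if len(series) < 2:
        raise ValueError("interpolation needs at least 2 observed days")
    daily = np.interp(FULL_GRID, series.days, series.mfi)
    return replace(series, days=FULL_GRID.copy(), mfi=daily)


def sum_dsa(series_list: Sequence[TrajectorySeries]) -> TrajectorySeries:
    """Sum a patient's individual DSA series into a total-DSA series.

    The output is defined on the union of all observed days; any DSA
    missing a day contributes its linearly interpolated value there
    (constant extension outside its own observed range).
    """
    if len(series_list) == 0:
        raise ValueError("need at least one DSA series to sum")
    pids = {s.patient_id for s in series_list}
    if len(pids) != 1:
        raise ValueError(f"all series must share one patient_id, got {sorted(pids)}")
    union_days = np.unique(np.concatenate([s.days for s in series_list]))
    total = np.zeros(union_days.size)
    for s in series_list:
        total += np.interp(union_days, s.days, s.mfi)
    groups = {s.group for s in series_list}
    group = groups.pop() if len(groups) == 1 else None
    baselines = [s.baseline_mfi for s in series_list]
    baseline = sum(baselines) if all(b is not None for b in baselines) else None
    return TrajectorySeries(
        patient_id=series_list[0].patient_id,
        dsa_label="total",
        days=union_days,
        mfi=total,
        group=group,
        baseline_mfi=baseline,
    )


def total_dsa_daily(
    series_list: Sequence[TrajectorySeries],
    order: str = "interpolate-then-sum",
) -> TrajectorySeries:
    """Daily total-DSA series for one patient.

    ``order`` picks whether per-DSA series are interpolated to the daily
    grid before summing (default) or summed on the union of observed days
    and then interpolated.  On fully observed inputs both commute.
    """
    if order == "interpolate-then-sum":
        dailies = [interpolate_daily(s) if not s.is_daily else s for s in series_list]
        return sum_dsa(dailies)
    if order == "sum-then-interpolate":
        return interpolate_daily(sum_dsa(series_list))
    raise ValueError(f"unknown order {order!r}")


def apply_sampling_schedule(
    series: TrajectorySeries, schedule: Iterable[int]
) -> TrajectorySeries:
    """Restrict a series to the days of a monitoring schedule.

    Mirrors clinical sampling: only the scheduled days are retained, with
    values unchanged.  The schedule must be a non-empty subset of days
    1..50 that the series actually covers.
    """
    return series.restrict(schedule)
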