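"""Search for minimal DSA monitoring schedules.

Three stages mirror how an optimal day set is found:

1. *Section sweep* — days 1-50 are split into N contiguous sections and
   one day is taken per section (first, middle or random point); accuracy
   is recorded for N = 2..50 (random selection averaged over repeats).
2. *Greedy augmentation* — starting from a small promising subset
   (typically days {1, 26}), candidate days are added one at a time,
   keeping the best, until a size cap; replacement scans swap each base
   day against every candidate.
3. *Regimen comparison* — published clinical monitoring protocols are
   scored with the same classifier and ranked.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import ClassificationOutcome, DsaPatternModel, DsaPatternResults
from .trajectories import DAY_MAX, DAY_MIN, TrajectorySeries, _validate_day_subset

TOTAL_DAYS = DAY_MAX - DAY_MIN + 1

Cohort = Sequence[TrajectorySeries]
FitLike = Union[DsaPatternResults, Cohort]

STRATEGIES = ("random", "middle", "first")


def _as_results(fit: FitLike, include_group0: bool = False) -> DsaPatternResults:
    if isinstance(fit, DsaPatternResults):
        return fit
    return DsaPatternModel(fit, include_group0=include_group0).fit()


@dataclass(frozen=True)
class SectionScheme:
    """Division of days 1..50 into N contiguous sections.

    Splitting rule: the first N-1 sections have length ``floor(50/N)``
    and the last section absorbs the remainder — so N = 26 yields 25
    single-day sections followed by one 25-day section.
    """

    n_sections: int
    boundaries: Tuple[Tuple[int, int], ...]  # inclusive (start, end) intervals
    strategy: str = "first"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; one of {STRATEGIES}")
        covered = []
        for start, end in self.boundaries:
            covered.extend(range(start, end + 1))
        if covered != list(range(DAY_MIN, DAY_MAX + 1)):
            raise ValueError("sections must be ordered, disjoint and cover days 1..50")

    @property
    def section_lengths(self) -> Tuple[int, ...]:
        return tuple(end - start + 1 for start, end in self.boundaries)


def split_sections(n_sections: int, total_days: int = TOTAL_DAYS) -> Tuple[Tuple[int, int], ...]:
    """Section boundaries for splitting ``total_days`` into N sections."""
    if not (2 <= n_sections <= total_days):
        raise ValueError(f"N must lie in [2, {total_days}], got {n_sections}")
    base_len = total_days // n_sections
    boundaries = []
    start = DAY_MIN
    for _ in range(n_sections - 1):
        boundaries.append((start, start + base_len - 1))
        start += base_len
    boundaries.append((start, DAY_MIN + total_days - 1))
    return tuple(boundaries)


def select_days(
    boundaries: Sequence[Tuple[int, int]],
    strategy: str,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Pick one monitoring day per section.

    ``first`` takes the section's first day; ``middle`` the ceiling-middle
    day (a 25-day section yields its 13th day); ``random`` draws uniformly
    within each section (seeded).
    """
    if strategy == "first":
        return np.array([start for start, _ in boundaries])
    if strategy == "middle":
        return np.array(
            [start + math.ceil((end - start + 1) / 2) - 1 for start, end in boundaries]
        )
    if strategy == "random":
        if rng is None:
            rng = np.random.default_rng(seed)
        return np.array([int(rng.integers(start, end + 1)) for start, end in boundaries])
    raise ValueError(f"unknown strategy {strategy!r}; one of {STRATEGIES}")


def evaluate_subset(
    fit: FitLike,
    days: Iterable[int],
    mode: str = "resubstitution",
) -> ClassificationOutcome:
    """Classify the cohort using only the given monitoring days."""
    return _as_results(fit).score(days=days, mode=mode)


def sweep_sections(
    fit: FitLike,
    strategy: str,
    n_range: Iterable[int] = range(2, TOTAL_DAYS + 1),
    repeats: int = 100,
    seed: int = 0,
    mode: str = "resubstitution",
) -> pd.DataFrame:
    """Accuracy of section-based day selection for each N.

    Deterministic strategies (first, middle) are evaluated once; the
    random strategy draws one day per section independently per repeat
    (substreams spawned from ``seed``) and reports the mean accuracy.
    Returns a frame indexed by N with columns ``accuracy`` (mean C, %),
    ``sd`` and ``days`` (the last repeat's selection).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; one of {STRATEGIES}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    results = _as_results(fit)
    eff_repeats = repeats if strategy == "random" else 1
    rows = {}
    for n in n_range:
        boundaries = split_sections(n)
        accs = np.empty(eff_repeats)
        rngs = np.random.default_rng(seed).spawn(eff_repeats)
        days = None
        for r in range(eff_repeats):
            days = select_days(boundaries, strategy, rng=rngs[r])
            accs[r] = results.score(days=days, mode=mode).accuracy
        rows[n] = {
            "accuracy": accs.mean(),
            "sd": accs.std(ddof=1) if eff_repeats > 1 else 0.0,
            "days": ",".join(str(d) for d in days),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "N"
    return df


@dataclass
class GreedyStep:
    """One augmentation step: every candidate addition, ranked by accuracy."""

    ranking: List[Tuple[Tuple[int, ...], float]]  # (days, C) best first

    @property
    def best(self) -> Tuple[Tuple[int, ...], float]:
        return self.ranking[0]


@dataclass
class GreedySearchResult:
    """Greedy schedule search output.

    ``steps`` holds the per-step candidate rankings; ``best_subset`` /
    ``best_accuracy`` the final selection; ``replacements`` maps each base
    day to the ranked outcomes of swapping it for each candidate.
    """

    base: Tuple[int, ...]
    steps: List[GreedyStep]
    best_subset: Tuple[int, ...]
    best_accuracy: float
    replacements: Dict[int, List[Tuple[Tuple[int, ...], float]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, step in enumerate(self.steps, start=1):
            for days, acc in step.ranking:
                rows.append({"step": k, "days": ",".join(map(str, days)), "C": acc})
        return pd.DataFrame(rows)


def greedy_augment(
    fit: FitLike,
    base: Iterable[int] = (1, 26),
    candidate_days: Optional[Iterable[int]] = None,
    max_size: int = 5,
    mode: str = "resubstitution",
) -> GreedySearchResult:
    """Greedily add monitoring days to a base subset.

    At each step every candidate day is appended to the current subset
    and scored; the best (ties to the smaller day) is kept.  A day is
    only added if it does not reduce accuracy.  Replacement scans swap
    each base day against every candidate while keeping the rest fixed.
    """
    results = _as_results(fit)
    base_days = tuple(int(d) for d in _validate_day_subset(base))
    if max_size < len(base_days):
        raise ValueError("max_size must be >= len(base)")
    if candidate_days is None:
        candidate_days = range(DAY_MIN, DAY_MAX + 1)
    candidates = [int(d) for d in _validate_day_subset(candidate_days)]
    if not candidates:
        raise ValueError("candidate set must be non-empty")

    def score(days: Tuple[int, ...]) -> float:
        return results.score(days=days, mode=mode).accuracy

    current = base_days
    current_acc = score(current)
    steps: List[GreedyStep] = []
    while len(current) < max_size:
        ranking = []
        for d in candidates:
            days = tuple(sorted(set(current) | {d}))
            ranking.append((days, score(days) if d not in current else current_acc))
        # best accuracy first; ties broken toward the smaller added day
        ranking.sort(key=lambda t: (-t[1], t[0]))
        steps.append(GreedyStep(ranking))
        best_days, best_acc = ranking[0]
        if best_days == current or best_acc < current_acc:
            break
        if len(best_days) == len(current):  # every candidate already present
            break
        current, current_acc = best_days, best_acc

    replacements: Dict[int, List[Tuple[Tuple[int, ...], float]]] = {}
    for day in base_days:
        scan = []
        rest = set(current) - {day}
        for d in candidates:
            days = tuple(sorted(rest | {d}))
            scan.append((days, score(days)))
        scan.sort(key=lambda t: (-t[1], t[0]))
        replacements[day] = scan

    return GreedySearchResult(
        base=base_days,
        steps=steps,
        best_subset=current,
        best_accuracy=current_acc,
        replacements=replacements,
    )


def exhaustive_search(
    fit: FitLike,
    candidate_days: Iterable[int],
    max_size: int = 5,
    must_include: Iterable[int] = (),
    mode: str = "resubstitution",
    top: int = 20,
) -> pd.DataFrame:
    """Score every subset of candidates up to ``max_size`` (slow; opt-in).

    Returns the ``top`` subsets ranked by accuracy.  Combinatorial cost
    grows as C(n, k); keep the candidate pool small.
    """
    results = _as_results(fit)
    candidates = [int(d) for d in _validate_day_subset(candidate_days)]
    fixed = tuple(int(d) for d in sorted(set(must_include)))
    pool = [d for d in candidates if d not in fixed]
    rows = []
    for k in range(max(1, len(fixed)), max_size + 1):
        for combo in itertools.combinations(pool, k - len(fixed)):
            days = tuple(sorted(fixed + combo))
            if not days:
                continue
            rows.append(
                {"days": ",".join(map(str, days)), "size": len(days),
                 "C": results.score(days=days, mode=mode).accuracy}
            )
    df = pd.DataFrame(rows).sort_values(["C", "size"], ascending=[False, True])
    return df.head(top).reset_index(drop=True)


@dataclass(frozen=True)
class Regimen:
    """A named clinical monitoring schedule to be scored."""

    name: str
    days: Tuple[int, ...]
    source: str = ""

    def __post_init__(self) -> None:
        try:
            arr = _validate_day_subset(self.days)
        except ValueError as exc:
            raise ValueError(f"regimen {self.name!r}: {exc}") from exc
        object.__setattr__(self, "days", tuple(int(d) for d in arr))


#: published monitoring protocols (regimens beyond day 50 excluded)
BUILTIN_REGIMENS: Tuple[Regimen, ...] = (
    Regimen("A", tuple(range(1, 15)) + (17, 18, 20, 22, 27, 30), source="centre A"),
    Regimen("B", (1, 8, 15, 22), source="centre B"),
    Regimen("C", (1, 7, 30), source="centre C"),
    Regimen("D", (4, 7, 14, 30), source="centre D"),
    Regimen("E", (1, 2, 3) + (7, 14, 21, 28), source="centre E"),
    Regimen("F", (1, 10, 26), source="proposed (day 34 variant: 1,10,34)"),
    Regimen("F'", (1, 10, 34), source="proposed variant"),
    Regimen("G", (1, 10, 26, 34), source="proposed"),
)


def compare_regimens(
    fit: FitLike,
    regimens: Optional[Sequence[Regimen]] = None,
    mode: str = "resubstitution",
) -> pd.DataFrame:
    """Score monitoring regimens and rank them by accuracy (descending)."""
    results = _as_results(fit)
    if regimens is None:
        regimens = BUILTIN_REGIMENS
    names = [r.name for r in regimens]
    if len(set(names)) != len(names):
        warnings.warn("duplicate regimen names; all will be scored")
    rows = []
    for r in regimens:
        try:
            out = results.score(days=r.days, mode=mode)
        except ValueError as exc:
            raise ValueError(f"regimen {r.name!r}: {exc}") from exc
        rows.append(
            {"name": r.name, "days": ",".join(map(str, r.days)),
             "n_days": len(r.days), "C": out.accuracy, "Ncp": out.ncp, "Np": out.np_}
        )
    df = pd.DataFrame(rows).sort_values("C", ascending=False, kind="stable")
    return df.reset_index(drop=True)
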