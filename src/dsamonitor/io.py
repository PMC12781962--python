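"""Long-format CSV I/O, run configuration and the end-to-end experiment.

Trajectories travel as long-format CSV with columns ``patient_id,
dsa_label, group, day, mfi`` (plus an optional ``baseline_mfi``); the same
layout accepts spreadsheet-exported clinical data.  MFI is written with at
most two decimals — Luminex precision beyond that carries no clinical
meaning.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import schedule as sched
from .model import DsaPatternModel
from .simulate import CohortConfig, generate_cohort
from .trajectories import (
    DAY_MAX,
    DAY_MIN,
    TrajectorySeries,
    interpolate_daily,
    sum_dsa,
)

CSV_COLUMNS = ("patient_id", "dsa_label", "group", "day", "mfi")


def trajectories_to_frame(cohort: Sequence[TrajectorySeries]) -> pd.DataFrame:
    """Long-format frame (one row per observation) from a cohort."""
    rows = []
    any_baseline = any(s.baseline_mfi is not None for s in cohort)
    for s in cohort:
        for d, v in zip(s.days, s.mfi):
            row = {
                "patient_id": s.patient_id,
                "dsa_label": s.dsa_label,
                "group": "" if s.group is None else int(s.group),
                "day": int(d),
                "mfi": round(float(v), 2),
            }
            if any_baseline:
                row["baseline_mfi"] = (
                    "" if s.baseline_mfi is None else round(float(s.baseline_mfi), 2)
                )
            rows.append(row)
    cols = list(CSV_COLUMNS) + (["baseline_mfi"] if any_baseline else [])
    return pd.DataFrame(rows, columns=cols)


def write_trajectories(cohort: Sequence[TrajectorySeries], path: Union[str, Path]) -> None:
    """Write a cohort as long-format CSV."""
    trajectories_to_frame(cohort).to_csv(path, index=False)


def trajectories_from_frame(df: pd.DataFrame) -> List[TrajectorySeries]:
    """Parse a long-format frame into per-(patient, DSA) series."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out: List[TrajectorySeries] = []
    if df.empty:
        return out
    work = df.copy()
    # validate row-wise so errors can name the offending row
    for col, kind in (("day", "integer day"), ("mfi", "numeric mfi")):
        vals = pd.to_numeric(work[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ValueError(f"row {bad[0]}: non-{kind.split()[0]} {col} value {work[col][bad[0]]!r}")
        work[col] = vals
    bad_day = work.index[(work["day"] < DAY_MIN) | (work["day"] > DAY_MAX)]
    if len(bad_day):
        r = bad_day[0]
        raise ValueError(
            f"row {r}: day {int(work['day'][r])} outside [{DAY_MIN}, {DAY_MAX}]"
        )
    has_baseline = "baseline_mfi" in work.columns
    for (pid, label), grp in work.groupby(["patient_id", "dsa_label"], sort=True):
        gvals = grp["group"].dropna().unique()
        gvals = [g for g in gvals if str(g) != ""]
        group = int(gvals[0]) if len(gvals) else None
        baseline = None
        if has_baseline:
            bvals = pd.to_numeric(grp["baseline_mfi"], errors="coerce").dropna()
            baseline = float(bvals.iloc[0]) if len(bvals) else None
        out.append(
            TrajectorySeries.from_observations(
                str(pid), str(label), grp["day"].to_numpy(), grp["mfi"].to_numpy(),
                group=group, baseline_mfi=baseline,
            )
        )
    return out


def read_trajectories(path: Union[str, Path]) -> List[TrajectorySeries]:
    """Read a long-format CSV of trajectories."""
    df = pd.read_csv(path)
    return trajectories_from_frame(df)


@dataclasses.dataclass
class RunConfig:
    """Configuration of the full three-stage schedule experiment.

    Exactly one cohort source: a synthetic-cohort configuration or a CSV
    path.  All randomness derives from ``master_seed``.
    """

    cohort: Optional[CohortConfig] = None
    cohort_csv: Optional[str] = None
    include_group0: bool = False
    mode: str = "resubstitution"
    repeats: int = 100
    base_days: Tuple[int, ...] = (1, 26)
    max_days: int = 5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.cohort_csv is None):
            raise ValueError("exactly one of cohort / cohort_csv must be set")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            if "seed" not in cohort:
                raise ValueError("cohort config requires an explicit seed")
            if "sampling_schedule" in cohort:
                cohort["sampling_schedule"] = tuple(cohort["sampling_schedule"])
            if "groups" in cohort:
                cohort["groups"] = tuple(cohort["groups"])
            cohort = CohortConfig(**cohort)
        if "base_days" in raw:
            raw["base_days"] = tuple(raw["base_days"])
        return cls(cohort=cohort, **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            c = dataclasses.asdict(self.cohort)
            c["sampling_schedule"] = list(self.cohort.sampling_schedule)
            c["groups"] = list(self.cohort.groups)
            if c["mfi_band_mixing"] is not None:
                c["mfi_band_mixing"] = {k: list(v) for k, v in c["mfi_band_mixing"].items()}
            d["cohort"] = c
        d["base_days"] = list(self.base_days)
        return d


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_full_experiment(config: RunConfig, outdir: Union[str, Path]) -> dict:
    """Run the three-stage monitoring-day experiment and write reports.

    Stage 1 sweeps section-based day selection (all three strategies);
    stage 2 greedily augments the base day pair; stage 3 scores the
    built-in clinical regimen catalogue.  Outputs (under ``outdir``):
    ``cohort.csv``, ``stage1_accuracy.csv``, ``stage2_greedy.json``,
    ``stage3_regimens.csv`` and ``report.json`` embedding the full
    configuration.  Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.cohort is not None:
        cohort = generate_cohort(config.cohort)
    else:
        cohort = read_trajectories(config.cohort_csv)

    # preprocess: per-DSA sum then daily interpolation
    by_patient: Dict[str, List[TrajectorySeries]] = {}
    for s in cohort:
        by_patient.setdefault(s.patient_id, []).append(s)
    daily = []
    for pid in sorted(by_patient):
        series = by_patient[pid]
        total = series[0] if len(series) == 1 else sum_dsa(
            [interpolate_daily(x) if not x.is_daily else x for x in series]
        )
        daily.append(total if total.is_daily else interpolate_daily(total))
    write_trajectories(daily, outdir / "cohort.csv")

    results = DsaPatternModel(daily, include_group0=config.include_group0).fit()

    # stage 1: section sweep, three selection strategies
    frames = []
    for strategy in sched.STRATEGIES:
        df = sched.sweep_sections(
            results, strategy, repeats=config.repeats,
            seed=config.master_seed, mode=config.mode,
        )
        df["strategy"] = strategy
        frames.append(df.reset_index())
    stage1 = pd.concat(frames, ignore_index=True)
    stage1.to_csv(outdir / "stage1_accuracy.csv", index=False)

    # stage 2: greedy augmentation from the base day pair
    greedy = sched.greedy_augment(
        results, base=config.base_days, max_size=config.max_days, mode=config.mode
    )
    stage2 = {
        "base": list(greedy.base),
        "best_subset": list(greedy.best_subset),
        "best_accuracy": round(greedy.best_accuracy, 1),
        "steps": [
            [[list(d), round(c, 1)] for d, c in step.ranking[:10]]
            for step in greedy.steps
        ],
        "replacements": {
            str(day): [[list(d), round(c, 1)] for d, c in scan[:10]]
            for day, scan in greedy.replacements.items()
        },
    }
    _write_json(stage2, outdir / "stage2_greedy.json")

    # stage 3: clinical regimen comparison
    stage3 = sched.compare_regimens(results, mode=config.mode)
    stage3.to_csv(outdir / "stage3_regimens.csv", index=False)

    stage1_best = {}
    for s in sched.STRATEGIES:
        sub = stage1[stage1.strategy == s]
        row = sub.loc[sub["accuracy"].idxmax()]
        stage1_best[s] = {"N": int(row["N"]), "accuracy": round(float(row["accuracy"]), 1)}

    report = {
        "config": config.to_jsonable(),
        "n_series": len(daily),
        "full_series_accuracy": round(results.score().accuracy, 1),
        "stage1_best": stage1_best,
        "stage2_best_subset": list(greedy.best_subset),
        "stage2_best_accuracy": round(greedy.best_accuracy, 1),
        "stage3_ranking": [
            {"name": r["name"], "days": r["days"], "C": round(r["C"], 1)}
            for r in stage3.to_dict(orient="records")
        ],
    }
    _write_json(report, outdir / "report.json")
    return report
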