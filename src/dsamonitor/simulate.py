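"""Synthetic cohorts of post-transplant DSA trajectories.

After HLA-incompatible kidney transplantation, early (day 1-50) total-DSA
MFI time courses fall into five dynamic patterns:

======  ====================  ==========================================
group   name                  noiseless shape used here
======  ====================  ==========================================
0       no response           constant low baseline
1       fast modulation       gamma pulse, early peak, resolves ~day 30
2       slow modulation       gamma pulse, later peak, resolves ~day 50
3       rise to sustained     saturating exponential rise to a plateau
4       sustained             high plateau with mild exponential drift
======  ====================  ==========================================

The modulated pulse is ``b + A (t/tp)^k exp(k (1 - t/tp))`` with the peak
at day ``tp`` and shape ``k = decay_rate * tp`` (the pulse's asymptotic
log-decay rate equals ``decay_rate``).  Default amplitudes and plateaus
are solved so each group's noiseless time average over days 1-50 matches
the published per-group average total-DSA (2062 / 7023 / 7105 / 14813 /
12674 MFI).  Measurement noise is multiplicative lognormal per time
point, as appropriate for a positive semi-quantitative assay; pattern
probabilities per pre-desensitisation MFI band follow the published
band-by-group cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .trajectories import (
    DAY_MAX,
    DAY_MIN,
    FULL_GRID,
    GROUP_IDS,
    TrajectorySeries,
    _validate_day_subset,
    apply_sampling_schedule,
)

#: published per-group average total-DSA MFI (groups 0..4)
GROUP_MEAN_TDSA = {0: 2062.0, 1: 7023.0, 2: 7105.0, 3: 14813.0, 4: 12674.0}

#: pre-desensitisation MFI band -> per-group DSA counts (groups 0..4);
#: the published band-by-pattern cross-tabulation
MFI_BAND_COUNTS: Dict[str, Tuple[int, ...]] = {
    "<2500": (64, 24, 21, 2, 3),
    "2500-5000": (5, 7, 14, 6, 5),
    "5000-10000": (3, 10, 6, 19, 10),
    ">10000": (0, 0, 2, 1, 7),
}

#: MFI range each band spans, used to draw a baseline value within a band
MFI_BAND_RANGES: Dict[str, Tuple[float, float]] = {
    "<2500": (200.0, 2500.0),
    "2500-5000": (2500.0, 5000.0),
    "5000-10000": (5000.0, 10000.0),
    ">10000": (10000.0, 25000.0),
}

BAND_LABELS = tuple(MFI_BAND_COUNTS)

#: default monitoring schedule: near-daily for two weeks, alternate days
#: to day 28, then sparse to day 50
DEFAULT_SCHEDULE: Tuple[int, ...] = tuple(
    list(range(1, 15)) + list(range(16, 29, 2)) + [31, 34, 38, 42, 46, 50]
)


def band_of(baseline_mfi: float) -> str:
    """Band label for a pre-desensitisation MFI value."""
    if baseline_mfi < 2500:
        return "<2500"
    if baseline_mfi < 5000:
        return "2500-5000"
    if baseline_mfi <= 10000:
        return "5000-10000"
    return ">10000"


@dataclass(frozen=True)
class PatternParams:
    """Parameters of one noiseless pattern curve.

    Units: MFI for levels/amplitudes, days for ``peak_day``, 1/day for
    rates.  Which fields matter depends on the group: the baseline for
    group 0; baseline, amplitude, peak day and decay rate for the
    modulated groups 1-2; baseline, plateau and rise rate for group 3;
    plateau and (drift) decay rate for group 4.
    """

    group: int
    baseline_mfi: float
    peak_amplitude: float = 0.0
    peak_day: float = 12.0
    rise_rate: float = 0.0
    decay_rate: float = 0.0
    plateau_level: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUP_IDS:
            raise ValueError(f"invalid group id {self.group!r}; must be one of {GROUP_IDS}")
        if self.baseline_mfi < 0 or self.peak_amplitude < 0 or self.plateau_level < 0:
            raise ValueError("MFI levels and amplitudes must be non-negative")
        if self.group in (1, 2):
            if not (DAY_MIN <= self.peak_day <= DAY_MAX):
                raise ValueError(
                    f"peak_day must lie within [{DAY_MIN}, {DAY_MAX}], got {self.peak_day}"
                )
            if self.decay_rate <= 0:
                raise ValueError("modulated groups (1, 2) require decay_rate > 0")
        if self.group == 3 and self.rise_rate <= 0:
            raise ValueError("rise-to-sustained (group 3) requires rise_rate > 0")


def _pulse(t: np.ndarray, tp: float, k: float) -> np.ndarray:
    # unit-peak gamma pulse: max 1 at t == tp
    return (t / tp) ** k * np.exp(k * (1.0 - t / tp))


def pattern_curve(params: PatternParams, days: Optional[np.ndarray] = None) -> np.ndarray:
    """Evaluate the noiseless parametric curve on ``days`` (default 1..50)."""
    t = FULL_GRID.astype(float) if days is None else np.asarray(days, dtype=float)
    g = params.group
    if g == 0:
        return np.full(t.size, params.baseline_mfi)
    if g in (1, 2):
        k = params.decay_rate * params.peak_day
        return params.baseline_mfi + params.peak_amplitude * _pulse(t, params.peak_day, k)
    if g == 3:
        span = params.plateau_level - params.baseline_mfi
        return params.baseline_mfi + span * (1.0 - np.exp(-params.rise_rate * t))
    # group 4: high plateau with mild exponential drift
    return params.plateau_level * np.exp(-params.decay_rate * (t - 1.0))


# baseline levels and time constants of the default group shapes;
# amplitudes/plateaus are solved below from the published group means
_DEFAULT_SHAPE = {
    0: dict(baseline=GROUP_MEAN_TDSA[0]),
    1: dict(baseline=1200.0, peak_day=12.0, decay_rate=1.0 / 3.0),
    2: dict(baseline=1500.0, peak_day=18.0, decay_rate=1.0 / 6.0),
    3: dict(baseline=2500.0, rise_rate=0.15),
    4: dict(decay_rate=0.001),
}


def default_params(group: int) -> PatternParams:
    """Default parameters for a pattern group.

    The free scale (pulse amplitude or plateau) is solved so the
    noiseless curve's mean over days 1-50 equals the group's published
    average total-DSA.
    """
    if group not in GROUP_IDS:
        raise ValueError(f"invalid group id {group!r}; must be one of {GROUP_IDS}")
    target = GROUP_MEAN_TDSA[group]
    s = _DEFAULT_SHAPE[group]
    if group == 0:
        return PatternParams(group=0, baseline_mfi=s["baseline"])
    if group in (1, 2):
        tp, dr, b = s["peak_day"], s["decay_rate"], s["baseline"]
        mean_factor = _pulse(FULL_GRID.astype(float), tp, dr * tp).mean()
        amp = (target - b) / mean_factor
        return PatternParams(
            group=group,
            baseline_mfi=b,
            peak_amplitude=amp,
            peak_day=tp,
            rise_rate=dr,
            decay_rate=dr,
        )
    if group == 3:
        b, rr = s["baseline"], s["rise_rate"]
        mean_factor = (1.0 - np.exp(-rr * FULL_GRID.astype(float))).mean()
        plateau = b + (target - b) / mean_factor
        return PatternParams(
            group=3,
            baseline_mfi=b,
            peak_amplitude=plateau - b,
            rise_rate=rr,
            plateau_level=plateau,
        )
    dr = s["decay_rate"]
    mean_factor = np.exp(-dr * (FULL_GRID.astype(float) - 1.0)).mean()
    plateau = target / mean_factor
    return PatternParams(
        group=4, baseline_mfi=plateau, decay_rate=dr, plateau_level=plateau
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _jitter_factor(rng: np.random.Generator, cv: float) -> float:
    """Between-patient parameter multiplier: lognormal, truncated at 2 sigma.

    Truncation reflects that cluster membership bounds a member's scale —
    an extreme trajectory would have been assigned to a different
    cluster, so within-group heterogeneity has no far tails.
    """
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
    return float(np.exp(-0.5 * sigma * sigma + sigma * z))


def generate_trajectory(
    params: PatternParams,
    noise_cv: float = 0.0,
    seed: Optional[int] = None,
    patient_id: str = "P000",
    dsa_label: str = "total",
    rng: Optional[np.random.Generator] = None,
) -> TrajectorySeries:
    """One daily (days 1..50) trajectory from pattern parameters.

    With ``noise_cv = 0`` the series is the noiseless parametric curve;
    otherwise each day's value is multiplied by an independent lognormal
    factor with unit mean and coefficient of variation ``noise_cv``.
    Deterministic given ``seed`` (or an explicit ``rng``).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    curve = pattern_curve(params)
    if noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        curve = curve * _lognormal_factor(rng, noise_cv, size=curve.size)
    return TrajectorySeries(
        patient_id=patient_id,
        dsa_label=dsa_label,
        days=FULL_GRID.copy(),
        mfi=np.maximum(curve, 0.0),
        group=params.group,
    )


def _normalise_mixing(
    mixing: Optional[Mapping[str, Sequence[float]]],
) -> Dict[str, np.ndarray]:
    """Per-band pattern probabilities; default from the published counts.

    User-supplied rows are percentages and must sum to 100 +- 1 (printed
    tables carry integer rounding).
    """
    if mixing is None:
        rows = {b: np.asarray(c, dtype=float) for b, c in MFI_BAND_COUNTS.items()}
        return {b: r / r.sum() for b, r in rows.items()}
    out = {}
    for band, row in mixing.items():
        r = np.asarray(row, dtype=float)
        if r.size != 5 or np.any(r < 0):
            raise ValueError(f"band {band!r}: need 5 non-negative percentages")
        if abs(r.sum() - 100.0) > 1.0:
            raise ValueError(
                f"band {band!r}: percentages sum to {r.sum():g}, expected 100 +- 1"
            )
        out[band] = r / r.sum()
    return out


def sample_patterns_for_band(
    band: str,
    n: int,
    rng: np.random.Generator,
    mixing: Optional[Mapping[str, Sequence[float]]] = None,
) -> np.ndarray:
    """Draw ``n`` pattern-group labels for DSAs in one baseline-MFI band."""
    probs = _normalise_mixing(mixing)
    if band not in probs:
        raise ValueError(f"unknown band {band!r}; known: {sorted(probs)}")
    return rng.choice(np.arange(5), size=n, p=probs[band])


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``n_per_group`` trajectories are generated for each group in
    ``groups`` (or, with band mixing enabled, ``n_per_group * len(groups)``
    trajectories with bands drawn first and patterns per band row).
    ``amplitude_cv``, ``plateau_cv``, ``baseline_cv`` and ``peak_day_sd``
    set the between-patient heterogeneity of the pattern parameters;
    ``noise_cv`` the per-time-point measurement noise.  The sustained
    plateaus (groups 3-4) get a tighter spread than the modulated pulse
    amplitudes because the two sustained cluster levels sit only ~15%
    apart — larger within-group spread would contradict the full-series
    clustering that defines the labels.
    """

    n_per_group: int
    seed: int
    noise_cv: float = 0.15
    groups: Tuple[int, ...] = GROUP_IDS
    mfi_band_mixing: Optional[Mapping[str, Sequence[float]]] = None
    use_band_mixing: bool = False
    sampling_schedule: Tuple[int, ...] = DEFAULT_SCHEDULE
    amplitude_cv: float = 0.12
    plateau_cv: float = 0.06
    baseline_cv: float = 0.15
    peak_day_sd: float = 1.5
    split_dsas: bool = False

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        bad = set(self.groups) - set(GROUP_IDS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}")
        sched = _validate_day_subset(self.sampling_schedule)
        if sched[0] != DAY_MIN or sched[-1] != DAY_MAX:
            raise ValueError(
                "sampling_schedule must contain day 1 and day 50 "
                "(interpolation anchors)"
            )
        self.sampling_schedule = tuple(int(d) for d in sched)


def _jitter_params(
    base: PatternParams, config: CohortConfig, rng: np.random.Generator
) -> PatternParams:
    """Draw one patient's parameters around the group defaults."""
    g = base.group
    b = base.baseline_mfi * _jitter_factor(rng, config.baseline_cv)
    if g == 0:
        return PatternParams(group=0, baseline_mfi=b)
    if g in (1, 2):
        amp = base.peak_amplitude * _jitter_factor(rng, config.amplitude_cv)
        tp = base.peak_day + rng.normal(0.0, config.peak_day_sd)
        tp = float(np.clip(round(tp), base.peak_day - 3, base.peak_day + 3))
        return PatternParams(
            group=g,
            baseline_mfi=b,
            peak_amplitude=amp,
            peak_day=tp,
            rise_rate=base.rise_rate,
            decay_rate=base.decay_rate,
        )
    if g == 3:
        plateau = base.plateau_level * _jitter_factor(rng, config.plateau_cv)
        return PatternParams(
            group=3,
            baseline_mfi=b,
            peak_amplitude=plateau - b,
            rise_rate=base.rise_rate,
            plateau_level=plateau,
        )
    plateau = base.plateau_level * _jitter_factor(rng, config.plateau_cv)
    return PatternParams(
        group=4, baseline_mfi=plateau, decay_rate=base.decay_rate, plateau_level=plateau
    )


#: how many DSAs a patient carries (1..7, median ~2-3 as observed clinically)
_N_DSA_PROBS = np.array([0.25, 0.30, 0.20, 0.12, 0.07, 0.04, 0.02])


def _draw_baseline_in_band(band: str, rng: np.random.Generator) -> float:
    lo, hi = MFI_BAND_RANGES[band]
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _band_conditional_on_group(group: int) -> np.ndarray:
    counts = np.array([MFI_BAND_COUNTS[b][group] for b in BAND_LABELS], dtype=float)
    return counts / counts.sum()


def generate_cohort(config: CohortConfig) -> List[TrajectorySeries]:
    """Generate a labelled synthetic cohort.

    Returns one series per patient sampled on ``config.sampling_schedule``
    (per-DSA series when ``split_dsas``).  Reproducible: identical configs
    produce identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    mixing = _normalise_mixing(config.mfi_band_mixing)
    band_weights = np.array([sum(MFI_BAND_COUNTS[b]) for b in BAND_LABELS], dtype=float)
    band_weights /= band_weights.sum()

    n_total = config.n_per_group * len(config.groups)
    assignments: List[Tuple[int, str]] = []  # (group, band) per patient
    if config.use_band_mixing or config.mfi_band_mixing is not None:
        for _ in range(n_total):
            band = BAND_LABELS[rng.choice(len(BAND_LABELS), p=band_weights)]
            group = int(rng.choice(np.arange(5), p=mixing[band]))
            assignments.append((group, band))
    else:
        for g in config.groups:
            for _ in range(config.n_per_group):
                band = BAND_LABELS[rng.choice(4, p=_band_conditional_on_group(g))]
                assignments.append((g, band))

    cohort: List[TrajectorySeries] = []
    for i, (group, band) in enumerate(assignments):
        pid = f"P{i + 1:03d}"
        params = _jitter_params(default_params(group), config, rng)
        baseline = _draw_baseline_in_band(band, rng)
        total = generate_trajectory(
            params, noise_cv=0.0, patient_id=pid, dsa_label="total", rng=rng
        )
        if not config.split_dsas:
            noisy = total.mfi * _lognormal_factor(rng, config.noise_cv, size=total.mfi.size)
            series = TrajectorySeries(
                pid, "total", FULL_GRID.copy(), np.maximum(noisy, 0.0),
                group=group, baseline_mfi=baseline,
            )
            cohort.append(apply_sampling_schedule(series, config.sampling_schedule))
        else:
            n_dsa = int(rng.choice(np.arange(1, 8), p=_N_DSA_PROBS))
            props = rng.dirichlet(np.full(n_dsa, 2.0))
            for d in range(n_dsa):
                comp = total.mfi * props[d]
                comp = comp * _lognormal_factor(rng, config.noise_cv, size=comp.size)
                series = TrajectorySeries(
                    pid, f"DSA{d + 1}", FULL_GRID.copy(), np.maximum(comp, 0.0),
                    group=group, baseline_mfi=baseline * props[d],
                )
                cohort.append(apply_sampling_schedule(series, config.sampling_schedule))
    return cohort
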