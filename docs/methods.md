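# Methods

## Data model

A trajectory is one DSA (or a patient's total-DSA) measured as Luminex
MFI — a semi-quantitative, strictly positive antibody level — on integer
days 1..50 after transplantation. Clinical sampling is irregular
(near-daily for two weeks, alternate days to ~day 28, sparse to day 50),
so preprocessing (i) sums a patient's individual DSA series into a
total-DSA series and (ii) linearly interpolates onto the daily grid.
Design choices where the procedure was open:

- **Edge handling.** Outside the observed range, values are extended as a
  constant (nearest observation) rather than extrapolated linearly;
  linear extrapolation can go negative, which is meaningless for MFI.
  Interpolated values never leave the observed [min, max] of a series.
- **Order of operations.** Interpolate-per-DSA-then-sum is the default;
  sum-then-interpolate is provided (`total_dsa_daily(order=...)`). On
  fully observed inputs the two commute.
- **Duplicates.** Repeated measurements on one day are averaged before
  interpolation (symmetric, order-independent).
- **No positivity threshold.** The analysis concerns trends, not
  laboratory positivity calls, so no MFI cut-off is applied.

## Classifier

Per-group centroids are arithmetic per-day means of the labelled daily
series. A series reduced to a monitoring-day subset is assigned to the
group whose equally reduced centroid minimises the DTW distance;
accuracy is `C = Ncp/Np × 100`.

DTW specifics (the variant was an open choice; these are this package's
declared defaults, selectable where noted):

- local cost `|a_i − b_j|` (squared difference available);
- no warping window — series are ≤ 50 points, the full matrix is cheap;
- no path-length normalisation by default: compared series and centroids
  always have equal length, so normalisation cannot change
  nearest-centroid rankings (still exposed as an option);
- ties among equal-cost warping steps prefer the diagonal — this affects
  the reported path, never the distance;
- exact distance ties between centroids go to the smallest group id.

The dynamic-programming implementation is verified against an exhaustive
path-enumeration oracle on short random sequences. A numba-compiled
distance-only kernel drives the batch classifier; the public
`dtw_distance` also returns the optimal path.

Evaluation is **resubstitution** by default (centroids include the series
being classified), matching how the study design reads; a leave-one-out
mode (`score(mode="loo")`) rebuilds the series' own-group centroid
without it for an honest generalisation estimate. The classification
universe is groups 1-4; the flat "no response" group 0 is excluded by
default (its membership is evident from a low, flat course) and can be
included with `include_group0=True`. `Np` is always reported alongside
`C` so denominators are never implicit.

## Synthetic cohort generator

The real cohort (88 patients, 211 DSAs) is not redistributable, so the
generator emulates its statistical structure. Noiseless shapes on days
*t* = 1..50:

| group | curve |
|---|---|
| 0 | `b` (constant) |
| 1, 2 | `b + A (t/tp)^k exp(k (1 − t/tp))`, peak at `tp`, `k = decay_rate·tp` |
| 3 | `b + (P − b)(1 − e^{−r t})` |
| 4 | `P e^{−d (t−1)}`, mild drift `d = 0.001/day` |

The gamma pulse is smooth, non-negative and single-peaked; its asymptotic
log-decay rate equals `decay_rate`, and `rise_rate` mirrors it (the pulse
has one shape parameter). Defaults: group 1 peaks at day 12 (fast
modulation peaks within 10-15 days) with `decay_rate = 1/3` (resolution
by ~day 30); group 2 peaks at day 18 with `decay_rate = 1/6` (resolution
towards day 50); group 3 rises with `r = 0.15/day` from a low baseline;
group 4 starts high. Free scales (`A`, `P`) are solved at construction so
each group's noiseless time average over days 1-50 equals the published
per-group average total-DSA (2062 / 7023 / 7105 / 14813 / 12674 MFI).

**Heterogeneity.** Between-patient parameter variability is not reported
for the source cohort, so defaults are exposed as configuration:
lognormal multipliers truncated at 2σ on baselines (CV 0.15), modulated
pulse amplitudes (CV 0.12) and sustained plateaus (CV 0.06), and peak-day
jitter (SD 1.5 days, clipped to ±3). The truncation and the tighter
plateau spread encode *label self-consistency*: the real labels come from
clustering the full 50-day series, so by construction no member sits
closer to another cluster's mean — within-group spread must stay below
the between-group gaps (the two sustained levels differ by only ~15%).
With these defaults every noiseless trajectory is strictly DTW-closest to
its own centroid, and full-series resubstitution is 100%, mirroring the
labelled clinical data.

**Noise.** Measurement error is multiplicative lognormal per time point
with unit mean, default CV 0.15 — MFI is positive and semi-quantitative,
making relative error the natural scale.

**Band mixing.** Pattern probabilities per pre-desensitisation MFI band
default to the published band-by-group count table (normalised counts;
printed percentage rows are accepted but validated only to 100 ± 1
because integer rounding makes one published row sum to 101). Baseline
MFI values are drawn log-uniformly within the band. Without mixing,
bands are drawn group-conditionally from the same table, so the joint
band×pattern structure is reproducible either way.

**Sampling.** The default schedule is days 1-14 daily, alternate days to
28, then 31, 34, 38, 42, 46, 50 — matching the narrative description of
the clinical sampling; exact per-day counts were never tabulated. Days 1
and 50 are mandatory anchors for interpolation. `split_dsas=True`
decomposes each patient's curve into 1-7 per-DSA components (Dirichlet
proportions, independent noise) to exercise the summation path.

**What the generator does not emulate:** treatment effects (DFPP,
lymphocyte depletion) and rejection episodes that perturb real
trajectories; per-locus immunology; correlation between baseline band and
trajectory scale beyond group membership; non-lognormal assay artefacts.
Passing tests therefore show the pipeline is correct and self-consistent
under the stated generative assumptions — not that real cohorts achieve
the same accuracies.

## Schedule search

- **Section splitting.** The first N−1 sections have length
  `floor(50/N)`; the last absorbs the remainder. This is the only rule
  consistent with the documented N = 26 behaviour (25 single-day sections
  then one 25-day section), which skews coverage towards the early period
  and produces the accuracy dip after N = 25.
- **Middle day** of a section is the ceiling middle (a 25-day section
  yields its 13th day), so N = 2 gives {13, 38}; "first" gives {1, 26}.
- **Random selection** draws one day uniformly per section, with
  per-repeat substreams spawned from a master seed; 100 repeats by
  default, averaged. Deterministic strategies are evaluated once.
- **Greedy stage 2** adds the best single day per step (ties to the
  smaller day), never accepting an accuracy decrease, up to a size cap
  (default 5); replacement scans swap each base day against every
  candidate. An exhaustive subset search is available
  (`exhaustive_search`) for small candidate pools — the full C(50, ≤5)
  space is combinatorially feasible but slow, hence opt-in.
- Accuracy is *not* monotone in subset refinement under DTW, so the
  search reports absolute C for every subset rather than deltas.

## Problem sizes and tolerances

Tests run on cohorts of 10-25 trajectories per group (the published
cohort has 15-23 per pattern group), full sweeps on N = 2..50 with up to
100 random repeats; DTW equality against the brute-force oracle is
asserted to 1e-9 on sequences of length ≤ 7 (path enumeration grows
exponentially beyond that). Reported accuracies are rounded to one
decimal place. The acceptance script (`scripts/acceptance.py`) uses 25
trajectories per group and derives all randomness from `--seed`.

## Known limitations

- Resubstitution accuracy is optimistic by construction; use
  `mode="loo"` for generalisation estimates.
- Unconstrained DTW lets amplitude differences dominate timing
  differences; a warping window (not implemented — out of scope) would
  change the trade-off.
- The generator's heterogeneity settings bound what noise levels the
  classifier is shown; conclusions about required monitoring days on real
  data rest on the labelled clinical cohort, not on these simulations.
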