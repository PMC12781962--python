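# dsamonitor

Tools for studying **early post-transplant donor-specific antibody (DSA)
dynamics** after HLA-incompatible (HLAi) kidney transplantation, and for
finding the **minimal set of monitoring days** that still identifies a
patient's DSA dynamic pattern.

## The problem

After HLAi transplantation, total-DSA MFI trajectories over the first 50
days fall into distinct dynamic patterns with different prognoses:

| group | name | behaviour |
|---|---|---|
| 0 | no response | flat, low MFI throughout |
| 1 | fast modulation | sharp early peak (~day 12), resolves by ~day 30 |
| 2 | slow modulation | later peak (~day 18), resolves towards day 50 |
| 3 | rise to sustained | starts low, rises to a high plateau |
| 4 | sustained | high from day 1 and stays high |

Modulated responses (1-2) carry a better graft prognosis than sustained
ones (3-4), so recognising the pattern early matters clinically — but
near-daily Luminex testing is costly. The question this package answers:
*how few monitoring days suffice to classify the pattern accurately?*

## The method

- **Centroids.** For each pattern group, the per-day arithmetic mean of
  its daily total-DSA series is the group *centroid*.
- **Classification.** A series reduced to a monitoring-day subset is
  assigned to the group whose (equally reduced) centroid has the smallest
  **dynamic time warping (DTW)** distance, with local cost `|a_i − b_j|`.
- **Accuracy.** `C = Ncp / Np × 100`, the percentage of series whose
  predicted group matches their label.
- **Schedule search.** Days 1-50 are split into *N* contiguous sections
  and one day taken per section (first / middle / random point) for
  *N* = 2..50; promising small subsets are then grown greedily under a
  size cap; finally, published clinical monitoring regimens are scored
  with the same classifier and ranked.

Because the original 88-patient clinical dataset is available only on
request, the package ships a **synthetic cohort generator** that emulates
its structure: the five trajectory shapes, per-group MFI scales anchored
to the published group averages, pattern probabilities per
pre-desensitisation MFI band, the irregular clinical sampling schedule,
and multiplicative lognormal measurement noise. All downstream stages are
developed and tested against it; real long-format CSV exports with the
same columns are accepted identically.

## Worked example

```python
from dsamonitor import (CohortConfig, DsaPatternModel, compare_regimens,
                        generate_cohort, interpolate_daily)

cfg = CohortConfig(n_per_group=25, seed=7, groups=(1, 2, 3, 4))
cohort = [interpolate_daily(s) for s in generate_cohort(cfg)]
results = DsaPatternModel(cohort).fit()
print(results.summary())
```

```
DSA dynamic-pattern nearest-centroid DTW classifier
series: 100   groups: [1, 2, 3, 4]
resubstitution accuracy (all 50 days): C = 99.0% (Ncp=99, Np=100)

group name                  n  day-1 MFI   peak MFI  day-50 MFI
    1 fast modulation      25       1171      19418        1221
    2 slow modulation      25       1571      12190        2661
    3 rise to sustained    25       4470      17313       17313
    4 sustained            25      13121      13744       12363
```

The summary shows 100 simulated patients, the fitted centroid levels per
group (modulated groups peak and fall back; sustained groups end high),
and that the full 50-day series recovers 99% of the labels. Scoring a
four-day schedule and the built-in clinical regimen catalogue:

```python
out = results.score(days=(1, 10, 26, 34))
print(f"days {out.days}: C = {out.accuracy:.1f}% (Ncp={out.ncp}, Np={out.np_})")
print(compare_regimens(results).to_string(index=False))
```

```
days (1, 10, 26, 34): C = 100.0% (Ncp=100, Np=100)
name                                               days  n_days     C  Ncp  Np
   A 1,2,3,4,5,6,7,8,9,10,11,12,13,14,17,18,20,22,27,30      20 100.0  100 100
   F                                            1,10,26       3 100.0  100 100
  F'                                            1,10,34       3 100.0  100 100
   G                                         1,10,26,34       4 100.0  100 100
   E                                   1,2,3,7,14,21,28       7  99.0   99 100
   B                                          1,8,15,22       4  98.0   98 100
   C                                             1,7,30       3  97.0   97 100
   D                                          4,7,14,30       4  94.0   94 100
```

Four well-chosen days (1, 10, 26, 34) match the 20-day regimen A and beat
every other published schedule on this cohort — days 1 (separates low
starters from sustained), 10 (near the fast-modulation peak) and 26/34
(separates resolving from plateauing trajectories) carry most of the
information.

The same stages are available from the shell:

```bash
dsamonitor simulate --n-per-group 25 --seed 7 --out cohort.csv
dsamonitor classify --cohort cohort.csv --days 1,10,26,34
dsamonitor sweep --cohort cohort.csv --strategy random --repeats 100 --seed 1 --out sweep.csv
dsamonitor optimize --cohort cohort.csv --base 1,26 --max-size 5
dsamonitor compare-protocols --cohort cohort.csv
dsamonitor run --config run.yaml --outdir results/
```

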