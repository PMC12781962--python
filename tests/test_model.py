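import numpy as np
import pandas as pd
import pytest

from dsamonitor import (
    CohortConfig,
    DsaPatternModel,
    accuracy,
    classify,
    compute_centroids,
    generate_cohort,
    summarize_bands,
    trajectories_to_frame,
)

from conftest import make_series

DAILY = np.arange(1, 51)


def constant_series(value, group, pid="P1"):
    return make_series(DAILY, np.full(50, float(value)), patient_id=pid, group=group)


class TestCentroids:
    def test_mean_of_members(self):
        cohort = [
            constant_series(100, 1, "P1"),
            constant_series(300, 1, "P2"),
            constant_series(50, 2, "P3"),  # singleton group
        ]
        cents = compute_centroids(cohort)
        assert np.all(cents.centroids[1].mfi == 200.0)
        assert np.all(cents.centroids[2].mfi == 50.0)

    def test_identical_members_give_that_member(self):
        cohort = [constant_series(7, 1, "P1"), constant_series(7, 1, "P2"),
                  constant_series(9, 3, "P3")]
        cents = compute_centroids(cohort)
        assert np.all(cents.centroids[1].mfi == 7.0)

    def test_rejects_unlabelled_and_sparse(self):
        with pytest.raises(ValueError, match="unlabelled"):
            compute_centroids([constant_series(1, None)])
        with pytest.raises(ValueError, match="not daily"):
            compute_centroids([make_series([1, 50], [1.0, 1.0], group=1)])
        with pytest.raises(ValueError, match="empty"):
            compute_centroids([])


class TestClassify:
    def test_zero_distance_to_own_centroid(self, noiseless_results):
        cents = noiseless_results.centroids
        member = cents.centroids[2]
        assert classify(member, cents, days=(1, 10, 26)) == 2

    def test_tie_goes_to_smallest_group_id(self):
        cohort = [constant_series(0, 1, "P1"), constant_series(10, 3, "P2")]
        cents = compute_centroids(cohort)
        probe = constant_series(5, None, "Q")  # exactly equidistant from 1 and 3
        assert classify(probe, cents, days=DAILY) == 1

    def test_centroid_supply_order_is_irrelevant(self, noiseless_cohort):
        fwd = compute_centroids(noiseless_cohort)
        rev = compute_centroids(list(reversed(noiseless_cohort)))
        for s in noiseless_cohort[:8]:
            days = (1, 10, 26, 34)
            assert classify(s, fwd, days) == classify(s, rev, days)


class TestAccuracy:
    @pytest.mark.parametrize(
        "preds, truths, expected",
        [
            ([1] * 64, [1] * 64, 100.0),
            ([1, 2, 3, 3], [1, 2, 3, 4], 75.0),
            ([1, 1], [2, 2], 0.0),
        ],
    )
    def test_formula(self, preds, truths, expected):
        out = accuracy(preds, truths)
        assert out.accuracy == pytest.approx(expected)
        assert out.ncp <= out.np_

    def test_rejects_length_mismatch_and_empty(self):
        with pytest.raises(ValueError, match="lengths differ"):
            accuracy([1], [1, 2])
        with pytest.raises(ValueError, match="at least one"):
            accuracy([], [])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        preds = rng.integers(1, 5, 40)
        truths = rng.integers(1, 5, 40)
        base = accuracy(preds, truths).accuracy
        perm = rng.permutation(40)
        assert accuracy(preds[perm], truths[perm]).accuracy == pytest.approx(base)


class TestModelResults:
    def test_noiseless_resubstitution_is_perfect(self, noiseless_results):
        out = noiseless_results.score()
        assert out.accuracy == 100.0 and out.np_ == 40

    def test_every_member_nearest_its_own_centroid(self, noiseless_cohort, noiseless_results):
        preds = noiseless_results.predict(noiseless_cohort)
        truths = [s.group for s in noiseless_cohort]
        assert list(preds) == truths

    def test_loo_mode_runs_and_is_not_better_than_resub(self, noisy_results):
        days = (1, 10, 26, 34)
        resub = noisy_results.score(days=days).accuracy
        loo = noisy_results.score(days=days, mode="loo").accuracy
        assert 0.0 <= loo <= 100.0
        assert loo <= resub + 10.0  # sanity, not a theorem

    def test_from_dataframe_round_trip(self, noisy_cohort):
        df = trajectories_to_frame(noisy_cohort)
        model = DsaPatternModel.from_dataframe(df)
        assert model.y.size == len(noisy_cohort)
        out = model.fit().score(days=(1, 26))
        assert 0.0 <= out.accuracy <= 100.0

    def test_group0_flag_extends_universe(self):
        cfg = CohortConfig(n_per_group=5, seed=2, noise_cv=0.0,
                           sampling_schedule=tuple(range(1, 51)))
        cohort = generate_cohort(cfg)
        m_default = DsaPatternModel(cohort)
        m_all = DsaPatternModel(cohort, include_group0=True)
        assert m_default.group_ids == (1, 2, 3, 4)
        assert m_all.group_ids == (0, 1, 2, 3, 4)
        assert m_all.fit().score().accuracy == 100.0

    def test_summary_reports_accuracy_and_groups(self, noiseless_results):
        text = noiseless_results.summary()
        assert "C = 100.0%" in text
        assert "fast modulation" in text


class TestSummarizeBands:
    def test_published_percentage_rows(self):
        counts = {
            "<2500": (64, 24, 21, 2, 3),
            ">10000": (0, 0, 2, 1, 7),
        }
        out = summarize_bands(counts)
        assert out.loc["<2500", [f"pct_group{g}" for g in range(5)]].tolist() == [
            56, 21, 18, 2, 3
        ]
        assert out.loc[">10000", ["pct_no_response", "pct_modulated", "pct_sustained"]
                       ].tolist() == [0, 20, 80]

    def test_single_nonzero_cell(self):
        out = summarize_bands({"x": (0, 5, 0, 0, 0)})
        assert out.loc["x", "pct_group1"] == 100

    def test_rows_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(8)
        counts = {f"b{i}": tuple(rng.integers(0, 40, 5) + 1) for i in range(10)}
        out = summarize_bands(counts)
        sums = out[[f"pct_group{g}" for g in range(5)]].sum(axis=1)
        assert np.all(np.abs(sums - 100) <= 1 + 1)  # 5 cells, half-up rounding

    def test_empty_band_flagged(self):
        with pytest.warns(UserWarning, match="zero total"):
            out = summarize_bands({"empty": (0, 0, 0, 0, 0)})
        assert np.isnan(out.loc["empty", "pct_group0"])

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            summarize_bands({"x": (-1, 0, 0, 0, 0)})
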