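import numpy as np
import pytest

from dsamonitor import (
    BUILTIN_REGIMENS,
    Regimen,
    SectionScheme,
    compare_regimens,
    evaluate_subset,
    exhaustive_search,
    greedy_augment,
    select_days,
    split_sections,
    sweep_sections,
)

from conftest import make_series

DAILY = np.arange(1, 51)


class TestSplitSections:
    def test_even_split(self):
        assert split_sections(2) == ((1, 25), (26, 50))

    def test_n26_anomaly(self):
        bounds = split_sections(26)
        assert bounds[:25] == tuple((d, d) for d in range(1, 26))
        assert bounds[25] == (26, 50)
        lengths = [e - s + 1 for s, e in bounds]
        assert max(lengths) == 25

    def test_singleton_sections(self):
        assert split_sections(50) == tuple((d, d) for d in range(1, 51))

    @pytest.mark.parametrize("n", [1, 0, 51])
    def test_bounds_rejected(self, n):
        with pytest.raises(ValueError, match=r"N must lie"):
            split_sections(n)

    @pytest.mark.parametrize("n", range(2, 51))
    def test_partition_covers_all_days(self, n):
        bounds = split_sections(n)
        covered = [d for s, e in bounds for d in range(s, e + 1)]
        assert covered == list(range(1, 51))
        scheme = SectionScheme(n, bounds)  # invariant check in constructor
        assert sum(scheme.section_lengths) == 50


class TestSelectDays:
    def test_first_and_middle_for_two_sections(self):
        bounds = split_sections(2)
        assert select_days(bounds, "first").tolist() == [1, 26]
        assert select_days(bounds, "middle").tolist() == [13, 38]

    def test_all_strategies_identity_at_n50(self):
        bounds = split_sections(50)
        for strat in ("first", "middle", "random"):
            assert select_days(bounds, strat, seed=0).tolist() == list(range(1, 51))

    def test_random_one_day_per_section_and_seeded(self):
        bounds = split_sections(7)
        a = select_days(bounds, "random", seed=42)
        b = select_days(bounds, "random", seed=42)
        assert a.tolist() == b.tolist()
        for (s, e), d in zip(bounds, a):
            assert s <= d <= e

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="unknown strategy"):
            select_days(split_sections(2), "last")


class TestEvaluateSubset:
    def test_full_grid_is_perfect_on_noiseless(self, noiseless_results):
        assert evaluate_subset(noiseless_results, range(1, 51)).accuracy == 100.0

    def test_key_days_perfect_on_noiseless(self, noiseless_results):
        assert evaluate_subset(noiseless_results, (1, 10, 26, 34)).accuracy == 100.0

    def test_single_coincident_day_cannot_separate(self):
        # groups 1 and 2 share the day-2 value by construction
        cohort = []
        for i in range(3):
            v1 = np.full(50, 10.0); v1[9] = 100.0   # bump day 10
            v2 = np.full(50, 10.0); v2[29] = 100.0  # bump day 30
            cohort.append(make_series(DAILY, v1, patient_id=f"A{i}", group=1))
            cohort.append(make_series(DAILY, v2, patient_id=f"B{i}", group=2))
        out = evaluate_subset(cohort, (2,))
        assert out.accuracy < 100.0


class TestSweepSections:
    def test_full_resolution_reaches_100(self, noiseless_results):
        df = sweep_sections(noiseless_results, "first", n_range=[50])
        assert df.loc[50, "accuracy"] == 100.0

    def test_deterministic_across_runs(self, noisy_results):
        a = sweep_sections(noisy_results, "random", n_range=[2, 5, 10], repeats=5, seed=3)
        b = sweep_sections(noisy_results, "random", n_range=[2, 5, 10], repeats=5, seed=3)
        assert a.equals(b)

    def test_deterministic_strategy_forces_single_repeat(self, noiseless_results):
        df = sweep_sections(noiseless_results, "middle", n_range=[2, 25], repeats=50)
        assert np.all(df["sd"] == 0.0)

    def test_more_sections_do_not_hurt_separable_cohort(self, noiseless_results):
        df = sweep_sections(noiseless_results, "first", n_range=[2, 25])
        assert df.loc[25, "accuracy"] >= df.loc[2, "accuracy"]

    def test_validates_inputs(self, noiseless_results):
        with pytest.raises(ValueError, match="unknown strategy"):
            sweep_sections(noiseless_results, "best")
        with pytest.raises(ValueError, match="repeats"):
            sweep_sections(noiseless_results, "random", repeats=0)


class TestGreedyAugment:
    def test_candidates_already_in_base_change_nothing(self, noiseless_results):
        res = greedy_augment(noiseless_results, base=(1, 26), candidate_days=(1, 26),
                             max_size=5)
        assert res.best_subset == (1, 26)

    def test_max_size_equal_base_returns_base(self, noiseless_results):
        res = greedy_augment(noiseless_results, base=(1, 26), max_size=2)
        assert res.best_subset == (1, 26)
        assert res.steps == []

    def test_adds_the_only_informative_day_first(self):
        # only day 10 separates groups 1 and 2
        cohort = []
        for i in range(3):
            v1 = np.full(50, 10.0); v1[9] = 200.0
            v2 = np.full(50, 10.0)
            cohort.append(make_series(DAILY, v1, patient_id=f"A{i}", group=1))
            cohort.append(make_series(DAILY, v2, patient_id=f"B{i}", group=2))
        res = greedy_augment(cohort, base=(1, 26), candidate_days=range(1, 51), max_size=3)
        assert res.best_subset == (1, 10, 26)
        assert res.best_accuracy == 100.0

    def test_replacement_scan_covers_base_days(self, noisy_results):
        res = greedy_augment(noisy_results, base=(1, 26), candidate_days=range(1, 51, 5),
                             max_size=3)
        assert set(res.replacements) == {1, 26}

    def test_rejects_empty_candidates_and_bad_sizes(self, noiseless_results):
        with pytest.raises(ValueError, match="non-empty"):
            greedy_augment(noiseless_results, base=(1,), candidate_days=(), max_size=3)
        with pytest.raises(ValueError, match="max_size"):
            greedy_augment(noiseless_results, base=(1, 26), max_size=1)


class TestRegimens:
    def test_builtin_catalogue_day_lists(self):
        days = {r.name: r.days for r in BUILTIN_REGIMENS}
        assert days["A"] == tuple(range(1, 15)) + (17, 18, 20, 22, 27, 30)
        assert days["B"] == (1, 8, 15, 22)
        assert days["C"] == (1, 7, 30)
        assert days["D"] == (4, 7, 14, 30)
        assert days["E"] == (1, 2, 3, 7, 14, 21, 28)
        assert days["F"] == (1, 10, 26)
        assert days["F'"] == (1, 10, 34)
        assert days["G"] == (1, 10, 26, 34)

    def test_out_of_range_regimen_named_in_error(self):
        with pytest.raises(ValueError, match="'weekly-90'"):
            Regimen("weekly-90", (1, 30, 60, 90))

    def test_all_regimens_perfect_on_noiseless_cohort(self, noiseless_results):
        df = compare_regimens(noiseless_results)
        with_day1 = df[df["days"].str.startswith("1,")]
        assert np.all(with_day1["C"] == 100.0)
        assert df["C"].is_monotonic_decreasing

    def test_full_series_regimen_matches_full_accuracy(self, noisy_results):
        reg = Regimen("all", tuple(range(1, 51)))
        df = compare_regimens(noisy_results, regimens=[reg])
        assert df.loc[0, "C"] == noisy_results.score().accuracy

    def test_duplicate_names_warn_but_score(self, noiseless_results):
        regs = [Regimen("X", (1, 26)), Regimen("X", (1, 10, 26))]
        with pytest.warns(UserWarning, match="duplicate"):
            df = compare_regimens(noiseless_results, regimens=regs)
        assert len(df) == 2


def test_exhaustive_search_finds_known_optimum():
    cohort = []
    for i in range(2):
        v1 = np.full(50, 10.0); v1[9] = 200.0
        v2 = np.full(50, 10.0)
        cohort.append(make_series(DAILY, v1, patient_id=f"A{i}", group=1))
        cohort.append(make_series(DAILY, v2, patient_id=f"B{i}", group=2))
    df = exhaustive_search(cohort, candidate_days=(1, 5, 10, 20), max_size=2)
    top = df.iloc[0]
    assert "10" in top["days"].split(",")
    assert top["C"] == 100.0
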