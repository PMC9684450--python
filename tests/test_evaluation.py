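"""Metrics, folds, protocol bookkeeping, permutation importance."""

import numpy as np
import pytest

from popdisagg import (
    CensusTable,
    PomeloRegressor,
    ValidationError,
    compute_metrics,
    make_folds,
    permutation_importance,
    run_coarse_supervision,
    run_fine_supervision,
    run_transfer,
    simulate_landscape,
    simulate_landscape_family,
    default_config,
)
from popdisagg.evaluation import _fold_sets
from popdisagg.grids import CovariateStack, GridSpec


class TestMetrics:
    def test_closed_forms(self):
        census = CensusTable("fine", {1: 10, 2: 20, 3: 30})
        exact = compute_metrics({1: 10.0, 2: 20.0, 3: 30.0}, census)
        assert (exact.r2, exact.mae, exact.mape) == (100.0, 0.0, 0.0)
        mean_pred = compute_metrics({1: 20.0, 2: 20.0, 3: 20.0}, census)
        assert mean_pred.r2 == pytest.approx(0.0)
        double = compute_metrics({1: 20.0, 2: 40.0, 3: 60.0}, census)
        assert double.mape == pytest.approx(100.0)

    def test_zero_census_regions_excluded_from_mape_only(self):
        census = CensusTable("fine", {1: 0, 2: 20, 3: 30})
        m = compute_metrics({1: 5.0, 2: 20.0, 3: 30.0}, census)
        assert m.excluded_zero_census == 1
        assert m.mape == 0.0
        assert m.mae == pytest.approx(5.0 / 3)

    def test_min_census_filter_knob(self):
        census = CensusTable("fine", {1: 5, 2: 20, 3: 30})
        m = compute_metrics({1: 10.0, 2: 20.0, 3: 30.0}, census, min_census=10.0)
        assert m.excluded_zero_census == 1 and m.mape == 0.0

    def test_needs_two_regions(self):
        with pytest.raises(ValidationError):
            compute_metrics({1: 5.0}, CensusTable("fine", {1: 5}))

    def test_agrees_with_independent_reimplementation(self):
        from sklearn.metrics import r2_score

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 40)
            c = rng.uniform(1, 1000, n)
            chat = rng.uniform(0, 1000, n)
            census = CensusTable("fine", {i + 1: c[i] for i in range(n)})
            m = compute_metrics({i + 1: chat[i] for i in range(n)}, census)
            assert m.r2 == pytest.approx(100 * r2_score(c, chat), abs=1e-12)
            assert m.mae == pytest.approx(np.abs(c - chat).mean(), abs=1e-12)
            assert m.mape == pytest.approx(100 * np.mean(np.abs(c - chat) / c), abs=1e-12)


class TestFolds:
    def test_170_regions_split_into_folds_of_34(self):
        folds = make_folds(range(1, 171), n_folds=5, seed=0)
        sizes = sorted(len(folds.fold_ids(f)) for f in range(5))
        assert sizes == [34] * 5

    def test_seven_regions_sizes_within_one(self):
        folds = make_folds(range(1, 8), n_folds=5, seed=1)
        sizes = sorted(len(folds.fold_ids(f)) for f in range(5))
        assert sizes == [1, 1, 1, 2, 2]

    def test_deterministic_and_partition(self):
        a = make_folds(range(1, 23), seed=9)
        b = make_folds(range(1, 23), seed=9)
        assert a.assignment == b.assignment
        covered = sorted(r for f in range(5) for r in a.fold_ids(f))
        assert covered == list(range(1, 23))

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValidationError):
            make_folds([1, 2, 3], n_folds=5, seed=0)


class TestProtocolBookkeeping:
    """Run the fold protocols with the cheap rate baseline to check wiring."""

    @pytest.fixture(scope="class")
    def folds(self, default_landscape):
        return make_folds(sorted(default_landscape.census_coarse.entries), seed=11)

    def test_rotations_partition_coarse_regions(self, default_landscape, folds):
        seen = []
        for r in range(5):
            train, val, test = _fold_sets(folds, r)
            assert not (set(train) & set(val)) and not (set(val) & set(test))
            seen.extend(test)
        assert sorted(seen) == sorted(default_landscape.census_coarse.entries)

    def test_pooled_test_set_covers_every_fine_region_once(self, default_landscape, folds):
        res = run_fine_supervision(default_landscape, "avg", folds, seed=0)
        assert sorted(res["predictions"]) == sorted(default_landscape.census_fine.entries)

    def test_fine_and_coarse_protocols_share_test_regions(self, default_landscape, folds):
        fine = run_fine_supervision(default_landscape, "avg", folds, seed=0)
        coarse = run_coarse_supervision(default_landscape, "buildings", folds, seed=0)
        assert sorted(fine["predictions"]) == sorted(coarse["predictions"])

    def test_fine_regions_inherit_coarse_fold(self, default_landscape, folds):
        t = default_landscape
        for r in range(5):
            _, _, test_c = _fold_sets(folds, r)
            from popdisagg.evaluation import _fine_ids_of

            for f in _fine_ids_of(t, test_c):
                assert folds.assignment[t.hierarchy.coarse_of(f)] == r

    def test_coarse_protocol_conserves_test_coarse_censuses(self, default_landscape, folds):
        t = default_landscape
        res = run_coarse_supervision(t, "buildings", folds, seed=0)
        for cid, count in t.census_coarse.entries.items():
            members = t.hierarchy.members(cid)
            total = sum(res["predictions"][f] for f in members if f in res["predictions"])
            assert total == pytest.approx(count, rel=1e-9, abs=1e-9)

    def test_learning_free_methods_rejected_in_fine_and_transfer(self, default_landscape, folds):
        with pytest.raises(ValidationError):
            run_fine_supervision(default_landscape, "buildings", folds)
        with pytest.raises(ValidationError):
            run_transfer([default_landscape, default_landscape], 0, "mrf")

    def test_transfer_needs_two_landscapes(self, default_landscape):
        with pytest.raises(ValidationError):
            run_transfer([default_landscape], 0, "pomelo")


class TestTransferHarness:
    def test_avg_baseline_runs_and_reports_mean_sd(self):
        fam = simulate_landscape_family(
            3, seed=2, base_config=default_config(
                seed=2, grid=GridSpec(32, 32), n_fine_regions=12, n_coarse_regions=4,
                built_fraction_target=0.12,
            ),
        )
        res = run_transfer(fam, 0, "avg", seed=0, n_runs=2)
        assert len(res["runs"]) == 2
        assert set(res["mean"]) == {"r2", "mae", "mape"}
        assert res["sd"]["r2"] == pytest.approx(0.0)  # avg baseline has no run randomness


class TestPermutationImportance:
    def test_generative_channel_ranks_first_and_constant_drops_zero(self):
        cfg = default_config(
            seed=0, occupancy_weights=(0, 0, 2.0, 0, 0, 0, 0, 0), occupancy_bias=0.0
        )
        t = simulate_landscape(cfg)
        vals = t.covariates.values.copy()
        vals[:, :, 7] = 0.0  # constant channel
        stack = CovariateStack(t.covariates.grid, list(t.covariates.channels), vals)
        m = PomeloRegressor(seed=0, weight_decay_grid=(0.0,), max_epochs=120)
        m.fit(stack, t.buildings, t.regions, t.census_fine)
        rep = permutation_importance(
            m, stack, t.buildings, t.regions, t.census_fine, n_repeats=2, seed=0
        )
        assert rep.ranked_by_r2_drop()[0] == "ch02"
        assert rep.drops["ch07"]["r2"] == 0.0
        assert rep.drops["ch07"]["mae"] == 0.0
        assert rep.drops["ch02"]["r2"] > 10.0
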