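"""Network, loss, aggregation and trainer behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popdisagg import (
    BuildingCountMap,
    CensusTable,
    GridSpec,
    NetworkSpec,
    PomeloRegressor,
    PopulationMap,
    RegionMap,
    ValidationError,
    aggregate_to_regions,
    count_params,
    log_l1_loss,
    merge_pseudo_regions,
    predict_population,
)
from popdisagg.nn import Adam, ConvNet
from popdisagg.pomelo import OccupancyMap, SupervisionDataset, init_network, train_pomelo

from conftest import toy_stack


class TestNetwork:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            (NetworkSpec(n_inputs=17), 35457),
            (NetworkSpec(n_inputs=17, kernel_size=3), 316033),
            (NetworkSpec(n_inputs=1, depth=2, hidden_width=1), 4),
        ],
    )
    def test_parameter_count_closed_form(self, spec, expected):
        assert count_params(spec) == expected
        assert init_network(spec, seed=0).n_params == expected

    def test_init_deterministic(self):
        a = init_network(NetworkSpec(n_inputs=3), seed=7)
        b = init_network(NetworkSpec(n_inputs=3), seed=7)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_grid_and_cell_paths_agree_for_1x1(self):
        net = init_network(NetworkSpec(n_inputs=4, hidden_width=8), seed=0)
        X = np.random.default_rng(0).normal(size=(5, 6, 4))
        z_grid, _ = net.forward_grid(X)
        z_cells, _ = net.forward_cells(X.reshape(-1, 4))
        np.testing.assert_allclose(z_grid, z_cells, rtol=1e-12)

    @pytest.mark.parametrize("kernel_size", [1, 3])
    def test_backward_matches_finite_differences(self, kernel_size):
        spec = NetworkSpec(n_inputs=2, depth=3, hidden_width=4, kernel_size=kernel_size,
                           dropout_p=0.0)
        net = ConvNet(spec, seed=1)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 4, 2))
        w = rng.normal(size=16)  # random linear functional of the outputs

        def loss_value():
            z, _ = net.forward_grid(X)
            return float(w @ z)

        z, cache = net.forward_grid(X)
        grads = net.backward_grid(cache, w)
        params = net.get_flat_params()
        eps = 1e-6
        for p, g in zip(params, grads):
            idx = np.unravel_index(np.argmax(np.abs(g)), p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            up = loss_value()
            p[idx] = orig - eps
            down = loss_value()
            p[idx] = orig
            fd = (up - down) / (2 * eps)
            assert fd == pytest.approx(g[idx], rel=1e-4, abs=1e-7)

    def test_dropout_only_active_in_train_mode(self):
        net = init_network(NetworkSpec(n_inputs=3, hidden_width=16, dropout_p=0.4), seed=0)
        X = np.random.default_rng(0).normal(size=(10, 3))
        z1, _ = net.forward_cells(X)
        z2, _ = net.forward_cells(X)
        np.testing.assert_array_equal(z1, z2)
        z3, _ = net.forward_cells(X, dropout_rng=np.random.default_rng(1))
        assert not np.array_equal(z1, z3)

    def test_adam_reduces_simple_quadratic(self):
        p = [np.array([5.0])]
        opt = Adam(p, lr=0.1)
        for _ in range(200):
            opt.step([2 * p[0]])
        assert abs(p[0][0]) < 0.1


class TestPredictPopulation:
    def test_arithmetic_and_linearity_in_buildings(self):
        grid = GridSpec(1, 2)
        occ = OccupancyMap(grid, np.array([[4.2, 1.0]]))
        b = BuildingCountMap(grid, np.array([[10, 0]]))
        pop = predict_population(occ, b)
        assert pop.values[0, 0] == pytest.approx(42.0)
        assert pop.values[0, 1] == 0.0
        b2 = BuildingCountMap(grid, np.array([[20, 0]]))
        np.testing.assert_allclose(predict_population(occ, b2).values, 2 * pop.values)

    def test_zero_initialized_head_gives_log2_occupancy(self):
        grid = GridSpec(4, 4)
        stack = toy_stack(grid, 3, np.random.default_rng(0))
        stack.values[:] = 0.0
        b = BuildingCountMap(grid, np.ones((4, 4), dtype=int))
        m = PomeloRegressor(seed=0, max_epochs=1, weight_decay_grid=(0.0,), hidden_width=8)
        regions = RegionMap(grid, np.ones((4, 4), dtype=int) + (np.arange(16) % 2).reshape(4, 4))
        census = CensusTable("fine", {1: 5, 2: 5})
        m.fit(stack, b, regions, census, val_ids=[2])
        m.net_.weights[-1][:] = 0.0
        m.net_.biases[-1][:] = 0.0
        occ = m.predict_occupancy(stack, b)
        np.testing.assert_allclose(occ.values, np.log(2.0), rtol=1e-12)


class TestAggregation:
    def test_hand_example(self):
        grid = GridSpec(2, 2)
        pop = PopulationMap(grid, np.array([[1.0, 2.0], [3.0, 4.0]]))
        regions = RegionMap(grid, np.array([[1, 1], [2, 2]]))
        assert aggregate_to_regions(pop, regions).entries == {1: 3.0, 2: 7.0}

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            grid = GridSpec(64, 64)
            vals = rng.gamma(1.0, 2.0, size=grid.shape)
            ids = rng.integers(0, 9, size=grid.shape)
            agg = aggregate_to_regions(PopulationMap(grid, vals), RegionMap(grid, ids))
            for rid in np.unique(ids[ids > 0]):
                brute = sum(
                    vals[i, j] for i in range(64) for j in range(64) if ids[i, j] == rid
                )
                assert agg.entries[int(rid)] == pytest.approx(brute, abs=1e-9)

    def test_linear_in_the_map(self):
        rng = np.random.default_rng(1)
        grid = GridSpec(8, 8)
        ids = rng.integers(1, 4, size=grid.shape)
        a = rng.gamma(1, 1, grid.shape)
        b = rng.gamma(1, 1, grid.shape)
        regions = RegionMap(grid, ids)
        agg_sum = aggregate_to_regions(PopulationMap(grid, a + b), regions)
        agg_a = aggregate_to_regions(PopulationMap(grid, a), regions)
        agg_b = aggregate_to_regions(PopulationMap(grid, b), regions)
        for r in agg_sum.entries:
            assert agg_sum.entries[r] == pytest.approx(agg_a.entries[r] + agg_b.entries[r])


class TestLogL1Loss:
    def test_closed_forms(self):
        assert log_l1_loss({1: 100.0, 2: 7.0}, {1: 100.0, 2: 7.0}) == 0.0
        assert log_l1_loss({1: 100.0 * np.e}, {1: 100.0}) == pytest.approx(1.0)
        assert log_l1_loss({1: 200.0}, {1: 100.0}) == pytest.approx(np.log(2.0))

    def test_symmetry_and_missing_region(self):
        assert log_l1_loss({1: 50.0}, {1: 80.0}) == pytest.approx(log_l1_loss({1: 80.0}, {1: 50.0}))
        with pytest.raises(KeyError):
            log_l1_loss({1: 1.0, 2: 2.0}, {1: 1.0})

    @settings(deadline=None, max_examples=50)
    @given(
        k=st.floats(min_value=0.01, max_value=100.0),
        a=st.floats(min_value=2.0, max_value=1e5),
        b=st.floats(min_value=2.0, max_value=1e5),
    )
    def test_scale_invariance_above_floor(self, k, a, b):
        base = log_l1_loss({1: a}, {1: b})
        scaled = log_l1_loss({1: k * a}, {1: k * b}, log_eps=min(1.0, k))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_floor_engages_for_zero_counts(self):
        assert log_l1_loss({1: 0.0}, {1: 0.0}) == 0.0
        assert log_l1_loss({1: 0.0}, {1: np.e}) == pytest.approx(1.0)


class TestPseudoRegions:
    def _setup(self, n=6):
        grid = GridSpec(6, 6)
        ids = (np.arange(36) % n + 1).reshape(6, 6)
        regions = RegionMap(grid, ids)
        census = CensusTable("fine", {i: float(10 * i) for i in range(1, n + 1)})
        return regions, census

    def test_merge_is_additive_in_counts_and_cells(self):
        regions, census = self._setup()
        units = merge_pseudo_regions(regions, census, n_pairs=3, seed=0)
        originals = {u.region_ids[0]: u for u in units if len(u.region_ids) == 1}
        merged = [u for u in units if len(u.region_ids) == 2]
        assert len(merged) == 3
        for u in merged:
            a, b = u.region_ids
            assert u.target == census.entries[a] + census.entries[b]
            assert len(u.cells) == len(originals[a].cells) + len(originals[b].cells)

    def test_zero_pairs_is_identity(self):
        regions, census = self._setup()
        units = merge_pseudo_regions(regions, census, n_pairs=0, seed=0)
        assert len(units) == census.n_c
        assert all(len(u.region_ids) == 1 for u in units)

    def test_cell_counts_additive_for_many_pairs(self):
        regions, census = self._setup()
        sizes = {r: int((regions.ids == r).sum()) for r in census.entries}
        units = merge_pseudo_regions(regions, census, n_pairs=100, seed=1)
        merged = [u for u in units if len(u.region_ids) == 2]
        assert len(merged) == 100
        for u in merged:
            assert len(u.cells) == sizes[u.region_ids[0]] + sizes[u.region_ids[1]]

    def test_negative_pairs_rejected(self):
        regions, census = self._setup()
        with pytest.raises(ValidationError):
            merge_pseudo_regions(regions, census, n_pairs=-1, seed=0)


class TestTrainer:
    def test_same_seed_reruns_identical(self, small_landscape):
        t = small_landscape
        kwargs = dict(seed=3, weight_decay_grid=(0.0,), max_epochs=10, hidden_width=16)
        a = PomeloRegressor(**kwargs).fit(t.covariates, t.buildings, t.regions, t.census_fine)
        b = PomeloRegressor(**kwargs).fit(t.covariates, t.buildings, t.regions, t.census_fine)
        assert a.best_val_mape_ == b.best_val_mape_
        for wa, wb in zip(a.net_.weights, b.net_.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_zero_census_region_keeps_loss_finite(self):
        grid = GridSpec(4, 4)
        rng = np.random.default_rng(0)
        stack = toy_stack(grid, 2, rng)
        b = BuildingCountMap(grid, rng.poisson(1.0, grid.shape))
        regions = RegionMap(grid, np.repeat([1, 2], 8).reshape(4, 4))
        census = CensusTable("fine", {1: 0.0, 2: 0.0})
        m = PomeloRegressor(seed=0, weight_decay_grid=(0.0,), max_epochs=5,
                            hidden_width=8, log_eps=1.0)
        m.fit(stack, b, regions, census, val_ids=[2])
        assert np.all(np.isfinite(m.history_[0.0]["train_loss"]))

    def test_no_active_cells_is_degenerate(self):
        grid = GridSpec(4, 4)
        stack = toy_stack(grid, 2, np.random.default_rng(0))
        b = BuildingCountMap(grid, np.zeros(grid.shape, dtype=int))
        regions = RegionMap(grid, np.repeat([1, 2], 8).reshape(4, 4))
        census = CensusTable("fine", {1: 10.0, 2: 5.0})
        with pytest.raises(ValidationError):
            PomeloRegressor(seed=0, max_epochs=2).fit(stack, b, regions, census, val_ids=[2])

    def test_validation_regions_must_be_disjoint(self, small_landscape):
        t = small_landscape
        ds = SupervisionDataset(t.covariates, t.buildings, t.regions, t.census_fine)
        with pytest.raises(ValidationError):
            PomeloRegressor(max_epochs=1).fit_multi([ds], [(0, 1), (0, 2)], [(0, 2)])

    def test_train_pomelo_wrapper_returns_model_and_history(self, small_landscape):
        t = small_landscape
        from popdisagg import TrainingConfig

        model, history = train_pomelo(
            t.covariates, t.buildings, t.regions, t.census_fine,
            config=TrainingConfig(weight_decay_grid=(0.0,), max_epochs=5),
        )
        assert 0.0 in history
        assert len(history[0.0]["train_loss"]) == 5
        assert model.predict(t.covariates, t.buildings).values.min() >= 0.0

    def test_channel_mismatch_rejected_at_predict(self, small_landscape):
        t = small_landscape
        m = PomeloRegressor(seed=0, weight_decay_grid=(0.0,), max_epochs=2, hidden_width=8)
        m.fit(t.covariates, t.buildings, t.regions, t.census_fine)
        bad = toy_stack(t.covariates.grid, t.covariates.n_channels + 1, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            m.predict(bad, t.buildings)

    def test_mask_invariant_for_arbitrary_parameters(self, small_landscape):
        t = small_landscape
        m = PomeloRegressor(seed=0, weight_decay_grid=(0.0,), max_epochs=2, hidden_width=8)
        m.fit(t.covariates, t.buildings, t.regions, t.census_fine)
        rng = np.random.default_rng(5)
        for _ in range(5):
            for w in m.net_.weights:
                w[...] = rng.normal(size=w.shape)
            pop = m.predict(t.covariates, t.buildings)
            assert pop.values[~t.buildings.active_mask].sum() == 0.0
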