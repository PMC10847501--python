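"""Lookup-table inversion: cost maps, clustering, pooling, full recovery."""

import numpy as np
import pytest

from filmetry.colorimetry import CameraModel
from filmetry.inversion import (
    CandidateMin,
    CostMap,
    ParameterGrid,
    RGBTable,
    build_lut,
    candidate_probabilities,
    cluster_pixels,
    cost_map,
    pool_cost_maps,
    pooled_cost_map,
    recover_maps,
)
from filmetry.synthetic import film_rgb, make_uniform_cell_phantom


class TestParameterGrid:
    def test_default_grid_node_count(self):
        grid = ParameterGrid()
        assert grid.shape == (1201, 221)

    def test_axis_values_hit_bounds(self):
        grid = ParameterGrid()
        assert grid.t_values[0] == 0.0 and grid.t_values[-1] == 1200.0
        assert grid.n_values[0] == pytest.approx(1.33)
        assert grid.n_values[-1] == pytest.approx(1.55)


class TestBuildLut:
    def test_zero_thickness_is_black_on_air(self, coarse_lut_air):
        assert coarse_lut_air.entries[0].max() == 0

    def test_rebuild_reproduces_fingerprint(self, coarse_grid, air, camera8):
        a = build_lut(coarse_grid, air, camera8)
        b = build_lut(coarse_grid, air, camera8)
        assert a.fingerprint == b.fingerprint
        assert np.array_equal(a.entries, b.entries)

    def test_entries_match_single_film_simulation(self, coarse_lut_air, air, camera8):
        grid = coarse_lut_air.grid
        i, j = 140, 25
        expected = film_rgb(grid.t_values[i], grid.n_values[j], camera8, air)
        assert np.array_equal(coarse_lut_air.entries[i, j], expected)

    def test_csv_round_trip(self, tmp_path, coarse_lut_air):
        path = tmp_path / "lut.csv"
        coarse_lut_air.to_csv(path)
        back = RGBTable.from_csv(path)
        assert back.grid == coarse_lut_air.grid
        assert back.fingerprint == coarse_lut_air.fingerprint
        assert np.array_equal(back.entries, coarse_lut_air.entries)


class TestCostMap:
    def test_exact_table_entry_has_zero_cost(self, coarse_lut_air):
        i, j = 120, 30
        cm = cost_map(coarse_lut_air.entries[i, j], coarse_lut_air)
        assert cm.values[i, j] == 0.0
        assert cm.values.min() == 0.0

    def test_hand_evaluated_mse(self, coarse_lut_air):
        # channel offsets (8, 0, 12) from a known entry: MSE = (64+144)/3
        i, j = 120, 30
        entry = coarse_lut_air.entries[i, j].astype(int)
        pixel = np.clip(entry + np.array([8, 0, 12]), 0, 255)
        offsets = pixel - entry
        cm = cost_map(pixel, coarse_lut_air)
        assert cm.values[i, j] == pytest.approx(np.sum(offsets**2) / 3)

    def test_matches_naive_loop_oracle(self, rng):
        grid = ParameterGrid(t_min=100, t_max=190, t_step=10, n_min=1.40,
                             n_max=1.49, n_step=0.01)
        entries = rng.integers(0, 256, size=grid.shape + (3,))
        table = RGBTable(grid, entries, bit_depth=8)
        pixel = np.array([40, 200, 120])
        cm = cost_map(pixel, table)
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                expected = sum(
                    (int(pixel[c]) - int(entries[i, j, c])) ** 2 for c in range(3)
                ) / 3
                assert cm.values[i, j] == expected

    def test_bit_depth_mismatch_rejected(self, coarse_lut_air):
        with pytest.raises(ValueError, match="bit depth"):
            cost_map(np.array([1, 2, 3]), coarse_lut_air, bit_depth=16)


class TestCandidateProbabilities:
    def _map_with(self, mses):
        grid = ParameterGrid(t_max=10, t_step=1, n_max=1.34, n_step=0.01)
        minima = [CandidateMin(float(i), 1.33, m, 0.0) for i, m in enumerate(mses)]
        return CostMap(grid, np.ones(grid.shape), minima)

    def test_single_minimum_certain(self):
        probs = candidate_probabilities(self._map_with([2.0]))
        assert probs[0][2] == pytest.approx(1.0)

    def test_equal_minima_split_evenly(self):
        probs = candidate_probabilities(self._map_with([1.5, 1.5]))
        assert [p for _, _, p in probs] == pytest.approx([0.5, 0.5])

    def test_inverse_mse_weighting(self):
        probs = candidate_probabilities(self._map_with([1.0, 3.0]))
        assert [p for _, _, p in probs] == pytest.approx([0.75, 0.25])

    def test_empty_map_rejected(self):
        grid = ParameterGrid(t_max=10, t_step=1, n_max=1.34, n_step=0.01)
        with pytest.raises(ValueError):
            candidate_probabilities(CostMap(grid, np.ones(grid.shape), []))


class TestPooling:
    def test_identical_maps_pool_to_themselves(self, coarse_lut_air):
        cm = cost_map(np.array([90, 40, 70]), coarse_lut_air)
        pooled = pool_cost_maps([cm, cm, cm])
        assert np.array_equal(pooled.values, cm.values)

    def test_mean_of_values(self):
        grid = ParameterGrid(t_max=10, t_step=10, n_max=1.331, n_step=1e-3)
        a = CostMap(grid, np.zeros(grid.shape))
        b = CostMap(grid, np.full(grid.shape, 2.0))
        assert np.allclose(pool_cost_maps([a, b]).values, 1.0)

    def test_grid_mismatch_rejected(self):
        g1 = ParameterGrid(t_max=10, t_step=10, n_max=1.331, n_step=1e-3)
        g2 = ParameterGrid(t_max=20, t_step=10, n_max=1.331, n_step=1e-3)
        with pytest.raises(ValueError):
            pool_cost_maps([CostMap(g1, np.zeros(g1.shape)),
                            CostMap(g2, np.zeros(g2.shape))])

    def test_single_pass_pooling_equals_mean_of_maps(self, coarse_lut_air, rng):
        pixels = rng.integers(0, 256, size=(9, 3))
        maps = [cost_map(p, coarse_lut_air) for p in pixels]
        ref = pool_cost_maps(maps)
        fast = pooled_cost_map(pixels, coarse_lut_air)
        assert np.allclose(fast.values, ref.values, atol=1e-8)


class TestClustering:
    def test_film_plus_black_background_gives_two_clusters(self, air, camera8):
        cam = CameraModel(bit_depth=8, value_variation=1)
        phantom = make_uniform_cell_phantom(567.0, 1.41, 64, cam, air, seed=3)
        cs = cluster_pixels(phantom.rgb_image, 2.0, seed=0)
        assert cs.n_clusters == 2
        assert len(cs.background_ids) == 1

    def test_uniform_image_is_one_cluster(self):
        img = np.full((12, 12, 3), 99, dtype=np.uint8)
        cs = cluster_pixels(img, 2.0, seed=0)
        assert cs.n_clusters == 1
        assert cs.mean_deviation_pct[0] == 0.0

    def test_two_well_separated_colors_split(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[:, :8] = [100, 120, 140]
        img[:, 8:] = [150, 180, 210]  # 50% brighter in every channel
        cs = cluster_pixels(img, 2.0, seed=0)
        assert cs.n_clusters == 2
        assert not cs.background_ids

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            cluster_pixels(np.zeros((0, 0, 3), dtype=np.uint8))


class TestRecovery:
    def test_noiseless_phantom_at_grid_nodes_recovers_exactly(
        self, coarse_lut_air, air, camera8
    ):
        grid = coarse_lut_air.grid
        t, n = grid.t_values[140], grid.n_values[25]
        phantom = make_uniform_cell_phantom(t, n, 48, camera8, air, seed=0)
        result = recover_maps(phantom.rgb_image, coarse_lut_air, seed=0)
        fg = phantom.foreground_mask
        assert np.all(result.thickness_map[fg] == t)
        assert np.all(result.ri_map[fg] == pytest.approx(n))
        assert np.all(np.isnan(result.thickness_map[~fg]))

    def test_two_region_phantom_recovers_both_films(self, coarse_lut_air, air, camera8):
        grid = coarse_lut_air.grid
        t1, n1 = grid.t_values[140], grid.n_values[25]
        t2, n2 = grid.t_values[90], grid.n_values[45]
        left = make_uniform_cell_phantom(t1, n1, 48, camera8, air, seed=0,
                                         cell_fraction=0.9)
        right = make_uniform_cell_phantom(t2, n2, 48, camera8, air, seed=0,
                                          cell_fraction=0.9)
        img = np.concatenate([left.rgb_image, right.rgb_image], axis=1)
        result = recover_maps(img, coarse_lut_air, seed=0)
        recovered = {(s["t_nm"], round(s["n"], 4)) for s in result.summary}
        assert (t1, round(n1, 4)) in recovered
        assert (t2, round(n2, 4)) in recovered

    def test_recovery_is_deterministic_in_seed(self, coarse_lut_air, air):
        cam = CameraModel(bit_depth=8, value_variation=1)
        phantom = make_uniform_cell_phantom(560.0, 1.412, 48, cam, air, seed=4)
        a = recover_maps(phantom.rgb_image, coarse_lut_air, seed=11)
        b = recover_maps(phantom.rgb_image, coarse_lut_air, seed=11)
        assert np.array_equal(a.thickness_map, b.thickness_map, equal_nan=True)
        assert np.array_equal(a.ri_map, b.ri_map, equal_nan=True)
        assert np.array_equal(a.cluster_labels, b.cluster_labels)

    def test_background_only_image_warns(self, coarse_lut_air):
        img = np.full((16, 16, 3), 2, dtype=np.uint8)
        with pytest.warns(UserWarning, match="background"):
            result = recover_maps(img, coarse_lut_air, seed=0)
        assert np.all(np.isnan(result.thickness_map))
        assert result.summary == []

    def test_pooled_minimum_sticks_to_true_node_under_jitter(
        self, default_lut_air, air
    ):
        """The true node attains the pooled-map minimum for <=1-code jitter."""
        cam = CameraModel(bit_depth=8, value_variation=1)
        grid = default_lut_air.grid
        i, j = 567, 80  # t = 567 nm, n = 1.41
        for seed in range(20):
            phantom = make_uniform_cell_phantom(
                grid.t_values[i], grid.n_values[j], 40, cam, air, seed=seed
            )
            pixels = phantom.rgb_image[phantom.foreground_mask]
            pooled = pooled_cost_map(pixels, default_lut_air)
            assert pooled.values[i, j] == pooled.values.min()
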