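"""Latent grid construction, JV assignment, region tests, trajectories."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fncinterp.static_interp import (GridLayout, TrajectorySpec,
                                     assign_to_grid, assignment_cost,
                                     choose_grid_side, classify_edge_change,
                                     decode_grid, grid_correspondence,
                                     grid_range, group_centroid,
                                     interpolate_trajectory, make_grid,
                                     overlay_measures, region_tests,
                                     trajectory_edge_tests)


class _LinearDecoder:
    """Deterministic linear decoder toy: x = B z + c."""

    latent_dim = 2

    def __init__(self, v=12, seed=0):
        rng = np.random.default_rng(seed)
        self.B = rng.normal(size=(2, v))
        self.c = rng.normal(size=v)

    def decode(self, Z):
        return np.atleast_2d(Z) @ self.B + self.c


class TestGridRange:
    def test_sort_based_percentile_oracle(self):
        vals = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        Z = np.column_stack([vals, vals])
        expected = np.percentile(np.abs(Z).ravel(), 80)
        assert grid_range(Z) == pytest.approx(expected)

    def test_constant_magnitude(self):
        Z = np.full((10, 2), 0.7) * np.sign(np.arange(20).reshape(10, 2) - 9.5)
        assert grid_range(Z) == pytest.approx(0.7)

    def test_positive_homogeneity(self, rng):
        Z = rng.normal(size=(50, 2))
        assert grid_range(3 * Z) == pytest.approx(3 * grid_range(Z))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            grid_range(np.zeros((10, 2)))


class TestMakeGrid:
    def test_default_side_gives_225_nodes(self):
        grid = make_grid(1.0, side=15)
        assert grid.n_nodes == 225

    def test_side_for_225_training_samples_is_15(self):
        assert choose_grid_side(225) == 15

    def test_corner_grid(self):
        grid = make_grid(1.0, side=2)
        assert sorted(map(tuple, grid.coords)) == [(-1.0, -1.0), (-1.0, 1.0),
                                                   (1.0, -1.0), (1.0, 1.0)]

    @pytest.mark.parametrize("side,r", [(15, 2.0), (7, 0.5), (4, 3.0)])
    def test_even_spacing(self, side, r):
        grid = make_grid(r, side=side)
        xs = np.unique(grid.coords[:, 0])
        assert xs.size == side
        np.testing.assert_allclose(np.diff(xs), 2 * r / (side - 1), atol=1e-12)

    def test_orientation_row0_is_top(self):
        grid = make_grid(1.0, side=3)
        # node (row 0, col 2): x largest, y largest
        assert tuple(grid.coords[2]) == (1.0, 1.0)
        # node (row 2, col 0): x smallest, y smallest
        assert tuple(grid.coords[6]) == (-1.0, -1.0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            make_grid(1.0, side=1)
        with pytest.raises(ValueError):
            make_grid(0.0, side=5)


class TestDecodeGrid:
    def test_deterministic(self):
        dec = _LinearDecoder()
        grid = make_grid(1.0, side=4)
        np.testing.assert_array_equal(decode_grid(dec, grid),
                                      decode_grid(dec, grid))

    def test_latent_dim_guard(self):
        dec = _LinearDecoder()
        dec.latent_dim = 3
        with pytest.raises(ValueError):
            decode_grid(dec, make_grid(1.0, side=4))


class TestAssignment:
    def test_exact_node_positions_cost_zero(self):
        grid = make_grid(1.0, side=3)
        latents = grid.coords[[0, 4, 8]]
        a = assign_to_grid(latents, grid)
        assert assignment_cost(latents, grid, a) == pytest.approx(0.0)
        assert [a[i] for i in range(3)] == [0, 4, 8]

    def test_matches_bruteforce_small_instances(self, rng):
        grid = make_grid(1.0, side=3)
        for trial in range(50):
            n = int(rng.integers(2, 7))
            latents = rng.uniform(-1.2, 1.2, size=(n, 2))
            a = assign_to_grid(latents, grid)
            cost = assignment_cost(latents, grid, a)
            d = np.linalg.norm(latents[:, None, :] - grid.coords[None, :, :],
                               axis=2)
            best = min(
                sum(d[i, c] for i, c in enumerate(combo))
                for combo in itertools.permutations(range(grid.n_nodes), n)
            )
            assert cost == pytest.approx(best, abs=1e-10)

    def test_input_order_invariance(self, rng):
        grid = make_grid(1.0, side=4)
        latents = rng.uniform(-1, 1, size=(10, 2))
        perm = rng.permutation(10)
        c1 = assignment_cost(latents, grid, assign_to_grid(latents, grid))
        c2 = assignment_cost(latents[perm], grid,
                             assign_to_grid(latents[perm], grid))
        assert c1 == pytest.approx(c2)

    def test_injective(self, rng):
        grid = make_grid(1.0, side=4)
        latents = rng.uniform(-1, 1, size=(16, 2))
        a = assign_to_grid(latents, grid)
        assert len(set(a.values())) == len(a) == 16

    def test_capacity_error_suggests_side(self):
        grid = make_grid(1.0, side=2)
        with pytest.raises(ValueError, match="increase side"):
            assign_to_grid(np.zeros((5, 2)), grid)


class TestCorrespondenceAndOverlay:
    def test_originals_equal_decoded(self):
        dec = _LinearDecoder()
        grid = make_grid(1.0, side=4)
        decoded = decode_grid(dec, grid)
        latents = grid.coords[:10]
        a = assign_to_grid(latents, grid)
        res = grid_correspondence(decoded, decoded[[a[i] for i in range(10)]], a)
        assert np.allclose(res["metrics"]["pearson_r"], 1.0)
        assert res["fractions"][0.6] == 1.0 and res["fractions"][0.8] == 1.0

    def test_threshold_fraction_manual_count(self, rng):
        dec = _LinearDecoder(v=40)
        grid = make_grid(1.0, side=4)
        decoded = decode_grid(dec, grid)
        latents = rng.uniform(-1, 1, size=(10, 2))
        a = assign_to_grid(latents, grid)
        originals = decoded[[a[i] for i in range(10)]].copy()
        originals[:4] += rng.normal(scale=20.0, size=(4, 40))  # break 4 pairs
        res = grid_correspondence(decoded, originals, a)
        rs = res["metrics"]["pearson_r"].to_numpy()
        assert res["fractions"][0.8] == pytest.approx(np.mean(rs > 0.8))

    def test_overlay_nan_propagation(self):
        grid = make_grid(1.0, side=3)
        meta = pd.DataFrame({"score": [1.0, np.nan, 3.0]})
        a = {0: 0, 1: 4, 2: 8}
        out = overlay_measures(a, meta, "score", grid)
        assert out[0, 0] == 1.0
        assert np.isnan(out[1, 1])  # missing value stays missing
        assert np.isnan(out[0, 1])  # unassigned node
        assert out[2, 2] == 3.0

    def test_overlay_unknown_column(self):
        grid = make_grid(1.0, side=3)
        with pytest.raises(KeyError, match="available"):
            overlay_measures({}, pd.DataFrame({"a": [1]}), "b", grid)


class TestRegionTests:
    @staticmethod
    def _assign_all(side):
        return {i: i for i in range(side * side)}

    def test_constant_measure_all_p_one(self):
        grid = make_grid(1.0, side=15)
        n = grid.n_nodes
        meta = pd.DataFrame({"m": np.ones(n), "group": ["p"] * n})
        df = region_tests(self._assign_all(15), meta, "m", grid)
        assert np.allclose(df["p_two_sided"].dropna(), 1.0)
        means = df.set_index("region")["mean"]
        assert means.nunique() == 1

    def test_planted_upper_lower_shift(self, rng):
        grid = make_grid(1.0, side=15)
        n = grid.n_nodes
        vals = rng.normal(size=n)
        for node in range(n):
            row, _ = grid.node_rowcol(node)
            if row < 7:
                vals[node] += 10.0
        meta = pd.DataFrame({"m": vals, "group": ["p"] * n})
        df = region_tests(self._assign_all(15), meta, "m", grid).set_index("region")
        assert df.loc["upper", "p_two_sided"] < 1e-3
        assert df.loc["upper", "p_this_greater"] < 1e-3
        assert df.loc["left", "p_two_sided"] > 0.01

    def test_partition_counts_complete(self, rng):
        grid = make_grid(1.0, side=15)
        latents = rng.uniform(-1, 1, size=(60, 2))
        a = assign_to_grid(latents, grid)
        meta = pd.DataFrame({"m": rng.normal(size=60), "group": ["p"] * 60})
        df = region_tests(a, meta, "m", grid).set_index("region")["n"]
        assert df["upper"] + df["lower"] == 60
        assert df["left"] + df["right"] == 60
        assert df["upper_triangle"] + df["lower_triangle"] == 60

    def test_row_split_is_seven_eight(self):
        grid = make_grid(1.0, side=15)
        a = self._assign_all(15)
        meta = pd.DataFrame({"m": np.ones(225), "group": ["p"] * 225})
        df = region_tests(a, meta, "m", grid).set_index("region")["n"]
        assert df["upper"] == 7 * 15 and df["lower"] == 8 * 15
        assert df["upper_triangle"] == 120  # includes the diagonal


class TestCentroidsAndTrajectory:
    def test_group_centroid_cases(self, rng):
        Z = rng.normal(size=(10, 2))
        labels = np.array(["a"] * 4 + ["b"] * 6)
        np.testing.assert_allclose(group_centroid(Z, labels, "a"),
                                   Z[:4].mean(axis=0), atol=1e-12)
        one = group_centroid(Z[:1], ["solo"], "solo")
        np.testing.assert_array_equal(one, Z[0])
        with pytest.raises(ValueError):
            group_centroid(Z, labels, "missing")

    def test_trajectory_points(self):
        spec = TrajectorySpec(start=[0.0, 0.0], end=[2.0, -2.0], n_points=3)
        np.testing.assert_allclose(spec.points,
                                   [[0, 0], [1, -1], [2, -2]], atol=1e-12)

    def test_zero_noise_identical_draws(self):
        dec = _LinearDecoder()
        spec = TrajectorySpec(start=[0.0, 0.0], end=[1.0, 1.0], n_points=2,
                              draw_count=5, noise_scale=0.0)
        draws = interpolate_trajectory(dec, spec, seed=0)
        for d in draws:
            assert np.ptp(d, axis=0).max() == 0.0

    def test_linear_decoder_midpoint_is_mean_of_ends(self):
        dec = _LinearDecoder()
        spec = TrajectorySpec(start=[-1.0, 0.5], end=[1.0, -0.5], n_points=3)
        a, mid, b = (d[0] for d in interpolate_trajectory(dec, spec, seed=0))
        np.testing.assert_allclose(mid, (a + b) / 2, atol=1e-10)


class TestTrajectoryEdgeTests:
    def test_no_change_no_significance(self, rng):
        draws = rng.normal(size=(20, 30))
        df = trajectory_edge_tests(draws, draws.copy())
        assert not df["significant"].any()

    def test_planted_shift_detected_only_there(self, rng):
        M, V = 50, 200
        base = rng.normal(scale=0.01, size=(M, V))
        end = base + rng.normal(scale=0.01, size=(M, V))
        end[:, 7] += 0.5
        df = trajectory_edge_tests(base, end, alpha=1e-4)
        assert df.loc[7, "significant"]
        assert df["significant"].sum() <= 3  # essentially only the planted edge

    def test_low_power_flag(self, rng):
        df = trajectory_edge_tests(rng.normal(size=(4, 5)),
                                   rng.normal(size=(4, 5)))
        assert df["low_power"].all()

    @pytest.mark.parametrize("a,b,expected", [
        (0.2, 0.6, "pos_stronger"),
        (0.6, 0.2, "pos_weaker"),
        (-0.2, -0.6, "neg_stronger"),
        (-0.6, -0.2, "neg_weaker"),
        (0.3, -0.3, "pos_to_neg"),
        (-0.3, 0.3, "neg_to_pos"),
    ])
    def test_edge_category_logic(self, a, b, expected):
        assert classify_edge_change(a, b) == expected
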