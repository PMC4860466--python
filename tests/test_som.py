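"""Map self-organization primitives: BMU search, updates, QE, radius rule."""

import numpy as np
import pytest

from bilexmap.som import (
    MapGrid,
    NeighborhoodState,
    TrainingSchedule,
    adapt_radius,
    find_bmu,
    learning_rate,
    neighborhood_field,
    quantization_error,
    update_map,
)


def random_grid(rng, rows=5, cols=5, dim=4):
    return MapGrid.initialize(dim, rows, cols, rng)


class TestFindBMU:
    def test_exact_match_wins(self, rng):
        grid = random_grid(rng)
        assert find_bmu(grid, grid.weights[7].copy()) == 7

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            grid = random_grid(rng)
            x = rng.uniform(0, 1, size=grid.dim)
            oracle = min(
                range(grid.n_nodes),
                key=lambda i: float(np.linalg.norm(grid.weights[i] - x)),
            )
            assert find_bmu(grid, x) == oracle

    def test_tie_breaks_to_lower_index(self, rng):
        grid = random_grid(rng)
        grid.weights[9] = grid.weights[4]
        assert find_bmu(grid, grid.weights[4].copy()) == 4

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            find_bmu(random_grid(rng), np.zeros(3))


class TestUpdateMap:
    def test_radius_zero_moves_only_bmu(self, rng):
        grid = random_grid(rng)
        before = grid.weights.copy()
        x = rng.uniform(0, 1, size=grid.dim)
        bmu = find_bmu(grid, x)
        update_map(grid, x, bmu, lr=0.5, radius=0)
        changed = np.nonzero((grid.weights != before).any(axis=1))[0]
        assert list(changed) == [bmu]

    def test_lr_zero_is_identity(self, rng):
        grid = random_grid(rng)
        before = grid.weights.copy()
        update_map(grid, rng.uniform(0, 1, grid.dim), 0, lr=0.0, radius=3)
        assert np.array_equal(grid.weights, before)

    def test_bmu_moves_by_lr_fraction(self, rng):
        """At grid distance 0 the kernel is 1, so w' = w + lr (x - w)."""
        grid = random_grid(rng)
        x = rng.uniform(0, 1, grid.dim)
        bmu = 12
        expected = grid.weights[bmu] + 0.1 * (x - grid.weights[bmu])
        update_map(grid, x, bmu, lr=0.1, radius=2)
        assert np.allclose(grid.weights[bmu], expected)

    def test_repeated_updates_converge_monotonically(self, rng):
        grid = random_grid(rng)
        x = rng.uniform(0, 1, grid.dim)
        bmu = find_bmu(grid, x)
        dists = []
        for _ in range(200):
            update_map(grid, x, bmu, lr=0.2, radius=1)
            dists.append(float(np.linalg.norm(grid.weights[bmu] - x)))
        assert all(b <= a + 1e-15 for a, b in zip(dists, dists[1:]))
        assert dists[-1] < 1e-6

    def test_nodes_beyond_radius_unchanged(self, rng):
        grid = random_grid(rng, rows=7, cols=7)
        before = grid.weights.copy()
        update_map(grid, rng.uniform(0, 1, grid.dim), bmu=0, lr=0.3, radius=2)
        far = grid.grid_dist2()[0] > 4
        assert np.array_equal(grid.weights[far], before[far])


class TestQuantizationError:
    def test_zero_when_inputs_equal_nodes(self, rng):
        grid = random_grid(rng)
        assert quantization_error(grid, grid.weights[[2, 5, 9]].copy()) == 0.0

    def test_single_input_single_node(self):
        grid = MapGrid(rows=1, cols=1, dim=2, weights=np.array([[0.0, 0.0]]))
        assert quantization_error(grid, np.array([[3.0, 4.0]])) == pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        grid = random_grid(rng)
        X = rng.uniform(0, 1, size=(6, grid.dim))
        expected = np.mean([
            min(np.linalg.norm(x - w) for w in grid.weights) for x in X
        ])
        assert quantization_error(grid, X) == pytest.approx(expected)

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError):
            quantization_error(random_grid(rng), np.empty((0, 4)))


class TestRadiusRule:
    def make_state(self, prev, cur, radius=15):
        return NeighborhoodState(radius=radius, qe_history=[prev] * 5 + [cur] * 5)

    def test_plateau_decrements(self):
        state = adapt_radius(self.make_state(1.0, 0.9))
        assert state.radius == 14

    def test_fast_improvement_keeps_radius(self):
        state = adapt_radius(self.make_state(1.0, 0.5))
        assert state.radius == 15

    def test_floor_is_respected(self):
        state = adapt_radius(self.make_state(1.0, 1.0, radius=1))
        assert state.radius == 1

    def test_insufficient_history_rejected(self):
        with pytest.raises(ValueError):
            adapt_radius(NeighborhoodState(qe_history=[1.0] * 7))

    def test_boundary_of_25_percent_band(self):
        # exactly 25% away still counts as similar -> decrement
        state = adapt_radius(self.make_state(1.0, 0.75))
        assert state.radius == 14


class TestSchedule:
    def test_linear_anneal_anchors(self):
        assert learning_rate(0) == pytest.approx(0.2)
        assert learning_rate(50) == pytest.approx(0.15)
        assert learning_rate(100) == pytest.approx(0.1)
        assert learning_rate(500) == pytest.approx(0.1)

    def test_monotone_non_increasing(self):
        sched = TrainingSchedule()
        lrs = [sched.lr(e) for e in range(0, 500, 7)]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))


class TestNeighborhoodField:
    def test_center_has_unit_activation(self, rng):
        grid = random_grid(rng)
        field = neighborhood_field(grid, 12, radius=3)
        assert field[12] == 1.0

    def test_truncated_beyond_radius(self, rng):
        grid = random_grid(rng, rows=9, cols=9)
        field = neighborhood_field(grid, 0, radius=2)
        assert field[grid.grid_dist2()[0] > 4].sum() == 0.0
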