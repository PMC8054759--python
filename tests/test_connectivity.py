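import numpy as np
import pandas as pd
import pytest

from conftest import make_grid
from helpers import brute_force_min_cost
from corridorscape.connectivity import (
    ConductanceGraph,
    build_graph,
    consensus_overlap,
    lcp_density,
    least_cost_path,
    percentile_mask,
    seasonal_conductance,
    solve_current,
    solve_current_graph,
)
from corridorscape.errors import (
    DegenerateRangeError,
    EmptyGraphError,
    MissingLayerError,
    NoPathError,
    SingularSystemError,
)


def pts(coords):
    return pd.DataFrame({"lon": [c[0] for c in coords], "lat": [c[1] for c in coords]})


class TestSeasonalConductance:
    def monthly(self, triples):
        return {m: make_grid(np.asarray(v, dtype=float)) for m, v in triples.items()}

    def test_identical_rasters_pass_through(self):
        v = np.full((2, 2), 0.4)
        out = seasonal_conductance(self.monthly({3: v, 4: v, 5: v}), "spring")
        np.testing.assert_allclose(out.values, 0.4)

    def test_cellwise_mean(self):
        out = seasonal_conductance(
            self.monthly({8: [[0.1]], 9: [[0.2]], 10: [[0.6]]}), "fall"
        )
        assert out.values[0, 0] == pytest.approx(0.3)

    def test_zero_cells_floored_at_epsilon(self):
        v = np.zeros((2, 2))
        out = seasonal_conductance(self.monthly({3: v, 4: v, 5: v}), "spring")
        assert np.all(out.values == 1e-6)

    def test_missing_month_raises(self):
        with pytest.raises(MissingLayerError):
            seasonal_conductance(self.monthly({3: [[0.1]], 4: [[0.1]]}), "spring")


class TestBuildGraph:
    def test_two_cell_chain(self):
        g = build_graph(make_grid(np.ones((1, 2))))
        assert g.n_nodes == 2
        assert g.cost[0, 1] == pytest.approx(1.0)
        assert g.conductance[0, 1] == pytest.approx(1.0)

    def test_diagonal_edge_length_scaling(self):
        grid = make_grid(np.ones((2, 2)))
        g = build_graph(grid)
        # nodes row-major: (0,0)=0, (0,1)=1, (1,0)=2, (1,1)=3
        assert g.cost[0, 3] == pytest.approx(np.sqrt(2.0))
        assert g.conductance[0, 3] == pytest.approx(1.0 / np.sqrt(2.0))

    def test_mean_resistance_rule(self):
        g = build_graph(make_grid(np.array([[1.0, 0.1]])))
        assert g.cost[0, 1] == pytest.approx((1.0 + 10.0) / 2.0)

    def test_all_masked_raises(self):
        grid = make_grid(np.ones((2, 2)), mask=np.ones((2, 2), dtype=bool))
        with pytest.raises(EmptyGraphError):
            build_graph(grid)

    def test_no_edges_into_masked_cells(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 1] = True
        g = build_graph(make_grid(np.ones((2, 2)), mask=mask))
        assert g.n_nodes == 3
        assert g.cost.nnz == 3 * 2  # triangle of 3 nodes, symmetric storage


class TestLeastCostPath:
    def test_uniform_chain_series_cost(self):
        g = build_graph(make_grid(np.ones((1, 3))))
        path, cost = least_cost_path(g, (0, 0), (0, 2))
        assert cost == pytest.approx(2.0)
        assert path == [(0, 0), (0, 1), (0, 2)]

    def test_path_routes_around_barrier(self):
        vals = np.ones((3, 3))
        vals[1, 1] = 0.1
        g = build_graph(make_grid(vals))
        path, cost = least_cost_path(g, (0, 0), (2, 2))
        assert (1, 1) not in path
        assert cost == pytest.approx(2.0 + np.sqrt(2.0), abs=1e-9)

    def test_src_equals_dst(self):
        g = build_graph(make_grid(np.ones((2, 2))))
        path, cost = least_cost_path(g, (1, 1), (1, 1))
        assert path == [] and cost == 0.0

    def test_unreachable_raises(self):
        mask = np.zeros((1, 3), dtype=bool)
        mask[0, 1] = True
        g = build_graph(make_grid(np.ones((1, 3)), mask=mask))
        with pytest.raises(NoPathError):
            least_cost_path(g, (0, 0), (0, 2))

    def test_matches_bruteforce_enumeration_on_random_grids(self):
        # oracle equivalence on random conductance rasters up to 4x4
        rng = np.random.default_rng(0)
        for rep in range(50):
            n_rows = int(rng.integers(2, 5))
            n_cols = int(rng.integers(2, 5))
            vals = rng.uniform(0.05, 1.0, size=(n_rows, n_cols))
            g = build_graph(make_grid(vals))
            src = (0, 0)
            dst = (n_rows - 1, n_cols - 1)
            _, cost = least_cost_path(g, src, dst)
            oracle = brute_force_min_cost(g.cost, g.node_at(*src), g.node_at(*dst))
            assert cost == pytest.approx(oracle, rel=1e-12)

    def test_raising_conductance_never_increases_cost(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.1, 1.0, size=(4, 4))
        g = build_graph(make_grid(vals))
        _, base = least_cost_path(g, (0, 0), (3, 3))
        for _ in range(10):
            r, c = rng.integers(0, 4, size=2)
            vals2 = vals.copy()
            vals2[r, c] = min(1.0, vals2[r, c] * 2.0)
            g2 = build_graph(make_grid(vals2))
            _, cost2 = least_cost_path(g2, (0, 0), (3, 3))
            assert cost2 <= base + 1e-12


class TestLcpDensity:
    def test_single_pair_density_is_path_indicator(self):
        grid = make_grid(np.ones((1, 4)))
        g = build_graph(grid)
        paths, dens, coords = lcp_density(
            g, pts([grid.center_of(0, 0)]), pts([grid.center_of(0, 3)])
        )
        assert len(paths) == 1
        np.testing.assert_array_equal(dens.values, [[1, 1, 1, 1]])
        assert len(coords[0]) == 4

    def test_pair_cardinality(self):
        grid = make_grid(np.ones((5, 5)))
        g = build_graph(grid)
        winter = pts([grid.center_of(4, c) for c in range(3)])
        summer = pts([grid.center_of(0, c) for c in range(2)])
        paths, dens, _ = lcp_density(g, winter, summer)
        assert len(paths) == 6

    def test_collinear_endpoints_concentrate_on_straight_line(self):
        grid = make_grid(np.ones((7, 3)))
        g = build_graph(grid)
        paths, dens, _ = lcp_density(
            g, pts([grid.center_of(6, 1)]), pts([grid.center_of(0, 1)])
        )
        assert np.all(dens.values[:, 1] == 1)
        assert dens.values[:, [0, 2]].sum() == 0

    def test_density_total_equals_sum_of_path_lengths(self):
        rng = np.random.default_rng(3)
        grid = make_grid(rng.uniform(0.2, 1.0, size=(6, 6)))
        g = build_graph(grid)
        winter = pts([grid.center_of(5, c) for c in (0, 2, 4)])
        summer = pts([grid.center_of(0, c) for c in (1, 3)])
        paths, dens, coords = lcp_density(g, winter, summer)
        assert dens.values.sum() == sum(len(c) for c in coords)


class TestSolveCurrent:
    def test_unit_chain_potentials_and_current(self):
        g = ConductanceGraph.from_edges(3, [(0, 1, 1.0, 1.0), (1, 2, 1.0, 1.0)])
        v, cur = solve_current_graph(g, sources=[0], grounds=[2], injection=1.0)
        np.testing.assert_allclose(v, [2.0, 1.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(cur, [0.5, 1.0, 0.5], atol=1e-10)

    def test_parallel_branch_current_split(self):
        # branch A conductance 1 (two series edges of 2), branch B conductance 3
        g = ConductanceGraph.from_edges(
            4,
            [
                (0, 1, 2.0, 0.5), (1, 3, 2.0, 0.5),
                (0, 2, 6.0, 1 / 6), (2, 3, 6.0, 1 / 6),
            ],
        )
        v, cur = solve_current_graph(g, sources=[0], grounds=[3], injection=1.0)
        assert cur[1] == pytest.approx(0.25, abs=1e-10)
        assert cur[2] == pytest.approx(0.75, abs=1e-10)

    def test_kirchhoff_conservation_at_interior_nodes(self):
        rng = np.random.default_rng(4)
        grid = make_grid(rng.uniform(0.1, 1.0, size=(6, 6)))
        graph = build_graph(grid)
        v, _ = solve_current_graph(graph, sources=[0], grounds=[graph.n_nodes - 1])
        lap = graph.conductance
        import scipy.sparse as sp

        deg = np.asarray(lap.sum(axis=1)).ravel()
        net = (sp.diags(deg) - lap) @ v
        interior = np.ones(graph.n_nodes, dtype=bool)
        interior[[0, graph.n_nodes - 1]] = False
        assert np.max(np.abs(net[interior])) < 1e-8

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        grid = make_grid(rng.uniform(0.1, 1.0, size=(5, 5)))
        graph = build_graph(grid)
        _, c1 = solve_current_graph(graph, [0], [graph.n_nodes - 1], injection=1.0)
        _, c2 = solve_current_graph(graph, [0], [graph.n_nodes - 1], injection=2.0)
        np.testing.assert_allclose(c2, 2.0 * c1, atol=1e-10)

    def test_chain_effective_resistance_closed_form(self):
        for n in (3, 5, 8):
            edges = [(i, i + 1, 1.0, 1.0) for i in range(n - 1)]
            g = ConductanceGraph.from_edges(n, edges)
            v, _ = solve_current_graph(g, [0], [n - 1], injection=1.0)
            assert v[0] == pytest.approx(n - 1, abs=1e-8)

    def test_ladder_effective_resistance_closed_form(self):
        # two parallel chains of 2 edges each, unit conductance:
        # R_parallel = (2 * 2) / (2 + 2) = 1
        g = ConductanceGraph.from_edges(
            4,
            [(0, 1, 1.0, 1.0), (1, 3, 1.0, 1.0), (0, 2, 1.0, 1.0), (2, 3, 1.0, 1.0)],
        )
        v, _ = solve_current_graph(g, [0], [3], injection=1.0)
        assert v[0] == pytest.approx(1.0, abs=1e-8)

    def test_disconnected_source_is_singular(self):
        g = ConductanceGraph.from_edges(4, [(0, 1, 1.0, 1.0), (2, 3, 1.0, 1.0)])
        with pytest.raises(SingularSystemError):
            solve_current_graph(g, [0], [3])

    def test_raster_interface_masks_propagate(self):
        grid = make_grid(np.ones((3, 3)))
        out = solve_current(grid, [(0, 0)], [(2, 2)], injection=1.0)
        assert out.shape == (3, 3)
        assert np.isfinite(out.values).all()


class TestPercentileMask:
    def test_interpolated_percentile_sets_five_cells(self):
        g = make_grid(np.arange(1, 101, dtype=float).reshape(10, 10))
        out = percentile_mask(g, q=95.0)
        # 95th percentile of 1..100 is 95.05; cells 96..100 reach it
        assert out.values.sum() == 5

    def test_q_zero_sets_all_valid_cells(self):
        g = make_grid(np.arange(1, 10, dtype=float).reshape(3, 3))
        out = percentile_mask(g, q=0.0)
        assert out.values.sum() == 9

    def test_mask_preserved_and_constant_rejected(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = True
        g = make_grid(np.arange(9, dtype=float).reshape(3, 3), mask=mask)
        out = percentile_mask(g, q=50.0)
        assert np.isnan(out.values[0, 0])
        with pytest.raises(DegenerateRangeError):
            percentile_mask(make_grid(np.full((3, 3), 1.0)), q=95.0)


class TestConsensus:
    def test_full_agreement_counts_three(self):
        ones = make_grid(np.ones((2, 2)))
        vals = make_grid(np.array([[1.0, 2.0], [3.0, 4.0]]))
        res = consensus_overlap(vals, vals.copy(), percentile_mask(vals, 0.0),
                                density_q=0.0, current_q=0.0)
        np.testing.assert_allclose(res.consensus.values, 3.0)
        assert res.consensus_cells().all()

    def test_disjoint_layers_max_one(self):
        d = make_grid(np.array([[1.0, 0.0], [0.0, 0.0]]))
        c = make_grid(np.array([[0.0, 1.0], [0.0, 0.0]]))
        m = make_grid(np.array([[0.0, 0.0], [1.0, 0.0]]))
        res = consensus_overlap(d, c, m, density_q=90.0, current_q=90.0)
        assert np.nanmax(res.consensus.values) == 1.0
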