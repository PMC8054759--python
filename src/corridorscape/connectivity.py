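"""Corridor inference from seasonal conductance surfaces.

A suitability raster is read as a conductance map: movement through a cell
is easier the more suitable it is.  Three complementary corridor methods run
on the same 8-connected cell graph:

* least-cost paths between every (winter, summer) point pair, aggregated
  into a path-density surface;
* circuit theory — the landscape as a resistor network with current
  injected at the season's start points and drained at its end points;
* a percentile mask of the seasonal suitability itself.

Cells flagged by all three methods form the consensus corridor.

Graph discretization: for neighbouring cells with conductances c_i, c_j at
edge length L (1 rook, √2 diagonal, in cell units), the edge conductance is
``mean(c_i, c_j) / L`` and the traversal cost ``L · mean(1/c_i, 1/c_j)``,
so the least-cost and circuit layers share one symmetric graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

from .errors import (
    EmptyGraphError,
    MissingLayerError,
    NoPathError,
    NoPathsError,
    SingularSystemError,
)
from .errors import DegenerateRangeError
from .raster import RasterGrid
from .spatial_stats import geodesic_km

__all__ = [
    "SEASON_MONTHS",
    "EPSILON_CONDUCTANCE",
    "ConductanceGraph",
    "CorridorResult",
    "seasonal_conductance",
    "build_graph",
    "least_cost_path",
    "lcp_density",
    "solve_current_graph",
    "solve_current",
    "percentile_mask",
    "consensus_overlap",
    "CONDUCTANCE_TRANSFORMS",
]

log = logging.getLogger(__name__)

#: Months averaged into each migration season's conductance surface.
SEASON_MONTHS = {"spring": (3, 4, 5), "fall": (8, 9, 10)}

EPSILON_CONDUCTANCE = 1e-6

#: Optional monotone transforms of the conductance surface.
CONDUCTANCE_TRANSFORMS = {
    "none": lambda x: x,
    "sqrt": np.sqrt,
    "log10": lambda x: np.log10(1.0 + 9.0 * x),
    "ln": lambda x: np.log1p(np.e * x) / np.log1p(np.e),
    "cbrt": np.cbrt,
}


def seasonal_conductance(
    monthly_sdms: dict[int, RasterGrid],
    season: str,
    transform: str = "none",
) -> RasterGrid:
    """Cell-wise mean of the season's three monthly suitability rasters.

    Unmasked cells are floored at ε = 10⁻⁶ so the graph stays connected;
    an optional monotone transform rescales the surface first.
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"season must be one of {sorted(SEASON_MONTHS)}")
    months = SEASON_MONTHS[season]
    missing = [m for m in months if m not in monthly_sdms]
    if missing:
        raise MissingLayerError(f"missing monthly rasters for months {missing}")
    grids = [monthly_sdms[m] for m in months]
    ref = grids[0]
    for g in grids[1:]:
        ref.require_aligned(g, (str(months[0]), g.name))
    mask = np.logical_or.reduce([g.mask for g in grids])
    mean = np.nanmean(np.stack([g.values for g in grids]), axis=0)
    mean = CONDUCTANCE_TRANSFORMS[transform](np.clip(mean, 0.0, None))
    mean = np.maximum(mean, EPSILON_CONDUCTANCE)
    mean[mask] = np.nan
    out = ref.copy(values=mean, name=f"conductance_{season}")
    out.mask = mask
    return out


_OFFSETS = ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0)))


@dataclass
class ConductanceGraph:
    """Node-per-valid-cell weighted graph over a conductance raster.

    Nodes are numbered row-major over valid cells; ``cost`` and
    ``conductance`` are symmetric sparse matrices over nodes.  The class can
    also wrap an explicit edge list (no raster) for closed-form circuit and
    path checks.
    """

    n_nodes: int
    cost: sp.csr_matrix
    conductance: sp.csr_matrix
    grid: RasterGrid | None = None
    node_of: np.ndarray | None = None  # grid -> node index, -1 where invalid
    cells: np.ndarray | None = None  # node -> (row, col)

    @classmethod
    def from_raster(cls, conductance: RasterGrid) -> "ConductanceGraph":
        valid = ~conductance.mask & np.isfinite(conductance.values)
        if not valid.any():
            raise EmptyGraphError("every cell of the conductance raster is masked")
        if np.any(conductance.values[valid] <= 0):
            raise ValueError("conductance must be positive on unmasked cells")
        node_of = -np.ones(conductance.shape, dtype=int)
        node_of[valid] = np.arange(int(valid.sum()))
        cells = np.argwhere(valid)
        c = conductance.values
        n_rows, n_cols = conductance.shape
        ii, jj, costs, conds = [], [], [], []
        for dr, dc, length in _OFFSETS:
            a_sl = (slice(0, n_rows - dr), slice(max(0, -dc), min(n_cols, n_cols - dc)))
            b_sl = (slice(dr, n_rows), slice(max(0, dc), min(n_cols, n_cols + dc)))
            ok = valid[a_sl] & valid[b_sl]
            ca, cb = c[a_sl][ok], c[b_sl][ok]
            i, j = node_of[a_sl][ok], node_of[b_sl][ok]
            cost = length * 0.5 * (1.0 / ca + 1.0 / cb)
            cond = 0.5 * (ca + cb) / length
            ii.append(i)
            jj.append(j)
            costs.append(cost)
            conds.append(cond)
        n = int(valid.sum())
        if ii:
            i = np.concatenate(ii)
            j = np.concatenate(jj)
            w = np.concatenate(costs)
            g = np.concatenate(conds)
            cost_m = sp.csr_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
            cond_m = sp.csr_matrix((np.r_[g, g], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
        else:
            cost_m = sp.csr_matrix((n, n))
            cond_m = sp.csr_matrix((n, n))
        return cls(
            n_nodes=n,
            cost=cost_m,
            conductance=cond_m,
            grid=conductance,
            node_of=node_of,
            cells=cells,
        )

    @classmethod
    def from_edges(
        cls, n_nodes: int, edges: list[tuple[int, int, float, float]]
    ) -> "ConductanceGraph":
        """Build from explicit (i, j, conductance, cost) edges (tests, closed forms)."""
        i = np.array([e[0] for e in edges], dtype=int)
        j = np.array([e[1] for e in edges], dtype=int)
        g = np.array([e[2] for e in edges], dtype=float)
        w = np.array([e[3] for e in edges], dtype=float)
        cost_m = sp.csr_matrix(
            (np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n_nodes, n_nodes)
        )
        cond_m = sp.csr_matrix(
            (np.r_[g, g], (np.r_[i, j], np.r_[j, i])), shape=(n_nodes, n_nodes)
        )
        return cls(n_nodes=n_nodes, cost=cost_m, conductance=cond_m)

    def node_at(self, row: int, col: int) -> int:
        if self.node_of is None:
            raise ValueError("graph has no raster geometry")
        shape = self.node_of.shape
        if not (0 <= row < shape[0] and 0 <= col < shape[1]):
            return -1
        return int(self.node_of[row, col])


def build_graph(conductance: RasterGrid) -> ConductanceGraph:
    """8-connected conductance graph of a raster (see module docstring)."""
    return ConductanceGraph.from_raster(conductance)


def _reconstruct_path(graph: ConductanceGraph, dist: np.ndarray, dst: int) -> list[int]:
    """Walk back from dst along tight edges, choosing the lowest node index.

    An edge (u, v) is tight when dist[u] + w(u, v) equals dist[v]; among
    tight predecessors the smallest node index wins, which makes the
    returned path deterministic regardless of heap order.
    """
    indptr, indices, data = graph.cost.indptr, graph.cost.indices, graph.cost.data
    path = [dst]
    v = dst
    while dist[v] > 0:
        best = -1
        lo, hi = indptr[v], indptr[v + 1]
        for u, w in zip(indices[lo:hi], data[lo:hi]):
            if dist[u] < dist[v] and abs(dist[u] + w - dist[v]) <= 1e-9 * (1.0 + dist[v]):
                if best < 0 or u < best:
                    best = int(u)
        if best < 0:  # numerical dead end: fall back to steepest descent
            u_all = indices[lo:hi]
            best = int(u_all[np.argmin(dist[u_all] + data[lo:hi])])
        path.append(best)
        v = best
    path.reverse()
    return path


def least_cost_path(
    graph: ConductanceGraph, src: tuple[int, int], dst: tuple[int, int]
) -> tuple[list[tuple[int, int]], float]:
    """Dijkstra least-cost path between two cells.

    Returns (path as list of (row, col) cells, accumulated cost); ties break
    toward the lexicographically smallest node index.  src == dst gives an
    empty path at zero cost.
    """
    s = graph.node_at(*src)
    d = graph.node_at(*dst)
    if s < 0 or d < 0:
        raise NoPathError(f"endpoint {src if s < 0 else dst} is masked or out of range")
    if s == d:
        return [], 0.0
    dist = dijkstra(graph.cost, directed=False, indices=s)
    if not np.isfinite(dist[d]):
        raise NoPathError(f"no path from {src} to {dst}")
    nodes = _reconstruct_path(graph, dist, d)
    cells = [tuple(graph.cells[n]) for n in nodes]
    return cells, float(dist[d])


def _point_cells(graph: ConductanceGraph, table: pd.DataFrame) -> list[tuple[int, tuple[float, float]]]:
    """Map point rows to (node, cell-centre lon/lat), skipping masked points."""
    out = []
    skipped = 0
    for lon, lat in zip(table["lon"].to_numpy(), table["lat"].to_numpy()):
        r, c = graph.grid.cell_of(float(lon), float(lat))
        node = graph.node_at(r, c)
        if node < 0:
            skipped += 1
            continue
        out.append((node, graph.grid.center_of(r, c)))
    if skipped:
        log.info("skipped %d endpoints on masked/out-of-range cells", skipped)
    return out


def lcp_density(
    graph: ConductanceGraph,
    winter: pd.DataFrame,
    summer: pd.DataFrame,
) -> tuple[pd.DataFrame, RasterGrid, list[np.ndarray]]:
    """All-pairs least-cost paths and the per-cell path-count density.

    One path per (winter, summer) pair; density(cell) = number of paths
    traversing the cell (each path counts a cell once).  Returns the path
    table (cost, great-circle straight distance, along-path ground distance,
    all in km where applicable), the density raster, and each path's
    cell-centre (lon, lat) polyline in table order.
    """
    if graph.grid is None:
        raise ValueError("lcp_density requires a raster-backed graph")
    w_pts = _point_cells(graph, winter)
    s_pts = _point_cells(graph, summer)
    if not w_pts or not s_pts:
        raise NoPathsError("no usable winter/summer endpoints")
    density = np.zeros(graph.grid.shape)
    rows = []
    coords: list[np.ndarray] = []
    pair_id = 0
    centers = graph.cells  # node -> (row, col)
    lon_of = graph.grid.origin_lon + (centers[:, 1] + 0.5) * graph.grid.cell_size
    lat_of = graph.grid.origin_lat - (centers[:, 0] + 0.5) * graph.grid.cell_size
    # one Dijkstra per distinct winter node serves all its pairs
    by_node: dict[int, tuple[float, float]] = {}
    for node, center in w_pts:
        by_node.setdefault(node, center)
    n_ok = 0
    for w_node, w_center in by_node.items():
        dist = dijkstra(graph.cost, directed=False, indices=w_node)
        n_pairs_here = sum(1 for n, _ in w_pts if n == w_node)
        for s_node, s_center in s_pts:
            for _ in range(n_pairs_here):
                pair_id += 1
                if not np.isfinite(dist[s_node]):
                    log.info("unreachable pair %d", pair_id)
                    continue
                if s_node == w_node:
                    nodes = [w_node]
                else:
                    nodes = _reconstruct_path(graph, dist, s_node)
                cells = centers[nodes]
                density[cells[:, 0], cells[:, 1]] += 1
                lons, lats = lon_of[nodes], lat_of[nodes]
                path_km = (
                    float(np.sum(geodesic_km(lons[:-1], lats[:-1], lons[1:], lats[1:])))
                    if len(nodes) > 1
                    else 0.0
                )
                rows.append(
                    {
                        "pair_id": pair_id,
                        "src_lon": w_center[0],
                        "src_lat": w_center[1],
                        "dst_lon": s_center[0],
                        "dst_lat": s_center[1],
                        "cost": float(dist[s_node]),
                        "straight_km": geodesic_km(
                            w_center[0], w_center[1], s_center[0], s_center[1]
                        ),
                        "path_km": path_km,
                    }
                )
                coords.append(np.column_stack([lons, lats]))
                n_ok += 1
    if n_ok == 0:
        raise NoPathsError("no (winter, summer) pair produced a path")
    out = graph.grid.copy(values=density, name="lcp_density")
    out.values[out.mask] = np.nan
    return pd.DataFrame(rows), out, coords


def solve_current_graph(
    graph: ConductanceGraph,
    sources: list[int],
    grounds: list[int],
    injection: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the Kirchhoff system on a conductance graph.

    Grounds are fixed at potential 0 and the total ``injection`` current is
    split equally across sources.  Returns (node potentials, node currents),
    node current being half the sum of absolute incident edge currents.
    """
    if not sources or not grounds:
        raise ValueError("sources and grounds must be non-empty")
    if set(sources) & set(grounds):
        raise ValueError("sources and grounds must be disjoint")
    n = graph.n_nodes
    n_comp, labels = connected_components(graph.conductance, directed=False)
    ground_comps = {labels[g] for g in grounds}
    if any(labels[s] not in ground_comps for s in sources):
        raise SingularSystemError("a source is disconnected from every ground")
    deg = np.asarray(graph.conductance.sum(axis=1)).ravel()
    lap = sp.diags(deg) - graph.conductance
    keep = np.ones(n, dtype=bool)
    keep[list(grounds)] = False
    b = np.zeros(n)
    b[list(sources)] = injection / len(sources)
    lap_red = lap[keep][:, keep].tocsc()
    v = np.zeros(n)
    v[keep] = sp.linalg.spsolve(lap_red, b[keep])
    # node current: half the absolute edge currents incident to each node
    coo = sp.triu(graph.conductance, k=1).tocoo()
    currents = np.zeros(n)
    flow = coo.data * (v[coo.row] - v[coo.col])
    np.add.at(currents, coo.row, np.abs(flow))
    np.add.at(currents, coo.col, np.abs(flow))
    return v, 0.5 * currents


def solve_current(
    conductance: RasterGrid,
    sources: list[tuple[int, int]],
    grounds: list[tuple[int, int]],
    injection: float = 1.0,
) -> RasterGrid:
    """Circuit-theory current map of a conductance raster.

    Sources/grounds are (row, col) cells; see :func:`solve_current_graph`.
    """
    graph = build_graph(conductance)
    src = [graph.node_at(r, c) for r, c in sources]
    gnd = [graph.node_at(r, c) for r, c in grounds]
    if any(s < 0 for s in src) or any(g < 0 for g in gnd):
        raise ValueError("a source or ground cell is masked or out of range")
    _, currents = solve_current_graph(graph, src, gnd, injection)
    out_vals = np.full(conductance.shape, np.nan)
    out_vals[graph.cells[:, 0], graph.cells[:, 1]] = currents
    out = conductance.copy(values=out_vals, name="current_map")
    return out


def percentile_mask(suitability: RasterGrid, q: float = 95.0) -> RasterGrid:
    """Binary raster: 1 where the value reaches the q-th percentile of valid cells."""
    vals = suitability.valid_values()
    vals = vals[~np.isnan(vals)]
    if len(np.unique(vals)) < 2:
        raise DegenerateRangeError("raster has fewer than 2 distinct valid values")
    thr = np.percentile(vals, q)
    out_vals = np.where(suitability.values >= thr, 1.0, 0.0)
    out_vals[suitability.mask] = np.nan
    out = suitability.copy(values=out_vals, name=f"percentile_{q:g}_mask")
    return out


@dataclass
class CorridorResult:
    """Per-method corridor surfaces and their consensus."""

    lcp_density: RasterGrid
    current_map: RasterGrid
    percentile_mask: RasterGrid
    consensus: RasterGrid
    density_threshold: float
    current_threshold: float
    paths: pd.DataFrame | None = None

    def consensus_cells(self) -> np.ndarray:
        """Boolean grid of cells where all three methods agree."""
        return np.nan_to_num(self.consensus.values, nan=0.0) == 3


def consensus_overlap(
    density: RasterGrid,
    current: RasterGrid,
    mask: RasterGrid,
    density_q: float = 95.0,
    current_q: float = 95.0,
    paths: pd.DataFrame | None = None,
) -> CorridorResult:
    """Count, per cell, how many of the three corridor methods flag it.

    Density and current are binarized at their own percentile thresholds;
    the suitability percentile mask is used as given.  consensus ∈ {0..3};
    cells at 3 are the candidate corridors.
    """
    density.require_aligned(current, ("density", "current"))
    density.require_aligned(mask, ("density", "mask"))
    dens_vals = density.valid_values()
    cur_vals = current.valid_values()
    d_thr = float(np.percentile(dens_vals[~np.isnan(dens_vals)], density_q))
    c_thr = float(np.percentile(cur_vals[~np.isnan(cur_vals)], current_q))
    d_bin = np.where(density.values >= d_thr, 1.0, 0.0)
    c_bin = np.where(current.values >= c_thr, 1.0, 0.0)
    m_bin = np.nan_to_num(mask.values, nan=0.0)
    combined_mask = density.mask | current.mask | mask.mask
    total = d_bin + c_bin + m_bin
    total[combined_mask] = np.nan
    consensus = density.copy(values=total, name="consensus")
    consensus.mask = combined_mask
    return CorridorResult(
        lcp_density=density,
        current_map=current,
        percentile_mask=mask,
        consensus=consensus,
        density_threshold=d_thr,
        current_threshold=c_thr,
        paths=paths,
    )
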