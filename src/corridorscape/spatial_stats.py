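"""Spatial clustering statistics and path-length tests.

Moran's I and Geary's C quantify whether a corridor surface (typically the
least-cost-path density raster) is positively clustered in space, as a real
migratory corridor should be; significance comes from a permutation test.
A one-sided paired t-test asks whether least-cost ground distances exceed
the straight-line (great-circle) distances between the same endpoint pairs,
i.e. whether the inferred routes detour around structure in the landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .errors import UndefinedStatisticError
from .raster import RasterGrid

__all__ = [
    "SpatialWeights",
    "ClusterStats",
    "morans_i",
    "gearys_c",
    "permutation_test",
    "cluster_stats",
    "paired_increase_test",
    "geodesic_km",
    "seasonal_similarity",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class SpatialWeights:
    """Binary contiguity weights over the valid cells of a grid.

    ``adjacency`` is a symmetric sparse 0/1 matrix over valid cells
    (row-major order), with zero diagonal; ``W`` is the total weight summed
    over ordered pairs.
    """

    adjacency: sp.csr_matrix
    valid: np.ndarray  # boolean grid mask of the cells the weights cover

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def W(self) -> float:
        return float(self.adjacency.sum())

    @classmethod
    def contiguity(cls, grid_or_mask, scheme: str = "queen") -> "SpatialWeights":
        """Rook (4-neighbour) or queen (8-neighbour) contiguity weights."""
        if isinstance(grid_or_mask, RasterGrid):
            valid = ~grid_or_mask.mask
        else:
            valid = np.asarray(grid_or_mask, dtype=bool)
        if scheme == "rook":
            offsets = [(0, 1), (1, 0)]
        elif scheme == "queen":
            offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
        else:
            raise ValueError(f"unknown contiguity scheme {scheme!r}")
        n_rows, n_cols = valid.shape
        node = -np.ones(valid.shape, dtype=int)
        node[valid] = np.arange(valid.sum())
        rows, cols = [], []
        for dr, dc in offsets:
            a_sl = (slice(0, n_rows - dr), slice(max(0, -dc), min(n_cols, n_cols - dc)))
            b_sl = (slice(dr, n_rows), slice(max(0, dc), min(n_cols, n_cols + dc)))
            ok = valid[a_sl] & valid[b_sl]
            i = node[a_sl][ok]
            j = node[b_sl][ok]
            rows.extend([i, j])
            cols.extend([j, i])
        n = int(valid.sum())
        if rows:
            r = np.concatenate(rows)
            c = np.concatenate(cols)
            adj = sp.csr_matrix((np.ones(len(r)), (r, c)), shape=(n, n))
        else:
            adj = sp.csr_matrix((n, n))
        return cls(adjacency=adj, valid=valid)


def _values_vector(values, weights: SpatialWeights) -> np.ndarray:
    if isinstance(values, RasterGrid):
        x = values.values[weights.valid]
    else:
        x = np.asarray(values, dtype=float)
    if len(x) != weights.n:
        raise ValueError("values do not match the weights' valid cells")
    if len(x) < 2:
        raise UndefinedStatisticError("need at least 2 valid cells")
    if np.all(x == x[0]):
        raise UndefinedStatisticError("zero variance: statistic undefined")
    return x


def morans_i(values, weights: SpatialWeights) -> float:
    """Global Moran's I: I = (N/W) Σ wᵢⱼ zᵢ zⱼ / Σ zᵢ² with z = x − mean."""
    x = _values_vector(values, weights)
    z = x - x.mean()
    num = float(z @ (weights.adjacency @ z))
    return (len(x) / weights.W) * num / float(z @ z)


def gearys_c(values, weights: SpatialWeights) -> float:
    """Global Geary's C: C = ((N−1)/2W) Σ wᵢⱼ (xᵢ−xⱼ)² / Σ zᵢ²."""
    x = _values_vector(values, weights)
    z = x - x.mean()
    row_w = np.asarray(weights.adjacency.sum(axis=1)).ravel()
    # Σ wᵢⱼ (xᵢ−xⱼ)² = 2 Σ wᵢ· xᵢ² − 2 Σ wᵢⱼ xᵢxⱼ for symmetric binary w
    sq = 2.0 * float(row_w @ (x**2)) - 2.0 * float(x @ (weights.adjacency @ x))
    return ((len(x) - 1) / (2.0 * weights.W)) * sq / float(z @ z)


def permutation_test(
    statistic_fn,
    values,
    weights: SpatialWeights,
    n_perm: int = 99,
    seed: int = 0,
    direction: str = "auto",
) -> tuple[float, float]:
    """One-sided permutation p-value for a clustering statistic.

    Values are permuted over the valid cells; "more clustered" means a
    higher Moran's I or a lower Geary's C.  With ``direction='auto'`` the
    orientation is taken from the statistic function (``gearys_c`` → lower).
    Returns (observed statistic, p) with the +1 permutation estimator
    p = (1 + #{permutations at least as clustered}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    if direction == "auto":
        direction = "lower" if statistic_fn is gearys_c else "higher"
    x = _values_vector(values, weights)
    observed = statistic_fn(x, weights)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = statistic_fn(rng.permutation(x), weights)
        if (direction == "higher" and perm >= observed) or (
            direction == "lower" and perm <= observed
        ):
            count += 1
    return observed, (1 + count) / (n_perm + 1)


@dataclass(frozen=True)
class ClusterStats:
    morans_i: float
    morans_p: float
    gearys_c: float
    gearys_p: float
    n_permutations: int
    seed: int


def cluster_stats(
    values, weights: SpatialWeights, n_perm: int = 99, seed: int = 0
) -> ClusterStats:
    """Moran's I and Geary's C with permutation p-values, one call."""
    i_obs, i_p = permutation_test(morans_i, values, weights, n_perm, seed)
    c_obs, c_p = permutation_test(gearys_c, values, weights, n_perm, seed + 1)
    return ClusterStats(i_obs, i_p, c_obs, c_p, n_perm, seed)


def paired_increase_test(path_km, straight_km) -> dict:
    """One-sided paired t-test of mean(path − straight) > 0.

    Returns mean_increase, t, df, p and a ``degenerate`` flag for the
    zero-variance cases (all differences equal).
    """
    d = np.asarray(path_km, dtype=float) - np.asarray(straight_km, dtype=float)
    if len(np.asarray(path_km)) != len(np.asarray(straight_km)):
        raise ValueError("paired vectors must have equal length")
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        if mean == 0:
            return {"mean_increase": 0.0, "t": 0.0, "df": df, "p": 0.5, "degenerate": True}
        t = np.inf if mean > 0 else -np.inf
        return {"mean_increase": mean, "t": float(t), "df": df,
                "p": 0.0 if mean > 0 else 1.0, "degenerate": True}
    t = mean / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df))
    return {"mean_increase": mean, "t": float(t), "df": df, "p": p, "degenerate": False}


def geodesic_km(lon1, lat1, lon2, lat2) -> float | np.ndarray:
    """Great-circle (haversine) distance in km, sphere radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    out = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def seasonal_similarity(a: RasterGrid, b: RasterGrid) -> float:
    """Pearson r between two seasonal suitability rasters on shared valid cells.

    A non-migratory (stationary) niche keeps winter and summer surfaces
    similar; a shifting niche drives the correlation down.
    """
    a.require_aligned(b, (a.name or "a", b.name or "b"))
    shared = ~(a.mask | b.mask | np.isnan(a.values) | np.isnan(b.values))
    if shared.sum() < 3:
        raise ValueError("need at least 3 shared valid cells")
    xa, xb = a.values[shared], b.values[shared]
    if xa.std() == 0 or xb.std() == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    return float(np.corrcoef(xa, xb)[0, 1])
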