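"""Synthetic landscapes with a known seasonal niche and a planted corridor.

This module is the ground-truth side of the pipeline: it builds monthly
environmental predictor stacks (nine layers mirroring a typical continental
SDM roster), a true suitability surface driven by a Gaussian thermal niche
whose optimum moves through the year, and presence-only samples with the
kind of spatial sampling bias found in aggregated museum/citizen-science
records.  Because the niche and the corridor are planted, every downstream
stage (model fitting, ensembles, corridor inference) can be tested against
known truth.

The planted corridor is an environmental feature, not just a label: along a
polyline the vegetation index is raised and elevation lowered (a vegetated
low valley), and true suitability gets an additive boost there.  Models can
therefore recover the corridor from the predictors alone, which is the
property the recovery tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

from .errors import ConfigurationError, DegenerateWeightsError, MissingLayerError
from .raster import RasterGrid

__all__ = [
    "DEFAULT_LAYERS",
    "EnvStackSpec",
    "NicheSpec",
    "generate_env_stack",
    "true_suitability",
    "sample_occurrences",
    "default_bias",
    "corridor_cell_mask",
    "study_specs",
]

#: The nine predictor layers of the emulated continental stack.
DEFAULT_LAYERS = (
    "precipitation",
    "solar_radiation",
    "avg_temperature",
    "vapor_pressure",
    "wind_speed",
    "human_influence",
    "elevation",
    "ndvi",
    "forest_cover",
)

# Per-layer (base level, per-row southward gradient, seasonal amplitude,
# noise sd) in the layer's natural units.  Static layers (elevation, forest
# cover, human influence) have zero amplitude; their noise field is seeded
# per layer only, so they are identical across months.
_LAYER_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "precipitation": (60.0, 0.5, 20.0, 8.0),
    "solar_radiation": (15000.0, 25.0, 4000.0, 300.0),
    "avg_temperature": (10.0, 0.2, 8.0, 0.5),
    "vapor_pressure": (1.0, 0.01, 0.4, 0.05),
    "wind_speed": (4.0, -0.01, 0.5, 0.4),
    "human_influence": (20.0, 0.1, 0.0, 5.0),
    "elevation": (400.0, 0.0, 0.0, 150.0),
    "ndvi": (0.5, -0.002, 0.15, 0.05),
    "forest_cover": (40.0, -0.2, 0.0, 10.0),
}

_BASES = ("Human Observation", "Preserved Specimen", "Material Sample")


@dataclass
class EnvStackSpec:
    """Geometry and statistical recipe for the monthly predictor stacks."""

    n_rows: int = 60
    n_cols: int = 60
    cell_size_deg: float = 0.25
    origin_lon: float = -100.0
    origin_lat: float = 50.0
    layer_names: tuple[str, ...] = DEFAULT_LAYERS
    base_level: dict[str, float] = field(default_factory=dict)
    spatial_gradient: dict[str, float] = field(default_factory=dict)
    seasonal_amplitude: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    #: optional environmental signature of the corridor: additive offset per layer
    corridor_polyline: tuple[tuple[float, float], ...] | None = None
    corridor_width_cells: int = 3
    corridor_layer_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 4 or self.n_cols < 4:
            raise ConfigurationError("grid must be at least 4x4")
        if self.cell_size_deg <= 0:
            raise ConfigurationError("cell_size_deg must be positive")
        for name in self.layer_names:
            base, grad, amp, sd = _LAYER_DEFAULTS.get(name, (0.0, 0.0, 0.0, 1.0))
            self.base_level.setdefault(name, base)
            self.spatial_gradient.setdefault(name, grad)
            self.seasonal_amplitude.setdefault(name, amp)
            self.noise_sd.setdefault(name, sd)

    def blank_grid(self, name: str = "") -> RasterGrid:
        return RasterGrid(
            values=np.zeros((self.n_rows, self.n_cols)),
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size_deg,
            name=name,
        )


@dataclass
class NicheSpec:
    """A Gaussian thermal niche with a monthly moving optimum and a corridor.

    ``optimum_by_month[m-1]`` is the optimal temperature in month ``m``;
    ``tolerance`` is the niche breadth (same units as the temperature layer).
    Cells within ``corridor_width_cells`` of the corridor polyline receive an
    additive suitability boost, and the whole surface is capped at
    ``max_suitability``.
    """

    optimum_by_month: Sequence[float]
    tolerance: float = 1.0
    corridor_polyline: tuple[tuple[float, float], ...] | None = None
    corridor_width_cells: int = 3
    corridor_boost: float = 0.0
    max_suitability: float = 1.0
    temperature_layer: str = "avg_temperature"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")
        if not (0.0 <= self.corridor_boost <= 1.0):
            raise ConfigurationError("corridor_boost must lie in [0, 1]")
        if not (0.0 <= self.max_suitability <= 1.0):
            raise ConfigurationError("max_suitability must lie in [0, 1]")
        if len(self.optimum_by_month) != 12:
            raise ConfigurationError("optimum_by_month needs 12 entries")


def _seasonal_factor(month: int) -> float:
    """Cosine annual cycle peaking at month 7 (July)."""
    return float(np.cos(2.0 * np.pi * (month - 7) / 12.0))


def _smoothed_noise(shape: tuple[int, int], sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field: white noise blurred 1 cell, rescaled to sd."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=1.0, mode="reflect")
    s = smooth.std()
    if s > 0:
        smooth = smooth * (sd / s)
    return smooth


def corridor_cell_mask(
    grid: RasterGrid,
    polyline: Sequence[tuple[float, float]],
    width_cells: int,
) -> np.ndarray:
    """Boolean array of cells whose centre lies within the corridor buffer.

    The corridor is the polyline buffered by ``width_cells / 2`` cell widths,
    so the band is roughly ``width_cells`` cells across.
    """
    line = LineString(polyline)
    buf = line.buffer(0.5 * width_cells * grid.cell_size)
    lon, lat = grid.cell_centers()
    return shapely.contains_xy(buf, lon.ravel(), lat.ravel()).reshape(grid.shape)


def generate_env_stack(spec: EnvStackSpec, month: int) -> dict[str, RasterGrid]:
    """Generate the predictor stack for one month.

    Each layer is ``base + gradient * row + amplitude * cos-cycle + noise``
    (row 0 = north), where the noise is a spatially autocorrelated Gaussian
    field seeded per layer so that zero-amplitude layers are static across
    months.  Deterministic for a given ``spec.seed``.
    """
    if not 1 <= month <= 12:
        raise ConfigurationError(f"month must be in 1..12, got {month}")
    rows = np.arange(spec.n_rows, dtype=float)[:, None]
    season = _seasonal_factor(month)
    corridor = None
    if spec.corridor_polyline is not None and spec.corridor_layer_effects:
        corridor = corridor_cell_mask(
            spec.blank_grid(), spec.corridor_polyline, spec.corridor_width_cells
        )
    stack: dict[str, RasterGrid] = {}
    for idx, name in enumerate(spec.layer_names):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))
        values = (
            spec.base_level[name]
            + spec.spatial_gradient[name] * rows
            + spec.seasonal_amplitude[name] * season
            + _smoothed_noise((spec.n_rows, spec.n_cols), spec.noise_sd[name], rng)
        )
        values = np.broadcast_to(values, (spec.n_rows, spec.n_cols)).copy()
        if corridor is not None and name in spec.corridor_layer_effects:
            values[corridor] += spec.corridor_layer_effects[name]
        grid = spec.blank_grid(name)
        grid.values = values
        stack[name] = grid
    return stack


def true_suitability(
    stack: dict[str, RasterGrid], niche: NicheSpec, month: int
) -> RasterGrid:
    """Ground-truth suitability for one month.

    Gaussian kernel of the temperature layer around the month's optimum,
    plus the corridor boost, capped at ``max_suitability``; values in [0, 1].
    """
    if niche.temperature_layer not in stack:
        raise MissingLayerError(
            f"stack lacks temperature layer {niche.temperature_layer!r}"
        )
    temp = stack[niche.temperature_layer]
    opt = niche.optimum_by_month[month - 1]
    suit = np.exp(-((temp.values - opt) ** 2) / (2.0 * niche.tolerance**2))
    if niche.corridor_polyline is not None and niche.corridor_boost > 0:
        inside = corridor_cell_mask(temp, niche.corridor_polyline, niche.corridor_width_cells)
        suit = suit + niche.corridor_boost * inside
    suit = np.clip(suit, 0.0, niche.max_suitability)
    out = temp.copy(values=suit, name="true_suitability")
    out.values[out.mask] = np.nan
    return out


def default_bias(grid: RasterGrid, sharpness: float = 8.0) -> RasterGrid:
    """Logistic sampling-effort gradient increasing toward the east edge.

    Emulates the institutional spatial bias of aggregated occurrence
    archives: effort rises smoothly from one side of the map to the other.
    """
    cols = np.arange(grid.n_cols, dtype=float)
    mid = (grid.n_cols - 1) / 2.0
    scale = grid.n_cols / sharpness
    bias_row = 1.0 / (1.0 + np.exp(-(cols - mid) / scale))
    bias = np.broadcast_to(bias_row, grid.shape).copy()
    return grid.copy(values=bias, name="sampling_bias")


def sample_occurrences(
    suit: RasterGrid,
    n: int,
    bias: RasterGrid | None,
    seed: int,
    month: int,
    species: str = "Synthetus migrans",
    year: int = 2015,
) -> pd.DataFrame:
    """Draw ``n`` presence-only points with probability ∝ suitability × bias.

    Points are jittered uniformly within their cell and labelled with the
    month and a calendar date; deterministic for a given seed.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    weights = np.where(suit.mask, 0.0, suit.values)
    if bias is not None:
        suit.require_aligned(bias, ("suitability", "bias"))
        weights = weights * np.where(bias.mask, 0.0, bias.values)
    weights = np.nan_to_num(weights, nan=0.0)
    total = weights.sum()
    if total <= 0:
        raise DegenerateWeightsError("all sampling weights are zero")
    rng = np.random.default_rng(seed)
    flat = weights.ravel() / total
    cells = rng.choice(flat.size, size=n, p=flat)
    row, col = np.unravel_index(cells, suit.shape)
    jitter_lon = rng.uniform(0.0, 1.0, size=n)
    jitter_lat = rng.uniform(0.0, 1.0, size=n)
    lon = suit.origin_lon + (col + jitter_lon) * suit.cell_size
    lat = suit.origin_lat - (row + jitter_lat) * suit.cell_size
    return pd.DataFrame(
        {
            "species": species,
            "lon": lon,
            "lat": lat,
            "year": year,
            "month": month,
            "day": rng.integers(1, 29, size=n),
            "basis_of_record": rng.choice(_BASES, size=n),
        }
    )


def study_specs(
    n_rows: int = 60,
    n_cols: int = 60,
    cell_size_deg: float = 0.25,
    corridor_boost: float = 0.3,
    noise_sd: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[EnvStackSpec, NicheSpec]:
    """The default synthetic study: a seasonally shifting niche + corridor.

    Temperature runs warmer southward (0.2 °C per row) with an 8 °C annual
    cycle; the monthly thermal optimum is chosen so the suitable band sits in
    the south of the map in winter and in the north in summer, moving
    smoothly between.  A three-cell-wide corridor runs north–south through
    the middle of the map as a vegetated low valley (NDVI +0.2,
    elevation −300 m) with a matching additive suitability boost.
    """
    env = EnvStackSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_deg=cell_size_deg,
        seed=seed,
    )
    if noise_sd:
        env.noise_sd.update(noise_sd)
    lon_mid = env.origin_lon + 0.5 * n_cols * cell_size_deg
    lat_top = env.origin_lat - 1.5 * cell_size_deg
    lat_bot = env.origin_lat - (n_rows - 1.5) * cell_size_deg
    polyline = ((lon_mid, lat_bot), (lon_mid, lat_top))
    env.corridor_polyline = polyline
    env.corridor_layer_effects = {"ndvi": 0.2, "elevation": -300.0}
    # optimum tracks a band moving from ~80% of the way south (January) to
    # ~17% of the way north (July): row_m = r_mid - r_amp * cos-cycle.
    base = env.base_level["avg_temperature"]
    grad = env.spatial_gradient["avg_temperature"]
    amp = env.seasonal_amplitude["avg_temperature"]
    r_mid, r_amp = 0.48 * n_rows, 0.315 * n_rows
    optima = []
    for m in range(1, 13):
        c = _seasonal_factor(m)
        row_m = r_mid - r_amp * c
        optima.append(base + grad * row_m + amp * c)
    niche = NicheSpec(
        optimum_by_month=optima,
        tolerance=1.0,
        corridor_polyline=polyline,
        corridor_width_cells=3,
        corridor_boost=corridor_boost,
        max_suitability=1.0,
    )
    return env, niche
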