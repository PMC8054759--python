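"""Cleaning, spatial thinning, seasonal partitioning and fold assignment
for presence-only occurrence records.

Occurrence tables are plain :class:`pandas.DataFrame` objects with columns
``species, lon, lat, year, month, day, basis_of_record`` (plus a derived
``season`` column after :func:`assign_season`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientBackgroundError, SchemaError
from .raster import RasterGrid

__all__ = [
    "REQUIRED_COLUMNS",
    "DEFAULT_BASES",
    "SEASON_OF_MONTH",
    "FoldAssignment",
    "read_occurrences",
    "write_occurrences",
    "filter_records",
    "grid_thin",
    "assign_season",
    "sample_pseudo_absences",
    "make_folds",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "lon", "lat", "year", "month", "day", "basis_of_record")

#: Record types retained by default (museum specimens, observations, samples).
DEFAULT_BASES = frozenset(
    {"Preserved Specimen", "Human Observation", "Material Sample"}
)

#: Season labels: winter Dec-Feb, spring Mar-May, summer Jun-Jul,
#: fall Aug-Oct; November belongs to no season and stays unassigned.
SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer",
    8: "fall", 9: "fall", 10: "fall",
    11: "unassigned",
}


def _require_columns(df: pd.DataFrame, columns=REQUIRED_COLUMNS) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"occurrence table missing columns: {missing}")


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read an occurrence CSV, rejecting malformed rows with their line numbers.

    Rows with unparsable or out-of-range coordinates/months are dropped and
    logged; a missing header is a :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    _require_columns(df)
    df = df.copy()
    for col in ("lon", "lat", "year", "month", "day"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df["lon"].between(-180, 180)
        & df["lat"].between(-90, 90)
        & (df["month"].isna() | df["month"].between(1, 12))
    )
    bad = df.index[~ok]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based indexing
        log.warning(
            "rejected %d malformed occurrence rows at lines %s",
            len(bad),
            [int(i) + 2 for i in bad[:20]],
        )
    return df[ok].reset_index(drop=True)


def write_occurrences(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def filter_records(
    raw: pd.DataFrame,
    ref_year: int = 2019,
    window_years: int = 50,
    allowed_bases: frozenset[str] | set[str] = DEFAULT_BASES,
) -> pd.DataFrame:
    """Keep clean, recent records of the allowed record types.

    Retains rows with non-missing in-range coordinates that are not the
    (0, 0) "null island" artefact, whose ``basis_of_record`` is allowed, and
    whose year satisfies ``ref_year - window_years < year <= ref_year``;
    exact duplicates on (species, lon, lat, year, month, day) collapse to one.
    """
    _require_columns(raw)
    df = raw.copy()
    keep = (
        df["lon"].notna()
        & df["lat"].notna()
        & df["lon"].between(-180, 180)
        & df["lat"].between(-90, 90)
        & ~((df["lon"] == 0) & (df["lat"] == 0))
        & df["basis_of_record"].isin(allowed_bases)
        & df["year"].notna()
        & (df["year"] > ref_year - window_years)
        & (df["year"] <= ref_year)
    )
    df = df[keep]
    df = df.drop_duplicates(subset=["species", "lon", "lat", "year", "month", "day"])
    return df.reset_index(drop=True)


def grid_thin(points: pd.DataFrame, cell_deg: float = 1.0) -> pd.DataFrame:
    """Subsample to at most one record per ``cell_deg``° grid cell.

    The grid is anchored at integer multiples of ``cell_deg``; the first
    record in input order wins a cell.  Idempotent.
    """
    if cell_deg <= 0:
        raise ValueError("cell_deg must be positive")
    if len(points) == 0:
        return points.copy()
    cx = np.floor(points["lon"].to_numpy() / cell_deg).astype(int)
    cy = np.floor(points["lat"].to_numpy() / cell_deg).astype(int)
    key = pd.DataFrame({"cx": cx, "cy": cy}, index=points.index)
    first = ~key.duplicated(keep="first")
    return points[first.to_numpy()].reset_index(drop=True)


def assign_season(points: pd.DataFrame) -> pd.DataFrame:
    """Attach the seasonal label derived from the month column."""
    months = points["month"]
    bad = months.isna() | ~months.isin(range(1, 13))
    if bad.any():
        raise ValueError(
            f"month outside 1..12 in {int(bad.sum())} rows; cannot assign seasons"
        )
    out = points.copy()
    out["season"] = months.astype(int).map(SEASON_OF_MONTH)
    return out


def sample_pseudo_absences(
    mask: RasterGrid,
    n: int = 1000,
    exclude: pd.DataFrame | None = None,
    seed: int = 0,
    month: int | None = None,
    species: str = "background",
) -> pd.DataFrame:
    """Draw ``n`` background points at distinct valid cell centres.

    Cells containing any point of *exclude* are never used; the draw is
    uniform without replacement and deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    valid = ~mask.mask
    if exclude is not None and len(exclude):
        for lon, lat in zip(exclude["lon"], exclude["lat"]):
            r, c = mask.cell_of(float(lon), float(lat))
            if 0 <= r < mask.n_rows and 0 <= c < mask.n_cols:
                valid[r, c] = False
    flat = np.flatnonzero(valid.ravel())
    if len(flat) < n:
        raise InsufficientBackgroundError(
            f"requested {n} pseudo-absences but only {len(flat)} valid cells remain"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, mask.shape)
    lon = mask.origin_lon + (cols + 0.5) * mask.cell_size
    lat = mask.origin_lat - (rows + 0.5) * mask.cell_size
    return pd.DataFrame(
        {
            "species": species,
            "lon": lon,
            "lat": lat,
            "year": np.nan,
            "month": month if month is not None else np.nan,
            "day": np.nan,
            "basis_of_record": "pseudo-absence",
        }
    )


@dataclass(frozen=True)
class FoldAssignment:
    """A random k-fold partition; fold ids run 1..k and sizes differ by ≤ 1."""

    folds: np.ndarray
    k: int
    seed: int

    def train_test(self, test_fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (train, test) index masks for one fold held out."""
        test = self.folds == test_fold
        return ~test, test


def make_folds(n_records: int, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Randomly partition ``n_records`` into ``k`` near-equal folds.

    With k = 5 each held-out fold gives the conventional 80% training /
    20% testing split.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_records:
        raise ValueError(f"k={k} exceeds n_records={n_records}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_records)
    folds = np.empty(n_records, dtype=int)
    folds[order] = np.arange(n_records) % k + 1
    return FoldAssignment(folds=folds, k=k, seed=seed)
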