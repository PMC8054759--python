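"""Pairwise predictor correlation and collinearity-driven variable dropping.

Before model fitting, predictors that are highly correlated across the
study grid are pruned: for every pair with |r| above the threshold the
variable ranked lower in a stated preference order is removed.  The
preference order stands in for expert judgement of biological relevance,
which cannot be computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedCorrelationError
from .raster import RasterGrid

__all__ = [
    "DEFAULT_PREFERENCE",
    "CorrelationReport",
    "pairwise_correlation",
    "drop_correlated",
]

#: Default preference order (most preferred first).
DEFAULT_PREFERENCE = (
    "avg_temperature",
    "solar_radiation",
    "vapor_pressure",
    "precipitation",
    "elevation",
    "human_influence",
    "wind_speed",
    "ndvi",
    "forest_cover",
)


@dataclass
class CorrelationReport:
    """Symmetric Pearson correlation matrix over shared valid cells."""

    names: tuple[str, ...]
    matrix: np.ndarray
    dropped: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.names), columns=list(self.names))

    def write(self, matrix_csv: str | Path, drop_json: str | Path) -> None:
        self.to_frame().to_csv(matrix_csv)
        Path(drop_json).write_text(json.dumps(self.dropped, indent=2) + "\n")


def pairwise_correlation(
    stack: dict[str, RasterGrid] | dict[str, np.ndarray]
) -> CorrelationReport:
    """Pearson r between every pair of layers, cell-wise over shared valid cells.

    Accepts either a stack of rasters or a mapping of equal-length value
    vectors (e.g. layers concatenated across months).  A layer with zero
    variance on the shared cells makes its correlations undefined.
    """
    names = tuple(stack)
    if len(names) < 2:
        raise ValueError("need at least two layers")
    columns = []
    masks = []
    for name in names:
        layer = stack[name]
        if isinstance(layer, RasterGrid):
            columns.append(layer.values.ravel())
            masks.append(layer.mask.ravel())
        else:
            arr = np.asarray(layer, dtype=float).ravel()
            columns.append(arr)
            masks.append(np.isnan(arr))
    n = len(columns[0])
    if any(len(c) != n for c in columns):
        raise ValueError("layers differ in size")
    n_layers = len(names)
    mat = np.eye(n_layers)
    for i in range(n_layers):
        for j in range(i + 1, n_layers):
            shared = ~(masks[i] | masks[j])
            if shared.sum() < 3:
                raise ValueError(
                    f"fewer than 3 shared valid cells between {names[i]} and {names[j]}"
                )
            xi, xj = columns[i][shared], columns[j][shared]
            if xi.std() == 0 or xj.std() == 0:
                raise UndefinedCorrelationError(
                    f"zero variance makes r undefined for pair ({names[i]}, {names[j]})"
                )
            r = float(np.corrcoef(xi, xj)[0, 1])
            mat[i, j] = mat[j, i] = r
    return CorrelationReport(names=names, matrix=mat)


def drop_correlated(
    report: CorrelationReport,
    threshold: float = 0.8,
    preference: tuple[str, ...] = DEFAULT_PREFERENCE,
) -> list[str]:
    """Greedily drop the less-preferred member of each pair with |r| > threshold.

    Pairs are processed in descending |r|; once a variable is dropped it takes
    no further part.  Returns the retained names (in report order) and records
    a drop log (dropped variable, retained partner, r) on the report.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    missing = [n for n in report.names if n not in preference]
    if missing:
        raise ConfigurationError(f"variables missing from preference order: {missing}")
    rank = {name: preference.index(name) for name in report.names}
    pairs = []
    n = len(report.names)
    for i in range(n):
        for j in range(i + 1, n):
            r = report.matrix[i, j]
            if abs(r) > threshold:
                pairs.append((abs(r), i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[str] = set()
    report.dropped = []
    for absr, i, j in pairs:
        a, b = report.names[i], report.names[j]
        if a in dropped or b in dropped:
            continue
        loser, winner = (a, b) if rank[a] > rank[b] else (b, a)
        dropped.add(loser)
        report.dropped.append(
            {"dropped": loser, "partner": winner, "r": float(report.matrix[i, j])}
        )
    return [name for name in report.names if name not in dropped]
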