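"""The four presence-background suitability models and raster prediction.

Algorithms
----------
``BC``
    The classic BIOCLIM climate envelope: a new point is scored per
    predictor by how central its value sits within the training presences'
    empirical distribution (tail score ``2·min(p, 1−p)`` with
    ``p = fraction of training values ≤ x``), and overall by the minimum
    across predictors.  Rank-based, hence invariant to monotone transforms
    of any single predictor.
``GLM``
    Logistic regression of presence vs background on standardized
    predictors with quadratic terms, so unimodal (niche-optimum) responses
    are representable.
``MAXENT``
    A maximum-entropy presence-background model in its penalized-logistic
    form: L1-regularized logistic regression on linear + quadratic +
    pairwise-product features of the standardized predictors.
``RF``
    A 500-tree classification random forest scoring by presence-vote
    fraction.

All models score in [0, 1] and are deterministic given their seed.
"""

from __future__ import annotations

import base64
import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .errors import DegenerateDesignError, EmptyDesignError, MissingLayerError
from .raster import RasterGrid

__all__ = [
    "ALGORITHMS",
    "TrainingDesign",
    "FittedSDM",
    "extract_design",
    "fit_bioclim",
    "fit_presence_background",
    "fit_model",
    "predict_raster",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

ALGORITHMS = ("BC", "GLM", "MAXENT", "RF")

_ARCHIVE_VERSION = 1


@dataclass
class TrainingDesign:
    """Presence + background rows with extracted predictor values."""

    X: np.ndarray
    y: np.ndarray
    predictor_names: tuple[str, ...]
    month: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D with one label per row")
        if np.isnan(self.X).any():
            raise ValueError("design contains missing predictor values")

    @property
    def n_presence(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_background(self) -> int:
        return int((self.y == 0).sum())

    def presences(self) -> np.ndarray:
        return self.X[self.y == 1]


def extract_design(
    points: pd.DataFrame,
    absences: pd.DataFrame,
    stack: dict[str, RasterGrid],
    predictor_names: tuple[str, ...] | None = None,
    month: int | None = None,
) -> TrainingDesign:
    """Sample predictor values at presence and background points.

    Rows falling outside the grid or on a masked cell in any predictor are
    dropped with a logged count; an empty presence set after dropping is an
    error.
    """
    names = tuple(predictor_names) if predictor_names else tuple(stack)
    for name in names:
        if name not in stack:
            raise MissingLayerError(f"stack lacks predictor {name!r}")
    ref = stack[names[0]]
    rows, labels, dropped = [], [], 0
    for label, table in ((1, points), (0, absences)):
        for lon, lat in zip(table["lon"].to_numpy(), table["lat"].to_numpy()):
            r, c = ref.cell_of(float(lon), float(lat))
            if not (0 <= r < ref.n_rows and 0 <= c < ref.n_cols):
                dropped += 1
                continue
            vals = [stack[n].values[r, c] for n in names]
            if any(stack[n].mask[r, c] for n in names) or np.isnan(vals).any():
                dropped += 1
                continue
            rows.append(vals)
            labels.append(label)
    if dropped:
        log.info("extract_design dropped %d points on masked/out-of-range cells", dropped)
    y = np.array(labels, dtype=int)
    if (y == 1).sum() == 0:
        raise EmptyDesignError("no usable presence rows after extraction")
    return TrainingDesign(np.array(rows), y, names, month=month)


# -- BIOCLIM ----------------------------------------------------------------


class _Bioclim:
    def __init__(self, presences: np.ndarray) -> None:
        if len(presences) < 2:
            raise ValueError("BIOCLIM needs at least 2 presence rows")
        self.sorted_cols = [np.sort(presences[:, j]) for j in range(presences.shape[1])]

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.ones(len(X))
        for j, col in enumerate(self.sorted_cols):
            n = len(col)
            if col[0] == col[-1]:
                # constant predictor: envelope collapses to a point
                s = np.where(X[:, j] == col[0], 1.0, 0.0)
            else:
                p = np.searchsorted(col, X[:, j], side="right") / n
                s = np.clip(2.0 * np.minimum(p, 1.0 - p), 0.0, 1.0)
            out = np.minimum(out, s)
        return out


# -- presence-background models ---------------------------------------------


class _PBModel:
    """Scaler + feature expansion + classifier, scored by P(presence)."""

    def __init__(self, scaler, expander, clf) -> None:
        self.scaler = scaler
        self.expander = expander
        self.clf = clf

    def _features(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(X) if self.scaler is not None else X
        return self.expander.transform(Z) if self.expander is not None else Z

    def score(self, X: np.ndarray) -> np.ndarray:
        proba = self.clf.predict_proba(self._features(np.asarray(X, dtype=float)))
        return proba[:, list(self.clf.classes_).index(1)]


class _QuadraticFeatures:
    """Main effects + per-predictor squares (no cross terms)."""

    def transform(self, Z: np.ndarray) -> np.ndarray:
        return np.hstack([Z, Z**2])


@dataclass
class FittedSDM:
    """A trained suitability model; ``score`` maps predictor rows to [0, 1]."""

    algorithm: str
    predictor_names: tuple[str, ...]
    impl: object
    month: int | None = None
    seed: int | None = None

    def score(self, X: np.ndarray) -> np.ndarray:
        s = self.impl.score(X)
        return np.clip(s, 0.0, 1.0)


def fit_bioclim(design: TrainingDesign, month: int | None = None) -> FittedSDM:
    """Fit the BIOCLIM envelope on the design's presence rows only."""
    pres = design.presences()
    if len(pres) < 2:
        raise EmptyDesignError("BIOCLIM needs at least 2 presence rows")
    return FittedSDM(
        algorithm="BC",
        predictor_names=design.predictor_names,
        impl=_Bioclim(pres),
        month=month if month is not None else design.month,
    )


def fit_presence_background(
    design: TrainingDesign,
    algorithm: str,
    seed: int = 0,
    maxent_regularization: float = 1.0,
    rf_trees: int = 500,
) -> FittedSDM:
    """Fit GLM, MAXENT or RF on the full presence/background design.

    Perfect separation is handled by the regularization already present in
    each fit; a predictor with zero variance makes the standardized design
    singular and is an error.
    """
    algorithm = algorithm.upper()
    if algorithm not in ("GLM", "MAXENT", "RF"):
        raise ValueError(f"unknown presence-background algorithm {algorithm!r}")
    if design.n_presence == 0 or design.n_background == 0:
        raise DegenerateDesignError("both classes must be present")
    X, y = design.X, design.y
    if algorithm == "RF":
        clf = RandomForestClassifier(
            n_estimators=rf_trees,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(X, y)
        impl = _PBModel(None, None, clf)
    else:
        if np.any(X.std(axis=0) == 0):
            raise DegenerateDesignError("a predictor is constant across the design")
        scaler = StandardScaler().fit(X)
        if algorithm == "GLM":
            expander = _QuadraticFeatures()
            clf = LogisticRegression(C=1e4, max_iter=5000)
        else:  # MAXENT
            expander = PolynomialFeatures(degree=2, include_bias=False)
            expander.fit(scaler.transform(X))
            clf = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / maxent_regularization,
                solver="liblinear",
                random_state=seed,
                max_iter=5000,
            )
        Z = expander.transform(scaler.transform(X))
        clf.fit(Z, y)
        impl = _PBModel(scaler, expander, clf)
    return FittedSDM(
        algorithm=algorithm,
        predictor_names=design.predictor_names,
        impl=impl,
        month=design.month,
        seed=seed,
    )


def fit_model(design: TrainingDesign, algorithm: str, seed: int = 0, **kw) -> FittedSDM:
    """Dispatch on algorithm name (BC, GLM, MAXENT, RF)."""
    if algorithm.upper() == "BC":
        return fit_bioclim(design)
    return fit_presence_background(design, algorithm, seed=seed, **kw)


def predict_raster(model: FittedSDM, stack: dict[str, RasterGrid]) -> RasterGrid:
    """Score every valid cell of the stack; masked cells stay masked."""
    for name in model.predictor_names:
        if name not in stack:
            raise MissingLayerError(f"stack lacks predictor {name!r}")
    layers = [stack[n] for n in model.predictor_names]
    ref = layers[0]
    for g in layers[1:]:
        ref.require_aligned(g, (ref.name, g.name))
    valid = ~np.logical_or.reduce([g.mask for g in layers])
    valid &= ~np.logical_or.reduce([np.isnan(g.values) for g in layers])
    X = np.column_stack([g.values[valid] for g in layers])
    out = np.full(ref.shape, np.nan)
    if valid.any():
        out[valid] = model.score(X)
    result = ref.copy(values=out, name=f"suitability_{model.algorithm.lower()}")
    result.mask = ~valid
    return result


# -- serialization -----------------------------------------------------------


def save_model(path: str | Path, model: FittedSDM) -> None:
    """Serialize to a versioned JSON archive.

    Envelope and BIOCLIM/GLM/MAXENT parameters are plain JSON; the
    random-forest payload is a base64-wrapped joblib blob.
    """
    doc: dict = {
        "format_version": _ARCHIVE_VERSION,
        "algorithm": model.algorithm,
        "predictor_names": list(model.predictor_names),
        "month": model.month,
        "seed": model.seed,
    }
    impl = model.impl
    if model.algorithm == "BC":
        doc["payload"] = {"sorted_cols": [c.tolist() for c in impl.sorted_cols]}
    else:
        buf = io.BytesIO()
        joblib.dump(impl, buf)
        doc["payload"] = {"joblib_b64": base64.b64encode(buf.getvalue()).decode()}
    Path(path).write_text(json.dumps(doc) + "\n")


def load_model(path: str | Path) -> FittedSDM:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version: {doc.get('format_version')}")
    if doc["algorithm"] == "BC":
        impl = _Bioclim.__new__(_Bioclim)
        impl.sorted_cols = [np.asarray(c, dtype=float) for c in doc["payload"]["sorted_cols"]]
    else:
        impl = joblib.load(io.BytesIO(base64.b64decode(doc["payload"]["joblib_b64"])))
    return FittedSDM(
        algorithm=doc["algorithm"],
        predictor_names=tuple(doc["predictor_names"]),
        impl=impl,
        month=doc["month"],
        seed=doc["seed"],
    )
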