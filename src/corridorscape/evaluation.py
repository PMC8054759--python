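"""Model evaluation (AUC, TSS), permutation variable importance,
TSS-weighted ensembling, and raster normalization.

AUC is the rank-based (Mann–Whitney) probability that a random presence
scores above a random background point, ties counted half.  TSS is
sensitivity + specificity − 1 maximized over candidate thresholds.  The
ensemble is a cell-wise weighted mean of per-algorithm suitability rasters
with weights proportional to max(metric, 0): a worse-than-chance model
contributes nothing rather than subtracting signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateRangeError, DegenerateWeightsError
from .raster import AlignmentError, RasterGrid
from .sdm import FittedSDM, TrainingDesign

__all__ = [
    "EvalResult",
    "auc",
    "tss_max",
    "evaluate_model",
    "permutation_importance",
    "ensemble_weighted",
    "normalize_raster",
]


@dataclass(frozen=True)
class EvalResult:
    algorithm: str
    month: int | None
    auc: float
    tss: float
    tss_threshold: float


def auc(scores_presence, scores_background) -> float:
    """Rank-based AUC with ties counted 0.5."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if len(sp) == 0 or len(sb) == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: len(sp)].sum() - len(sp) * (len(sp) + 1) / 2.0
    return float(u / (len(sp) * len(sb)))


def tss_max(scores_presence, scores_background) -> tuple[float, float]:
    """Maximum TSS over candidate thresholds, with its threshold.

    Candidates are the midpoints between consecutive sorted unique scores
    plus sentinels below the minimum and above the maximum; prediction rule
    is ``score >= threshold``.  Ties on TSS break toward the lower threshold.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if len(sp) == 0 or len(sb) == 0:
        raise ValueError("both score lists must be non-empty")
    uniq = np.unique(np.concatenate([sp, sb]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    # sens/spec for score >= t, vectorized over thresholds
    sens = (sp[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (sb[None, :] < candidates[:, None]).mean(axis=1)
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax takes the first (lowest threshold) tie
    return float(tss[best]), float(candidates[best])


def evaluate_model(
    model: FittedSDM, design: TrainingDesign, test_idx: np.ndarray | None = None
) -> EvalResult:
    """AUC and max-TSS of a fitted model on (a subset of) a design."""
    X, y = design.X, design.y
    if test_idx is not None:
        X, y = X[test_idx], y[test_idx]
    scores = model.score(X)
    a = auc(scores[y == 1], scores[y == 0])
    t, thr = tss_max(scores[y == 1], scores[y == 0])
    return EvalResult(model.algorithm, model.month, a, t, thr)


def permutation_importance(
    model: FittedSDM,
    design: TrainingDesign,
    n_reps: int = 10,
    seed: int = 0,
) -> list[dict]:
    """Permutation importance of each predictor, ranked 1 = most important.

    Importance of a variable is the drop in AUC when its column is permuted,
    averaged over ``n_reps`` permutations.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    X, y = design.X, design.y
    scores = model.score(X)
    baseline = auc(scores[y == 1], scores[y == 0])
    drops = []
    for j, name in enumerate(design.predictor_names):
        vals = []
        for _ in range(n_reps):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            s = model.score(Xp)
            vals.append(auc(s[y == 1], s[y == 0]))
        drops.append(baseline - float(np.mean(vals)))
    order = np.argsort([-d for d in drops], kind="stable")
    ranks = np.empty(len(drops), dtype=int)
    ranks[order] = np.arange(1, len(drops) + 1)
    return [
        {
            "variable": name,
            "importance": drops[j],
            "rank": int(ranks[j]),
            "baseline_auc": baseline,
        }
        for j, name in enumerate(design.predictor_names)
    ]


def ensemble_weighted(
    rasters: dict[str, RasterGrid], weights: dict[str, float]
) -> RasterGrid:
    """Cell-wise weighted mean of aligned rasters; weights = max(w, 0), normalized.

    A cell masked in any input is masked in the ensemble.
    """
    if set(rasters) != set(weights):
        raise ValueError("rasters and weights must cover the same algorithms")
    names = list(rasters)
    ref = rasters[names[0]]
    for name in names[1:]:
        try:
            ref.require_aligned(rasters[name], (names[0], name))
        except AlignmentError:
            raise
    w = np.array([max(float(weights[n]), 0.0) for n in names])
    if w.sum() <= 0:
        raise DegenerateWeightsError("all ensemble weights are non-positive")
    w = w / w.sum()
    mask = np.logical_or.reduce([rasters[n].mask for n in names])
    acc = np.zeros(ref.shape)
    for wi, name in zip(w, names):
        acc += wi * np.nan_to_num(rasters[name].values, nan=0.0)
    acc[mask] = np.nan
    out = ref.copy(values=acc, name="suitability_ensemble")
    out.mask = mask
    return out


def normalize_raster(r: RasterGrid, winsor_q: float = 99.0) -> RasterGrid:
    """Cap outliers at the ``winsor_q``-th percentile, then min–max rescale to [0, 1].

    Percentiles use linear interpolation between order statistics.
    """
    vals = r.valid_values()
    vals = vals[~np.isnan(vals)]
    if len(np.unique(vals)) < 2:
        raise DegenerateRangeError("raster has fewer than 2 distinct valid values")
    cap = np.percentile(vals, winsor_q)
    capped = np.minimum(r.values, cap)
    lo = np.nanmin(np.where(r.mask, np.nan, capped))
    hi = np.nanmax(np.where(r.mask, np.nan, capped))
    if hi == lo:
        raise DegenerateRangeError("raster is constant after winsorizing")
    out_vals = (capped - lo) / (hi - lo)
    out_vals[r.mask] = np.nan
    out = r.copy(values=out_vals, name=r.name)
    return out
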