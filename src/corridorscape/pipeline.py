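"""End-to-end orchestration: synthetic landscape → occurrence prep →
predictor screening → monthly model fits → TSS-weighted ensembles →
seasonal conductance → three corridor methods → consensus → statistics.

Every stage writes its artifacts (ASCII-grid rasters, CSV tables, GeoJSON
paths) under the configured output directory and the run closes with a
manifest of content hashes, so two runs with the same configuration and
master seed produce byte-identical numeric artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    CorridorResult,
    SEASON_MONTHS,
    build_graph,
    consensus_overlap,
    lcp_density,
    percentile_mask,
    seasonal_conductance,
    solve_current,
)
from .errors import ConfigurationError
from .evaluation import (
    EvalResult,
    auc,
    ensemble_weighted,
    normalize_raster,
    permutation_importance,
    tss_max,
)
from .occurrences import (
    assign_season,
    filter_records,
    grid_thin,
    make_folds,
    sample_pseudo_absences,
    write_occurrences,
)
from .raster import RasterGrid, write_raster
from .screening import DEFAULT_PREFERENCE, drop_correlated, pairwise_correlation
from .sdm import ALGORITHMS, TrainingDesign, extract_design, fit_model, predict_raster
from .spatial_stats import (
    SpatialWeights,
    cluster_stats,
    paired_increase_test,
    seasonal_similarity,
)
from .synthetic import (
    default_bias,
    generate_env_stack,
    sample_occurrences,
    study_specs,
    true_suitability,
)

__all__ = ["PipelineConfig", "RunResult", "run_pipeline"]

log = logging.getLogger(__name__)

# fixed per-stage seed offsets derived from the master seed
_STAGE_OFFSET = {"occurrences": 10_000, "absences": 20_000, "folds": 30_000,
                 "fits": 40_000, "importance": 50_000, "stats": 60_000}

WINTER_MONTHS = (12, 1, 2)
SUMMER_MONTHS = (6, 7)


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; see field defaults for the knobs."""

    out_dir: str
    master_seed: int = 0
    # synthetic landscape
    n_rows: int = 60
    n_cols: int = 60
    cell_size_deg: float = 0.25
    corridor_boost: float = 0.3
    n_presences_per_month: int = 300
    noise_sd: dict[str, float] = field(default_factory=dict)
    sampling_bias: bool = True
    # preparation
    thin_cell_deg: float = 1.0
    ref_year: int = 2019
    window_years: int = 50
    n_pseudo_absences: int = 1000
    k_folds: int = 5
    min_occurrences_warn: int = 25
    min_occurrences_refuse: int = 13
    allow_sparse_months: bool = False
    # screening
    correlation_threshold: float = 0.8
    preference: tuple[str, ...] = DEFAULT_PREFERENCE
    # models
    algorithms: tuple[str, ...] = ALGORITHMS
    rf_trees: int = 500
    ensemble_metric: str = "TSS"
    winsor_q: float = 99.0
    importance_months: tuple[int, ...] = ()
    importance_reps: int = 5
    # corridors
    percentile_q: float = 95.0
    conductance_transform: str = "none"
    n_permutations: int = 99
    write_rasters: bool = True

    def __post_init__(self) -> None:
        for alg in self.algorithms:
            if alg.upper() not in ALGORITHMS:
                raise ConfigurationError(f"unknown algorithm {alg!r}")
        self.algorithms = tuple(a.upper() for a in self.algorithms)
        if self.ensemble_metric.upper() not in ("TSS", "AUC"):
            raise ConfigurationError("ensemble_metric must be TSS or AUC")
        self.ensemble_metric = self.ensemble_metric.upper()
        if not 0 < self.correlation_threshold <= 1:
            raise ConfigurationError("correlation_threshold must lie in (0, 1]")
        if not 0 <= self.percentile_q <= 100:
            raise ConfigurationError("percentile_q must lie in [0, 100]")
        if self.master_seed < 0:
            raise ConfigurationError("master_seed must be non-negative")

    def stage_seed(self, stage: str, index: int = 0) -> int:
        return (self.master_seed * 1_000_000 + _STAGE_OFFSET[stage] + index) % (2**31)


@dataclass
class RunResult:
    """In-memory view of a pipeline run (files are also on disk)."""

    config: PipelineConfig
    retained_predictors: list[str]
    evaluations: pd.DataFrame
    monthly_ensembles: dict[int, RasterGrid]
    truth: dict[int, RasterGrid]
    corridors: dict[str, CorridorResult]
    season_stats: pd.DataFrame
    seasonal_similarity: float
    corridor_mask: np.ndarray | None
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _ensemble_scores(models: dict[str, object], weights: dict[str, float], X) -> np.ndarray:
    w = np.array([max(weights[a], 0.0) for a in models])
    w = w / w.sum()
    return np.sum([wi * models[a].score(X) for wi, a in zip(w, models)], axis=0)


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full workflow on the synthetic study landscape."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    env_spec, niche = study_specs(
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        cell_size_deg=config.cell_size_deg,
        corridor_boost=config.corridor_boost,
        noise_sd=config.noise_sd,
        seed=config.master_seed,
    )

    # -- stage 1: synthetic landscape and occurrences -----------------------
    stacks: dict[int, dict[str, RasterGrid]] = {}
    truth: dict[int, RasterGrid] = {}
    occ_parts = []
    bias = None
    for month in range(1, 13):
        stacks[month] = generate_env_stack(env_spec, month)
        truth[month] = true_suitability(stacks[month], niche, month)
        if bias is None and config.sampling_bias:
            bias = default_bias(truth[month])
        occ_parts.append(
            sample_occurrences(
                truth[month],
                n=config.n_presences_per_month,
                bias=bias,
                seed=config.stage_seed("occurrences", month),
                month=month,
            )
        )
    raw = pd.concat(occ_parts, ignore_index=True)
    write_occurrences(out / "occurrences_raw.csv", raw)

    # -- stage 2: prep ------------------------------------------------------
    filtered = filter_records(raw, ref_year=config.ref_year, window_years=config.window_years)
    thinned_by_month: dict[int, pd.DataFrame] = {}
    for month in range(1, 13):
        part = filtered[filtered["month"] == month]
        thinned = grid_thin(part, config.thin_cell_deg)
        n = len(thinned)
        if n < config.min_occurrences_refuse and not config.allow_sparse_months:
            raise ConfigurationError(
                f"month {month} has only {n} thinned occurrences "
                f"(< {config.min_occurrences_refuse}); pass allow_sparse_months to override"
            )
        if n < config.min_occurrences_warn:
            log.warning("month %d has only %d thinned occurrences", month, n)
        thinned_by_month[month] = thinned
    thinned_all = assign_season(pd.concat(thinned_by_month.values(), ignore_index=True))
    write_occurrences(out / "occurrences_thinned.csv", thinned_all)

    # -- stage 3: predictor screening ---------------------------------------
    pooled = {
        name: np.concatenate([stacks[m][name].values.ravel() for m in range(1, 13)])
        for name in env_spec.layer_names
    }
    report = pairwise_correlation(pooled)
    retained = drop_correlated(report, config.correlation_threshold, config.preference)
    report.write(out / "predictor_correlations.csv", out / "predictor_drops.json")

    # -- stage 4: monthly fits, evaluation, ensembles ------------------------
    mask_grid = stacks[1][retained[0]]
    eval_rows = []
    importance_rows = []
    monthly_ensembles: dict[int, RasterGrid] = {}
    for month in range(1, 13):
        presences = thinned_by_month[month]
        absences = sample_pseudo_absences(
            mask_grid,
            n=config.n_pseudo_absences,
            exclude=presences,
            seed=config.stage_seed("absences", month),
            month=month,
        )
        design = extract_design(presences, absences, stacks[month], tuple(retained), month)
        folds = make_folds(len(design.y), config.k_folds, config.stage_seed("folds", month))
        train, test = folds.train_test(test_fold=1)
        train_design = TrainingDesign(
            design.X[train], design.y[train], design.predictor_names, month
        )
        models, weights, rasters = {}, {}, {}
        for alg in config.algorithms:
            model = fit_model(
                train_design,
                alg,
                seed=config.stage_seed("fits", month * 10 + ALGORITHMS.index(alg)),
                **({"rf_trees": config.rf_trees} if alg == "RF" else {}),
            )
            scores = model.score(design.X[test])
            y_test = design.y[test]
            a = auc(scores[y_test == 1], scores[y_test == 0])
            t, thr = tss_max(scores[y_test == 1], scores[y_test == 0])
            eval_rows.append(
                {"month": month, "algorithm": alg, "auc": a, "tss": t, "threshold": thr}
            )
            models[alg] = model
            weights[alg] = t if config.ensemble_metric == "TSS" else a
            rasters[alg] = predict_raster(model, stacks[month])
            if month in config.importance_months:
                for row in permutation_importance(
                    model, design, n_reps=config.importance_reps,
                    seed=config.stage_seed("importance", month),
                ):
                    importance_rows.append({"month": month, "algorithm": alg, **row})
        ens = ensemble_weighted(rasters, weights)
        ens_scores = _ensemble_scores(models, weights, design.X[test])
        y_test = design.y[test]
        a = auc(ens_scores[y_test == 1], ens_scores[y_test == 0])
        t, thr = tss_max(ens_scores[y_test == 1], ens_scores[y_test == 0])
        eval_rows.append(
            {"month": month, "algorithm": "ENSEMBLE", "auc": a, "tss": t, "threshold": thr}
        )
        monthly_ensembles[month] = normalize_raster(ens, config.winsor_q)
        if config.write_rasters:
            write_raster(out / f"ensemble_month_{month:02d}.asc", monthly_ensembles[month])
            write_raster(out / f"truth_month_{month:02d}.asc", truth[month])
    evaluations = pd.DataFrame(eval_rows)
    evaluations.to_csv(out / "evaluations.csv", index=False)
    if importance_rows:
        pd.DataFrame(importance_rows).to_csv(out / "importance.csv", index=False)

    # -- stage 5: seasonal conductance and corridor methods ------------------
    winter_pts = grid_thin(
        thinned_all[thinned_all["month"].isin(WINTER_MONTHS)], config.thin_cell_deg
    )
    summer_pts = grid_thin(
        thinned_all[thinned_all["month"].isin(SUMMER_MONTHS)], config.thin_cell_deg
    )
    corridors: dict[str, CorridorResult] = {}
    stats_rows = []
    for season in ("spring", "fall"):
        conductance = seasonal_conductance(
            monthly_ensembles, season, config.conductance_transform
        )
        graph = build_graph(conductance)
        paths, density, path_coords = lcp_density(graph, winter_pts, summer_pts)
        # migration direction: spring runs winter -> summer, fall the reverse
        if season == "spring":
            src_tab, gnd_tab = winter_pts, summer_pts
        else:
            src_tab, gnd_tab = summer_pts, winter_pts
        src = sorted(
            {conductance.cell_of(lo, la) for lo, la in zip(src_tab["lon"], src_tab["lat"])}
        )
        gnd = sorted(
            {conductance.cell_of(lo, la) for lo, la in zip(gnd_tab["lon"], gnd_tab["lat"])}
        )
        gnd_set = set(gnd)
        src = [cell for cell in src if cell not in gnd_set]
        if not src:
            raise ConfigurationError(f"no {season} source cells distinct from grounds")
        current = solve_current(conductance, src, gnd, injection=1.0)
        suit_mask = percentile_mask(conductance, config.percentile_q)
        result = consensus_overlap(
            density, current, suit_mask, config.percentile_q, config.percentile_q, paths
        )
        corridors[season] = result
        weights = SpatialWeights.contiguity(density, scheme="queen")
        cs = cluster_stats(
            density, weights, n_perm=config.n_permutations,
            seed=config.stage_seed("stats", 1 if season == "spring" else 2),
        )
        tt = paired_increase_test(paths["path_km"], paths["straight_km"])
        stats_rows.append(
            {
                "season": season,
                "morans_i": cs.morans_i,
                "morans_p": cs.morans_p,
                "gearys_c": cs.gearys_c,
                "gearys_p": cs.gearys_p,
                "mean_increase_km": tt["mean_increase"],
                "t": tt["t"],
                "df": tt["df"],
                "t_p": tt["p"],
                "n_pairs": len(paths),
            }
        )
        paths.to_csv(out / f"paths_{season}.csv", index=False)
        if config.write_rasters:
            write_raster(out / f"conductance_{season}.asc", conductance)
            write_raster(out / f"lcp_density_{season}.asc", density)
            write_raster(out / f"current_{season}.asc", current)
            write_raster(out / f"consensus_{season}.asc", result.consensus)
        _write_paths_geojson(out / f"paths_{season}.geojson", paths, path_coords)
    season_stats = pd.DataFrame(stats_rows)
    season_stats.to_csv(out / "season_stats.csv", index=False)

    # -- stage 6: seasonal similarity (migrant vs resident contrast support) --
    winter_mean = monthly_ensembles[12].copy(
        values=np.nanmean(
            np.stack([monthly_ensembles[m].values for m in WINTER_MONTHS]), axis=0
        ),
        name="winter_mean",
    )
    summer_mean = monthly_ensembles[6].copy(
        values=np.nanmean(
            np.stack([monthly_ensembles[m].values for m in SUMMER_MONTHS]), axis=0
        ),
        name="summer_mean",
    )
    similarity = seasonal_similarity(winter_mean, summer_mean)

    from .synthetic import corridor_cell_mask

    corridor_mask = (
        corridor_cell_mask(truth[1], niche.corridor_polyline, niche.corridor_width_cells)
        if niche.corridor_polyline is not None
        else None
    )

    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed_registry": {s: config.stage_seed(s) for s in _STAGE_OFFSET},
        "wall_time_s": None,  # filled below, excluded from hashing semantics
        "artifacts": {},
    }
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][p.name] = _sha256(p)
    manifest["wall_time_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return RunResult(
        config=config,
        retained_predictors=retained,
        evaluations=evaluations,
        monthly_ensembles=monthly_ensembles,
        truth=truth,
        corridors=corridors,
        season_stats=season_stats,
        seasonal_similarity=similarity,
        corridor_mask=corridor_mask,
        manifest=manifest,
    )


def _write_paths_geojson(
    path: Path, paths: pd.DataFrame, coords: list[np.ndarray]
) -> None:
    """One LineString per least-cost path, following the cell centres."""
    features = []
    for (_, row), line in zip(paths.iterrows(), coords):
        pts = line if len(line) > 1 else np.vstack([line, line])
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "pair_id": int(row["pair_id"]),
                    "cost": row["cost"],
                    "path_km": row["path_km"],
                    "straight_km": row["straight_km"],
                },
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[round(x, 6), round(y, 6)] for x, y in pts],
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(doc) + "\n")
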