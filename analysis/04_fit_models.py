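#!/usr/bin/env python
"""Fit the four suitability models per month and build the TSS-weighted
ensembles.

For every month: extract the presence/background design on the retained
predictors, hold out one of five folds for testing, fit BIOCLIM, GLM,
MaxEnt-style and random-forest models, score them on the held-out fold
(AUC and TSS), combine the predicted rasters with TSS weights, and
winsorize + rescale the ensemble.  Writes the evaluation table,
permutation variable importances for January and July, and the monthly
ensemble rasters under results/04_models/.
"""

import json
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import CFG, LANDSCAPE, MODELS, OCCURRENCES, SCREENING

from corridorscape.evaluation import (
    auc,
    ensemble_weighted,
    normalize_raster,
    permutation_importance,
    tss_max,
)
from corridorscape.occurrences import make_folds, read_occurrences, sample_pseudo_absences
from corridorscape.raster import read_stack, write_raster
from corridorscape.sdm import ALGORITHMS, TrainingDesign, extract_design, fit_model, predict_raster

IMPORTANCE_MONTHS = (1, 7)


def main() -> None:
    warnings.filterwarnings("ignore", category=FutureWarning)
    MODELS.mkdir(parents=True, exist_ok=True)
    retained = tuple(json.loads((SCREENING / "retained.json").read_text()))
    thinned = read_occurrences(OCCURRENCES / "occurrences_thinned.csv")
    eval_rows, importance_rows = [], []
    for month in range(1, 13):
        stack = read_stack(LANDSCAPE / f"month_{month:02d}")
        presences = thinned[thinned["month"] == month]
        absences = sample_pseudo_absences(
            stack[retained[0]],
            n=CFG.n_pseudo_absences,
            exclude=presences,
            seed=CFG.stage_seed("absences", month),
            month=month,
        )
        design = extract_design(presences, absences, stack, retained, month)
        folds = make_folds(len(design.y), CFG.k_folds, CFG.stage_seed("folds", month))
        train, test = folds.train_test(1)
        train_design = TrainingDesign(
            design.X[train], design.y[train], design.predictor_names, month
        )
        y_test = design.y[test]
        models, weights, rasters = {}, {}, {}
        for alg in CFG.algorithms:
            model = fit_model(
                train_design, alg,
                seed=CFG.stage_seed("fits", month * 10 + ALGORITHMS.index(alg)),
                **({"rf_trees": CFG.rf_trees} if alg == "RF" else {}),
            )
            s = model.score(design.X[test])
            a = auc(s[y_test == 1], s[y_test == 0])
            t, thr = tss_max(s[y_test == 1], s[y_test == 0])
            eval_rows.append({"month": month, "algorithm": alg,
                              "auc": a, "tss": t, "threshold": thr})
            models[alg], weights[alg], rasters[alg] = model, t, predict_raster(model, stack)
            if month in IMPORTANCE_MONTHS:
                for row in permutation_importance(
                    model, design, n_reps=CFG.importance_reps,
                    seed=CFG.stage_seed("importance", month),
                ):
                    importance_rows.append({"month": month, "algorithm": alg, **row})
        w = np.array([max(weights[a_], 0.0) for a_ in models])
        w = w / w.sum()
        ens_scores = np.sum(
            [wi * models[a_].score(design.X[test]) for wi, a_ in zip(w, models)], axis=0
        )
        a = auc(ens_scores[y_test == 1], ens_scores[y_test == 0])
        t, thr = tss_max(ens_scores[y_test == 1], ens_scores[y_test == 0])
        eval_rows.append({"month": month, "algorithm": "ENSEMBLE",
                          "auc": a, "tss": t, "threshold": thr})
        ens = normalize_raster(ensemble_weighted(rasters, weights), CFG.winsor_q)
        write_raster(MODELS / f"ensemble_month_{month:02d}.asc", ens)
    ev = pd.DataFrame(eval_rows)
    ev.to_csv(MODELS / "evaluations.csv", index=False)
    pd.DataFrame(importance_rows).to_csv(MODELS / "importance.csv", index=False)
    summary = ev.groupby("algorithm")[["auc", "tss"]].mean().round(3)
    print("mean test scores across the 12 monthly models:")
    print(summary.to_string())
    best = summary["tss"].idxmax()
    print(f"best mean TSS: {best}")


if __name__ == "__main__":
    main()
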