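#!/usr/bin/env python
"""Screen predictors for collinearity across the full year of layers.

Computes pairwise Pearson correlations over all twelve monthly stacks
pooled cell-wise and drops the less-preferred member of every pair with
|r| > 0.8.  Writes the correlation matrix, the drop log, and the retained
predictor list under results/03_screening/.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import CFG, ENV_SPEC, LANDSCAPE, SCREENING

from corridorscape.raster import read_stack
from corridorscape.screening import drop_correlated, pairwise_correlation


def main() -> None:
    SCREENING.mkdir(parents=True, exist_ok=True)
    pooled: dict[str, list] = {name: [] for name in ENV_SPEC.layer_names}
    for month in range(1, 13):
        stack = read_stack(LANDSCAPE / f"month_{month:02d}")
        for name in ENV_SPEC.layer_names:
            pooled[name].append(stack[name].values.ravel())
    vectors = {name: np.concatenate(parts) for name, parts in pooled.items()}
    report = pairwise_correlation(vectors)
    retained = drop_correlated(report, CFG.correlation_threshold, CFG.preference)
    report.write(SCREENING / "predictor_correlations.csv",
                 SCREENING / "predictor_drops.json")
    (SCREENING / "retained.json").write_text(json.dumps(retained) + "\n")
    print(f"retained {len(retained)} of {len(ENV_SPEC.layer_names)} predictors:")
    print("  " + ", ".join(retained))
    for d in report.dropped:
        print(f"  dropped {d['dropped']} (r = {d['r']:+.3f} with {d['partner']})")


if __name__ == "__main__":
    main()
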