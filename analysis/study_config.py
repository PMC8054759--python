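"""Shared configuration for the numbered analysis scripts.

One study: a 60x60-cell (15° x 15°) landscape at 0.25°, nine monthly
predictor layers, a thermal niche wintering in the south and summering in
the north, a planted three-cell-wide corridor (boost 0.3), 300 biased
presence samples per month.  All scripts derive their seeds from the same
master seed so the stages compose deterministically.
"""

from pathlib import Path

from corridorscape import PipelineConfig
from corridorscape.synthetic import study_specs

RESULTS = Path(__file__).resolve().parent.parent / "results"

CFG = PipelineConfig(out_dir=str(RESULTS), master_seed=1)

ENV_SPEC, NICHE = study_specs(
    n_rows=CFG.n_rows,
    n_cols=CFG.n_cols,
    cell_size_deg=CFG.cell_size_deg,
    corridor_boost=CFG.corridor_boost,
    noise_sd=CFG.noise_sd,
    seed=CFG.master_seed,
)

LANDSCAPE = RESULTS / "01_landscape"
OCCURRENCES = RESULTS / "02_occurrences"
SCREENING = RESULTS / "03_screening"
MODELS = RESULTS / "04_models"
CORRIDORS = RESULTS / "05_corridors"
STATS = RESULTS / "06_stats"
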