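#!/usr/bin/env python
"""Clean, thin and seasonally label the raw occurrence records.

Filters to valid recent records of the allowed record types, thins each
month to one record per 1° grid cell, and attaches seasonal labels.
Writes the thinned table and a per-month count summary under
results/02_occurrences/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import CFG, LANDSCAPE, OCCURRENCES

from corridorscape.occurrences import (
    assign_season,
    filter_records,
    grid_thin,
    read_occurrences,
    write_occurrences,
)


def main() -> None:
    OCCURRENCES.mkdir(parents=True, exist_ok=True)
    raw = read_occurrences(LANDSCAPE / "occurrences_raw.csv")
    filtered = filter_records(raw, ref_year=CFG.ref_year, window_years=CFG.window_years)
    thinned = []
    counts = []
    for month in range(1, 13):
        part = grid_thin(filtered[filtered["month"] == month], CFG.thin_cell_deg)
        thinned.append(part)
        counts.append({"month": month, "raw": int((raw["month"] == month).sum()),
                       "filtered": int((filtered["month"] == month).sum()),
                       "thinned": len(part)})
    table = assign_season(pd.concat(thinned, ignore_index=True))
    write_occurrences(OCCURRENCES / "occurrences_thinned.csv", table)
    counts = pd.DataFrame(counts)
    counts.to_csv(OCCURRENCES / "monthly_counts.csv", index=False)
    print(counts.to_string(index=False))
    low = counts[counts["thinned"] < CFG.min_occurrences_warn]
    if len(low):
        print(f"months below the {CFG.min_occurrences_warn}-record comfort "
              f"threshold: {list(low['month'])}")
    else:
        print("every month clears the 25-record comfort threshold")


if __name__ == "__main__":
    main()
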