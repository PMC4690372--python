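#!/usr/bin/env python
"""Quantify each simulated scene and report the multi-year changes.

Runs the full raster chain (reflectance -> NDSI/NIR snow mask ->
red:green ratio categories -> biomass summary) on the scenes written by
01_simulate_scenes.py, then prints and stores the per-year summaries
and the consecutive percent changes under results/timeseries/.
"""

from pathlib import Path

import pandas as pd

from redsnow import run_timeseries

ROOT = Path(__file__).resolve().parents[1]
SCENES = ROOT / "results" / "scenes"
OUT = ROOT / "results" / "timeseries"


def main() -> None:
    paths = sorted(SCENES.glob("scene_*.tif"))
    if len(paths) < 2:
        raise SystemExit("run analysis/01_simulate_scenes.py first")
    table = run_timeseries(paths, OUT)
    per_year = pd.read_csv(OUT / "per_year_summaries.csv")
    print("per-year summaries:")
    print(per_year.to_string(index=False))
    print("\nconsecutive changes (%):")
    print(table.round(1).to_string(index=False))
    print(f"\ntables written under {OUT}")


if __name__ == "__main__":
    main()
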