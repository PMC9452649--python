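#!/usr/bin/env python
"""Fit per-player force-to-VO2 calibrations and band thresholds.

Each player's incremental shuttle-run stages give (AvF_NET, estimated
VO2) pairs; an OLS line per player converts the 10/40/90/100 %VO2R band
edges into personalized newton thresholds.  Writes
results/calibration_models.csv and prints the fit quality range.
"""

from pathlib import Path

import pandas as pd

from courtload.pipeline import build_calibrations

ROOT = Path(__file__).resolve().parent.parent / "results"
roster = pd.read_csv(ROOT / "cohort" / "roster.csv")
stages = pd.read_csv(ROOT / "cohort" / "calibration.csv")

calibs = build_calibrations(roster, stages)
rows = []
for pid, (model, bands) in calibs.items():
    row = dict(player_id=pid, slope=model.slope, intercept=model.intercept,
               r_squared=model.r_squared, vo2_max=model.vo2_max)
    row.update({f"threshold_{int(p)}pct_n": t
                for p, t in zip(bands.edges_pct, bands.thresholds_n)})
    rows.append(row)
out = pd.DataFrame(rows).sort_values("player_id")
out.to_csv(ROOT / "calibration_models.csv", index=False)

print(f"calibrated {len(out)} players -> {ROOT / 'calibration_models.csv'}")
print(f"r^2 range: {out.r_squared.min():.3f}-{out.r_squared.max():.3f}")
print(f"10%VO2R threshold range: {out.threshold_10pct_n.min():.0f}-"
      f"{out.threshold_10pct_n.max():.0f} N")
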