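#!/usr/bin/env python
"""Render descriptive demand tables and the training-schedule summary.

Median (Q1-Q3) per variable and role x period cell, on original units,
written as markdown under results/tables/, plus the average session and
cumulative weekly training durations per period.
"""

from pathlib import Path

import pandas as pd

from courtload.pipeline import write_report_tables
from courtload.sessions import weekly_training_load

ROOT = Path(__file__).resolve().parent.parent / "results"
summaries = pd.read_csv(ROOT / "summaries.csv")

write_report_tables(summaries, ROOT / "tables")
print(f"wrote descriptive tables to {ROOT / 'tables'}")

load = weekly_training_load(summaries)
print("\ntraining schedule per period:")
for period, row in load.items():
    print(f"  {period}: session {row['session_median']:.0f} min "
          f"({row['session_q1']:.0f}-{row['session_q3']:.0f}), "
          f"weekly {row['weekly_median']:.0f} min "
          f"({row['weekly_q1']:.0f}-{row['weekly_q3']:.0f}), "
          f"n={row['n_sessions']}")
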