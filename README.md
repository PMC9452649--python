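# courtload

Accelerometry-based time-motion analysis of basketball training and
match demands, with a mixed-model comparison of regular season vs
finals by player role.

Team-sport practitioners monitor external load with trunk-mounted
triaxial accelerometers. This package implements that pipeline for
basketball end to end:

1. **Signal** — raw 100 Hz traces are band-pass filtered (0.1–15 Hz,
   4th-order Butterworth, zero-phase) per axis; the resultant
   acceleration times body mass gives the net force series, summarized
   per session as the average net force **AvF_NET** (N, intensity) and
   the impulse **AvF_NET × duration** (kN·s, volume).
2. **Calibration** — each player's incremental shuttle-run stages give
   an individual linear AvF_NET↔V̇O₂ relationship; the 10/40/90/100
   %V̇O₂R band edges (V̇O₂ reserve) invert to personalized newton
   thresholds, classifying every 1 s epoch as inactive, light,
   moderate-vigorous, maximal, or supramaximal.
3. **Sessions** — per player-session summaries (minutes and % per
   band, minutes played) with roles: starter, in-rotation bench
   (≥10 min played), out-rotation bench.
4. **Statistics** — log-transformed responses (offset +1 where zeros
   occur), participant-random-intercept linear mixed models with
   season period × role × team, an interaction decision tree choosing
   per-role(-and-team) follow-ups, Bonferroni-adjusted post-hocs,
   percentile-bootstrap mean differences (1,000 resamples), Cohen's d
   on the log scale, partial η², and the design-effect sample-size
   calculation k·m = N_base·(1+(m−1)·ICC).
5. **Synthetic cohort** — because raw player recordings for studies of
   this kind are not publicly deposited, a generator produces a
   two-team season (23 players; 387/75 match and 445/113 training
   observations, regular/finals) with planted ground truth — known
   band occupancies, calibration lines, and role-dependent finals
   effects — so every stage is testable without any download.

See `docs/methods.md` for the full model description and assumptions.

## Worked example

The sample-size calculation for the clustered repeated-measures design
(effect size 0.40, power 0.80, α 0.05, 23 players, ICC 0.05):

```bash
$ courtload power
base two-sample N: 198.2
observations per subject: 14
total sample size: 331
```

The analysis pipeline runs as numbered scripts over a synthetic season
(quarter-scale counts, 10-minute sessions, seed 7):

```bash
python analysis/01_simulate_cohort.py   # roster, calendar, manifest, truth
python analysis/02_calibrate_players.py # per-player thresholds
python analysis/03_process_sessions.py  # traces -> summaries.csv
python analysis/04_compare_periods.py   # mixed models + decision tree
python analysis/05_report_tables.py     # median (Q1-Q3) tables
```

`04_compare_periods.py` prints the branch the interaction tree took
per variable and the significant period contrasts, e.g.:

```
== match (116 observations) ==
  minutes_played: branch=per_role; out_rotation: MD=-1.07 [-1.54, -0.60],
      p_adj=0.029, d=0.82 (moderate); starter: MD=+4.37 [3.27, 5.41],
      p_adj=0.020, d=0.93 (moderate)
  maximal_min: branch=per_role; starter: MD=+0.18 [0.12, 0.23],
      p_adj=0.040, d=0.85 (moderate)
== training (139 observations) ==
  avf_net_n: branch=main_effect; all: MD=+10.93 [5.86, 15.82],
      p_adj=0.031, d=0.33 (small)
```

Read: playing-time differences between periods depended on role
(branch `per_role`); starters gained 4.37 min in finals (planted
truth: +4.4) while out-rotation bench players lost time; training
intensity rose period-wide. MD is the bootstrap mean difference on
original units with its percentile 95% CI; d is Cohen's d on the log
scale.

A single trace can be processed directly:

```python
from courtload import synth, pipeline

cohort = synth.generate_cohort(synth.SimConfig.scaled(seed=7, factor=0.25))
summaries = pipeline.process_cohort(cohort)
print(summaries[["session_id", "player_id", "role", "avf_net_n",
                 "inactive_pct"]].head())
```

A `courtload` CLI wraps the same stages (`simulate`, `calibrate`,
`process`, `analyze`, `report`, `power`) for disk-based runs on the
plain CSV formats documented in the module docstrings.

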