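#!/usr/bin/env python
"""Compare regular-season vs finals demands with the mixed-model tree.

For every demand variable: Shapiro-Wilk screen, log transform (offset 1
for zero-containing variables), the participant-random-intercept model
with period x role x team, the interaction decision tree, and the
bootstrap/Bonferroni/effect-size follow-ups the chosen branch calls for.
Writes results/stats.json and prints the branch taken plus any
significant period contrasts.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from courtload.pipeline import analyze_summaries, _json_default

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7

summaries = pd.read_csv(ROOT / "summaries.csv")
results = analyze_summaries(summaries, seed=SEED)

with open(ROOT / "stats.json", "w") as fh:
    json.dump(results, fh, indent=1, default=_json_default)
print(f"wrote {ROOT / 'stats.json'}\n")

for stype, block in results.items():
    print(f"== {stype} ({block['n_obs']} observations) ==")
    for var, res in block["variables"].items():
        if "error" in res:
            print(f"  {var}: skipped ({res['error']})")
            continue
        sig = [c for c in res["comparisons"]
               if c["p_adjusted"] is not None and c["p_adjusted"] <= 0.05]
        line = f"  {var}: branch={res['branch']}"
        for c in sig:
            line += (f"; {c['label']}: MD={c['md']:+.2f} "
                     f"[{c['ci_low']:.2f}, {c['ci_high']:.2f}], "
                     f"p_adj={c['p_adjusted']:.3f}, d={c['d']:.2f} "
                     f"({c['d_category']})")
        print(line)
    print()
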