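#!/usr/bin/env python
"""Demonstrate the assay statistics on simulated cytometry events.

Samples lognormal flow-cytometry events with a planted 20-fold repression,
recovers the fold repression from the sampled medians, and evaluates the
other measurement-derived statistics on representative inputs.
"""

from pathlib import Path

import pandas as pd

from anchorscape import (
    TiterPair,
    circuit_score,
    fold_propagation,
    fold_repression,
    median_of_events,
    ratio_fold_repression,
    relative_expression,
    resistance_index,
)
from anchorscape.simulate import sample_flow_events

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

background = 50.0
events_u = sample_flow_events(background + 20 * 100, cv=0.3, n=20001, seed=11)
events_i = sample_flow_events(background + 100, cv=0.3, n=20001, seed=12)
est = fold_repression(median_of_events(events_u), median_of_events(events_i),
                      background)

rows = [
    ("fold_repression_planted20", est),
    ("relative_expression", relative_expression(150, 50, 200)),
    ("circuit_score", circuit_score([500, 800], [50, 100])),
    ("resistance_index", resistance_index(750, 500)),
    ("fold_propagation", fold_propagation(TiterPair(5e6, 3.65e8))),
    ("mammalian_ratio_fold_repression",
     ratio_fold_repression(300, 110, 1100, 110, 100, 10)),
]
df = pd.DataFrame(rows, columns=["statistic", "value"])
df.to_csv(OUT / "assay_statistics.tsv", sep="\t", index=False)
print(df.to_string(index=False))
print(f"\nplanted 20-fold repression recovered as {est:.2f} "
      f"from 20001 sampled events per group")
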