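#!/usr/bin/env python
"""Directed spectral causality between region groups.

Sliding-window Vieira-Morf MVAR models over the NC epochs feed the three
frequency-domain measures (GGC, dDTF, nPDC), band-averaged over 13-50 Hz.
Under the ground truth, TeamFlow plants directed edges 0 -> 13 and 4 -> 13,
so region 13 should surface as the strongest information receiver (lowest
to/from ratio) and those edges as top senders.
"""

import warnings

import numpy as np

from hyperflow.mvar import to_from_summary, top_senders
from hyperflow.pipeline import stage_causality
from hyperflow.synth import read_study

warnings.filterwarnings("ignore")

study = read_study("results/study")
table = stage_causality(study, max_order=3)
table.to_csv("results/causality.tsv", sep="\t", index=False)

ggc = table[(table.measure == "GGC") & (table.condition == "TeamFlow")]
conn = ggc.groupby(["from", "to"])["value"].mean().unstack().to_numpy()
np.fill_diagonal(conn, 0.0)
summary = to_from_summary(conn)
receiver = int(np.argmin(summary.log_ratio))
print(f"TeamFlow GGC: strongest receiver (lowest log to/from) = region {receiver}")
edges = top_senders(summary.edge_log_ratio, retain_fraction=0.10)
print("top ~10% sender edges (from -> to, log to/from):")
for i, j, v in edges[:5]:
    print(f"  {i} -> {j}: {v:.3f}")
print("wrote results/causality.tsv")
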