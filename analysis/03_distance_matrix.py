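#!/usr/bin/env python
"""Build the colour-distance matrix between analytes.

The four temperatures are concatenated into one 36-bin vector per analyte
and pairwise dissimilarity is the sum over bins of squared per-channel
ΔRGB differences.  Writes results/distances.csv (+ PHYLIP copy).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phagesensor import distance_matrix
from phagesensor.features import assemble_feature_table, frame_to_patterns

ROOT = Path(__file__).resolve().parent.parent / "results"

patterns = frame_to_patterns(pd.read_csv(ROOT / "features.csv"))
concat = assemble_feature_table(patterns, mode="concatenated")
dmat = distance_matrix(concat, dialect="squared")
dmat.save_csv(ROOT / "distances.csv")
dmat.save_phylip(ROOT / "distances.phy")

classes = {a: ("estrogen" if a in ("E1", "E2", "E3", "EE2") else "antibiotic")
           for a in dmat.labels}
within, between = [], []
for i in range(dmat.n):
    for j in range(i + 1, dmat.n):
        same = classes[dmat.labels[i]] == classes[dmat.labels[j]]
        (within if same else between).append(dmat.values[i, j])
print(f"wrote {dmat.n}x{dmat.n} distance matrix to {ROOT / 'distances.csv'}")
print(f"mean within-class distance:  {np.mean(within):.0f}")
print(f"mean between-class distance: {np.mean(between):.0f}")
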