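#!/usr/bin/env python
"""Recovery study for the syngeneic purity MLE.

Simulates RNA-seq read depths at cell-line SNPs over a range of true
purities and depth regimes, estimates purity by the grid MLE, and tabulates
bias / RMSE / coverage. Also demonstrates the depth cap on a cohort with a
few extreme-depth sites.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from xenopurity.mle import purity_mle
from xenopurity.simulate import SimConfig, gen_syngeneic_sites

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for theta in (0.6, 0.8, 0.85, 0.95):
    for depth_mean in (20.0, 50.0):
        errors = []
        for rep in range(100):
            cfg = SimConfig(seed=3000 + rep, theta_true=theta, n_sites=500,
                            depth_mean=depth_mean, het_fraction=0.5)
            sites, _ = gen_syngeneic_sites(cfg)
            errors.append(purity_mle(sites).theta_hat - theta)
        errors = np.asarray(errors)
        rows.append({
            "theta_true": theta,
            "depth_mean": depth_mean,
            "bias": round(float(errors.mean()), 5),
            "rmse": round(float(np.sqrt(np.mean(errors**2))), 5),
            "frac_within_002": round(float(np.mean(np.abs(errors) < 0.02)), 3),
        })

table = pd.DataFrame(rows)
table.to_csv(OUT / "syngeneic_mle_recovery.tsv", sep="\t", index=False)
print("syngeneic purity MLE recovery (500 sites, 100 replicates each):")
print(table.to_string(index=False))

# depth cap demonstration: highly overdispersed depths distort nothing
cfg = SimConfig(seed=77, theta_true=0.8, n_sites=500, depth_mean=50, depth_dispersion=0.3)
sites, _ = gen_syngeneic_sites(cfg)
est = purity_mle(sites)
print(f"\noverdispersed cohort (k=0.3): theta_hat={est.theta_hat:.3f}, "
      f"{est.n_sites_capped} of {est.n_sites_used} sites capped at 5x median depth")
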