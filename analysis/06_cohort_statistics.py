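#!/usr/bin/env python
"""Cohort-level purity statistics on a synthetic PDX collection.

Builds a cohort with model-intrinsic purity (model-level sd larger than
within-model sd), a strain effect, and passage structure; then runs the
within/between comparison, early/late pairing, balanced strain comparison
and per-cancer summary. Finally computes the purity-mutation Spearman on
the packaged 19-model syngeneic table.
"""

import json
from pathlib import Path

import numpy as np

from xenopurity.cohort import (
    BALBC_NUDE,
    NOD_SCID,
    TumorSample,
    balanced_strain_subset,
    cancer_purity_summary,
    early_late_pairing,
    load_syngeneic_table,
    purity_mutation_correlation,
    strain_comparison,
    within_between_differences,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng(7000)
CANCERS = {"CR": 0.85, "GA": 0.82, "PA": 0.67, "KI": 0.61, "LU": 0.78,
           "LI": 0.84, "OV": 0.80, "ES": 0.83, "HN": 0.74}
STRAIN_SHIFT = {NOD_SCID: 0.04, BALBC_NUDE: -0.04}

samples = []
for cancer, cancer_mean in CANCERS.items():
    for m in range(8):
        model_mean = float(np.clip(cancer_mean + rng.normal(0, 0.10), 0.05, 0.98))
        strain = NOD_SCID if m % 2 == 0 else BALBC_NUDE
        for k in range(5):
            passage = int(rng.integers(0, 8))
            p = float(np.clip(model_mean + STRAIN_SHIFT[strain] + rng.normal(0, 0.04), 0, 1))
            samples.append(
                TumorSample(f"{cancer}m{m}s{k}", f"{cancer}m{m}", cancer, strain, passage, p)
            )

report = {}

wb = within_between_differences(samples)
report["within_between"] = {
    "median_within_pct": round(100 * wb.median_within, 2),
    "median_between_pct": round(100 * wb.median_between, 2),
    "p_value": wb.p_value,
}
print(f"within- vs between-model median |delta purity|: "
      f"{100 * wb.median_within:.2f}% vs {100 * wb.median_between:.2f}% (p={wb.p_value:.2e})")

el = early_late_pairing(samples, seed=7)
report["early_late"] = {
    "n_models": len(el.model_ids),
    "pearson_r": round(el.pearson_r, 3),
    "mean_diff_pct": round(100 * el.mean_diff, 2),
    "paired_t_p": el.p_value,
}
print(f"early/late pairing over {len(el.model_ids)} models: r={el.pearson_r:.2f}, "
      f"mean late-early = {100 * el.mean_diff:+.2f}%")

subset, composition = balanced_strain_subset(samples, seed=7)
sc = strain_comparison(subset)
report["strain_comparison"] = {
    "n_balanced": len(subset),
    "pooled_median_pct": {k: round(100 * v, 1) for k, v in sc.pooled_medians.items()},
    "pooled_p": sc.pooled_p,
    "cross_strain_pearson_r": round(sc.cross_strain_pearson_r, 3),
}
print(f"balanced subset ({len(subset)} samples): pooled medians "
      f"{ {k: f'{100 * v:.1f}%' for k, v in sc.pooled_medians.items()} }, "
      f"p={sc.pooled_p:.2e}, per-cancer cross-strain r={sc.cross_strain_pearson_r:.2f}")

summary, mean_of_medians = cancer_purity_summary(samples, min_n=20)
summary.to_csv(OUT / "cancer_purity_summary.tsv", sep="\t", index=False)
report["cancer_summary_mean_of_medians_pct"] = round(100 * mean_of_medians, 2)
print(f"per-cancer summary ({len(summary)} cancers >= 20 samples): "
      f"mean of medians = {100 * mean_of_medians:.1f}%")

rho, p = purity_mutation_correlation(load_syngeneic_table())
report["syngeneic_table"] = {"spearman_rho": round(rho, 4), "p_value": round(p, 4)}
print(f"packaged syngeneic table: Spearman(purity, mutations) = {rho:.3f} (p={p:.2f})")

(OUT / "cohort_statistics.json").write_text(json.dumps(report, indent=2) + "\n")
print(f"\nwrote {OUT / 'cohort_statistics.json'}")
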