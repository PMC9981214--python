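#!/usr/bin/env python
"""Germline/somatic classification on synthetic variant tables.

Checks rule-by-rule recovery against hidden labels, then shows how the
per-model median VAF of somatic missense mutations tracks tumor purity
(clonal monoallelic mutations sit at VAF = purity/2).
"""

from pathlib import Path

import pandas as pd

from xenopurity.simulate import SimConfig, gen_variant_table
from xenopurity.variants import VariantLabel, classify_variants, model_median_vaf

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

records = gen_variant_table(SimConfig(seed=5000, n_sites=2000))
truth = [v.label for v in records]
predicted = classify_variants(records)

confusion = pd.crosstab(
    pd.Series([t.value for t in truth], name="truth"),
    pd.Series([p.value for p in predicted], name="predicted"),
)
confusion.to_csv(OUT / "variant_confusion_matrix.tsv", sep="\t")
accuracy = sum(t is p for t, p in zip(truth, predicted)) / len(records)
print("confusion matrix on 2,000 separable synthetic variants:")
print(confusion.to_string())
print(f"accuracy: {accuracy:.1%}")

rows = []
for purity in (1.0, 0.9, 0.8, 0.7, 0.6, 0.5):
    clonal = gen_variant_table(
        SimConfig(seed=5001, n_sites=500), purity=purity,
        germline_fraction=0.0, ensure_separable=False,
    )
    classify_variants(clonal)
    med = model_median_vaf(clonal)
    n_somatic = sum(1 for v in clonal if v.label is VariantLabel.SOMATIC)
    rows.append({"purity": purity, "median_somatic_vaf": med, "n_somatic": n_somatic})

table = pd.DataFrame(rows)
table.to_csv(OUT / "median_vaf_by_purity.tsv", sep="\t", index=False)
print("\nmedian somatic missense VAF by simulated purity (expect purity/2):")
print(table.to_string(index=False))
print("note: at low purity the <10% VAF rule starts absorbing genuine subclonal-"
      "looking somatic calls, shaving the somatic count.")
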