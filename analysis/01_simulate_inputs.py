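#!/usr/bin/env python
"""Generate one example of every input the pipeline consumes.

Writes synthetic SNP-site, amplicon-segment, variant, expression,
signature/ortholog and score-purity reference files under results/data/ so
the downstream drivers (and any user) can run against concrete files with
known hidden truth.
"""

import json
from pathlib import Path

from xenopurity.io import (
    write_expression,
    write_gmt,
    write_ortholog_map,
    write_reference_pairs,
    write_segment_table,
    write_sites_table,
    write_variant_table,
)
from xenopurity.simulate import (
    SimConfig,
    gen_expression_cohort,
    gen_score_purity_reference,
    gen_segment_counts,
    gen_syngeneic_sites,
    gen_variant_table,
    make_synthetic_signature,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# compact demo sizes: every written file stays a small, diffable TSV
cfg = SimConfig(seed=2026, theta_true=0.85, n_sites=300, n_samples=6, n_genes=400)
truth = {"seed": cfg.seed}

sites, theta = gen_syngeneic_sites(cfg)
write_sites_table(sites, OUT / "syngeneic_sites.tsv")
truth["theta_true"] = theta

segments, f_true = gen_segment_counts(cfg)
write_segment_table(segments, OUT / "amplicon_segments.tsv")
truth["human_fraction_true"] = f_true

variants = gen_variant_table(cfg)
write_variant_table(variants, OUT / "variants.tsv")

signature = make_synthetic_signature()
write_gmt(
    {"stromal": sorted(signature.stromal_genes), "immune": sorted(signature.immune_genes)},
    OUT / "signature.gmt",
)
write_ortholog_map(signature.ortholog_map, OUT / "ortholog_map.tsv")

human, mouse, purities = gen_expression_cohort(cfg, signature)
write_expression(human, OUT / "expression_human.tsv")
write_expression(mouse, OUT / "expression_mouse.tsv")
truth["expression_purities"] = [round(float(p), 4) for p in purities]

reference, _ = gen_score_purity_reference(SimConfig(seed=2026, n_samples=100))
write_reference_pairs(reference, OUT / "score_purity_reference.tsv")

(OUT / "hidden_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
print(f"wrote synthetic inputs for seed {cfg.seed} to {OUT}")
print(f"  syngeneic theta_true={theta}, amplicon f_true={f_true}, "
      f"{len(variants)} variants, {human.shape[1]} expression samples")
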