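"""Validated configuration and the simulate -> estimate -> report pipeline.

The pipeline is the glue used by the analysis drivers and by end-to-end
tests: it generates synthetic inputs from a seeded configuration, runs the
requested estimators, and emits a report that embeds the configuration,
seed and package version so every output is reproducible from the config
alone. Unknown configuration keys are rejected before any stage runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .amplicon import assay_purity
from .mle import purity_mle
from .simulate import SimConfig, gen_segment_counts, gen_syngeneic_sites, gen_variant_table
from .variants import VariantLabel, classify_variants, model_median_vaf

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger("xenopurity")

Stage = Literal["syngeneic_mle", "amplicon", "variants"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimParams(_Block):
    theta_true: float = 0.85
    n_sites: int = 500
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0
    het_fraction: float = 0.5
    n_segments: int = 108
    segment_depth: int = 3000
    n_samples: int = 50
    n_genes: int = 2000
    noise_sd: float = 0.2


class MleParams(_Block):
    grid_step: float = Field(default=0.001, gt=0, le=0.1)
    depth_min: int = 20
    cap_multiplier: float = 5.0
    cap_mode: Literal["rescale", "drop"] = "rescale"


class AmpliconParams(_Block):
    min_depth: int = 100


class VariantParams(_Block):
    min_missense: int = 30
    purity: float = 1.0


class PipelineConfig(_Block):
    seed: int = 0
    log_level: str = "INFO"
    stages: list[Stage] = ["syngeneic_mle"]
    sim: SimParams = SimParams()
    mle: MleParams = MleParams()
    amplicon: AmpliconParams = AmpliconParams()
    variants: VariantParams = VariantParams()

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim.model_dump())


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path) -> PipelineConfig:
    """Load and schema-validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def _stage_syngeneic_mle(cfg: PipelineConfig) -> dict:
    sites, theta_true = gen_syngeneic_sites(cfg.sim_config())
    est = purity_mle(
        sites,
        depth_min=cfg.mle.depth_min,
        cap_multiplier=cfg.mle.cap_multiplier,
        grid_step=cfg.mle.grid_step,
        cap_mode=cfg.mle.cap_mode,
    )
    return {
        "theta_true": theta_true,
        "theta_hat": est.theta_hat,
        "n_sites_used": est.n_sites_used,
        "n_sites_capped": est.n_sites_capped,
    }


def _stage_amplicon(cfg: PipelineConfig) -> dict:
    segments, f_true = gen_segment_counts(cfg.sim_config())
    purity, report = assay_purity(segments, min_depth=cfg.amplicon.min_depth)
    return {
        "human_fraction_true": f_true,
        "purity": purity,
        "n_segments_used": int(report["used"].sum()),
    }


def _stage_variants(cfg: PipelineConfig) -> dict:
    records = gen_variant_table(cfg.sim_config(), purity=cfg.variants.purity)
    truth = [v.label for v in records]
    labels = classify_variants(records)
    correct = sum(1 for t, l in zip(truth, labels) if t is l)
    median_vaf = model_median_vaf(records, min_missense=cfg.variants.min_missense)
    return {
        "n_variants": len(records),
        "n_somatic": sum(1 for l in labels if l is VariantLabel.SOMATIC),
        "label_accuracy": correct / len(records),
        "median_somatic_missense_vaf": median_vaf,
    }


_STAGES = {
    "syngeneic_mle": _stage_syngeneic_mle,
    "amplicon": _stage_amplicon,
    "variants": _stage_variants,
}


def run_pipeline(cfg: PipelineConfig, out_path=None, check: bool = False) -> dict:
    """Run the configured stages in order and return the report.

    The report embeds the full configuration, the seed and the package
    version. With ``check=True`` everything is run a second time and the two
    reports are compared; any difference raises, guaranteeing that the output
    is reproducible from config + seed. A failing stage raises
    :class:`PipelineError` naming the stage.
    """
    logging.basicConfig()
    logger.setLevel(cfg.log_level.upper())
    report = {
        "package": "xenopurity",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.model_dump(),
        "stages": {},
    }
    for stage in cfg.stages:
        logger.info("running stage %s", stage)
        try:
            report["stages"][stage] = _STAGES[stage](cfg)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    if check:
        rerun = run_pipeline(cfg, out_path=None, check=False)
        if rerun != report:
            raise PipelineError("check failed: re-run produced a different report")
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2) + "\n")
    return report
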