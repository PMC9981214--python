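"""Germline/somatic classification of PDX variants without matched normals.

PDX cohorts usually lack matched normal tissue, so germline variants are
flagged by orthogonal evidence instead of subtraction. A variant is called
germline if any of these rules fires:

  (i)   its allele frequency is > 0.01 in dbSNP AND gnomAD AND ExAC;
  (ii)  it is seen in more than 20% of the tested PDX models (a shared
        artifact or common polymorphism, not a tumor-private event);
  (iii) the variant allele is present in more than one of 45 other
        vertebrate genomes (a conserved ancestral allele);
  (iv)  its variant allele fraction is below 10% (removes subclonal calls
        and noise from the somatic set).

Everything else is somatic. The per-model median VAF of somatic missense
mutations summarises clonality: clonal monoallelic mutations in a pure
tumor sit near VAF 0.5 and scale down with purity.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "VariantLabel",
    "VariantRecord",
    "compute_vaf",
    "classify_variant",
    "classify_variants",
    "compute_cohort_prevalence",
    "model_median_vaf",
]

N_VERTEBRATE_GENOMES = 45


class VariantLabel(enum.Enum):
    GERMLINE = "GERMLINE"
    SOMATIC = "SOMATIC"


@dataclass
class VariantRecord:
    """One annotated variant call in one PDX model.

    Population allele frequencies are ``None`` when the database has no
    entry; ``cohort_prevalence`` is the fraction of tested models carrying
    the same variant. ``label`` holds the (predicted or, in synthetic data,
    true) germline/somatic class.
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    consequence: str
    alt_depth: int
    total_depth: int
    af_dbsnp: Optional[float] = None
    af_gnomad: Optional[float] = None
    af_exac: Optional[float] = None
    vertebrate_hits: int = 0
    cohort_prevalence: float = 0.0
    label: Optional[VariantLabel] = None

    def __post_init__(self) -> None:
        if self.total_depth < 0 or self.alt_depth < 0:
            raise ValueError(f"negative depth in {self.variant_id}")
        if self.alt_depth > self.total_depth:
            raise ValueError(f"alt depth exceeds total depth in {self.variant_id}")
        if not 0 <= self.vertebrate_hits <= N_VERTEBRATE_GENOMES:
            raise ValueError(f"vertebrate_hits out of [0, {N_VERTEBRATE_GENOMES}]")

    @property
    def vaf(self) -> float:
        return compute_vaf(self.alt_depth, self.total_depth)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def compute_vaf(alt_depth: int, total_depth: int) -> float:
    """Variant allele fraction alt_depth / total_depth."""
    if total_depth <= 0:
        raise ValueError("total depth must be positive")
    if not 0 <= alt_depth <= total_depth:
        raise ValueError("alt depth must be in [0, total depth]")
    return alt_depth / total_depth


def _population_rule(v: VariantRecord, threshold: float, missing_af: str) -> bool:
    afs = (v.af_dbsnp, v.af_gnomad, v.af_exac)
    if missing_af == "zero":
        # absent entry counts as frequency 0: the rule cannot fire on it
        return all(a is not None and a > threshold for a in afs)
    if missing_af == "ignore":
        present = [a for a in afs if a is not None]
        return bool(present) and all(a > threshold for a in present)
    raise ValueError(f"missing_af must be 'zero' or 'ignore', got {missing_af!r}")


def classify_variant(
    v: VariantRecord,
    af_threshold: float = 0.01,
    prevalence_threshold: float = 0.20,
    vertebrate_threshold: int = 1,
    low_vaf_threshold: float = 0.10,
    missing_af: str = "zero",
    apply_low_vaf_rule: bool = True,
) -> VariantLabel:
    """Apply the germline rules (pure OR); anything unflagged is somatic."""
    germline = (
        _population_rule(v, af_threshold, missing_af)
        or v.cohort_prevalence > prevalence_threshold
        or v.vertebrate_hits > vertebrate_threshold
        or (apply_low_vaf_rule and v.vaf < low_vaf_threshold)
    )
    return VariantLabel.GERMLINE if germline else VariantLabel.SOMATIC


def classify_variants(variants: Sequence[VariantRecord], **kwargs) -> list[VariantLabel]:
    """Classify a list of variants, storing the label on each record."""
    labels = []
    for v in variants:
        lab = classify_variant(v, **kwargs)
        v.label = lab
        labels.append(lab)
    return labels


def compute_cohort_prevalence(
    model_variants: Mapping[str, Sequence[VariantRecord]]
) -> dict[tuple[str, int, str, str], float]:
    """Fraction of models carrying each variant, keyed by (chrom, pos, ref, alt).

    The prevalence table must be built across the whole cohort before
    per-model classification, since rule (ii) compares against it. The
    computed values are written back onto every record.
    """
    n_models = len(model_variants)
    if n_models == 0:
        raise ValueError("need at least one model")
    carriers: dict[tuple[str, int, str, str], set[str]] = {}
    for model_id, variants in model_variants.items():
        for v in variants:
            carriers.setdefault(v.key, set()).add(model_id)
    prevalence = {k: len(models) / n_models for k, models in carriers.items()}
    for variants in model_variants.values():
        for v in variants:
            v.cohort_prevalence = prevalence[v.key]
    return prevalence


def model_median_vaf(
    variants: Sequence[VariantRecord],
    min_missense: int = 30,
    missense_term: str = "missense",
) -> Optional[float]:
    """Median VAF of somatic missense variants of one model.

    Models with fewer than ``min_missense`` somatic missense mutations are
    excluded (returns ``None``): their median would be too noisy to anchor a
    purity statement.
    """
    vafs = [
        v.vaf
        for v in variants
        if v.label is VariantLabel.SOMATIC and missense_term in v.consequence.lower()
    ]
    if len(vafs) < min_missense:
        return None
    return float(statistics.median(vafs))
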