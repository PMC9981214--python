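"""Readers and writers for the pipeline's tabular formats.

All tabular formats are tab-separated with a header row, UTF-8, and ``.``
for missing values; coordinates are 1-based. VCF input is read through
pysam (allele depths from the first sample's AD field). Writers emit
exactly what the matching reader consumes, so write -> read round-trips are
identities.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon import SegmentCounts
from .calibration import ScorePurityReference
from .mle import GenotypeClass, SnpSite
from .variants import VariantLabel, VariantRecord

__all__ = [
    "read_sites_table",
    "write_sites_table",
    "read_sites_vcf",
    "read_variant_table",
    "write_variant_table",
    "read_variant_vcf",
    "read_segment_table",
    "write_segment_table",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_reference_pairs",
    "write_reference_pairs",
]

MISSING = "."


class TableFormatError(ValueError):
    """Malformed tabular input, reported with its line number."""


def _parse(row: Mapping[str, str], key: str, cast, line: int, required: bool = True):
    raw = row.get(key)
    if raw is None or raw == MISSING or raw == "":
        if required:
            raise TableFormatError(f"line {line}: missing required field {key!r}")
        return None
    try:
        return cast(raw)
    except ValueError as exc:
        raise TableFormatError(f"line {line}: bad value {raw!r} for {key!r}") from exc


# ---------------------------------------------------------------- SNP sites

SITE_COLUMNS = ["site_id", "genotype_class", "H1", "T1", "n_H", "n_T"]


def write_sites_table(sites: Sequence[SnpSite], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SITE_COLUMNS)
        for s in sites:
            w.writerow([s.site_id, s.genotype_class.value, s.H1, s.T1, s.n_H, s.n_T])


def read_sites_table(path) -> list[SnpSite]:
    sites = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line, row in enumerate(reader, start=2):
            sites.append(
                SnpSite(
                    site_id=_parse(row, "site_id", str, line),
                    genotype_class=GenotypeClass(_parse(row, "genotype_class", str, line)),
                    H1=_parse(row, "H1", float, line),
                    T1=_parse(row, "T1", float, line),
                    n_H=_parse(row, "n_H", int, line),
                    n_T=_parse(row, "n_T", int, line),
                )
            )
    return sites


def read_sites_vcf(path, sample: Optional[str] = None) -> list[SnpSite]:
    """SNP sites from a VCF: AD of one sample gives (n_H, n_T).

    The genotype class is taken from the chosen sample's GT: homozygous-alt
    calls are HOM_TT, heterozygous calls HET_HT (with T1 = 0.5). Records
    without AD or with non-biallelic genotypes are skipped.
    """
    import pysam

    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = sample or list(vcf.header.samples)[0]
        for rec in vcf:
            call = rec.samples[sample]
            ad = call.get("AD")
            gt = call.get("GT")
            if ad is None or gt is None or len(ad) < 2 or None in gt:
                continue
            alleles = set(gt)
            if alleles == {1}:
                cls = GenotypeClass.HOM_TT
            elif alleles == {0, 1}:
                cls = GenotypeClass.HET_HT
            else:
                continue
            sites.append(
                SnpSite(
                    site_id=f"{rec.chrom}:{rec.pos}",
                    genotype_class=cls,
                    n_H=int(ad[0]),
                    n_T=int(ad[1]),
                )
            )
    return sites


# ----------------------------------------------------------------- variants

VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "alt_depth",
    "total_depth",
    "af_dbsnp",
    "af_gnomad",
    "af_exac",
    "vertebrate_hits",
    "cohort_prevalence",
    "label",
]


def write_variant_table(variants: Sequence[VariantRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for v in variants:
            w.writerow(
                [
                    v.variant_id,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.consequence,
                    v.alt_depth,
                    v.total_depth,
                    MISSING if v.af_dbsnp is None else repr(v.af_dbsnp),
                    MISSING if v.af_gnomad is None else repr(v.af_gnomad),
                    MISSING if v.af_exac is None else repr(v.af_exac),
                    v.vertebrate_hits,
                    repr(v.cohort_prevalence),
                    MISSING if v.label is None else v.label.value,
                ]
            )


def read_variant_table(path) -> list[VariantRecord]:
    variants = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line, row in enumerate(reader, start=2):
            label = _parse(row, "label", str, line, required=False)
            variants.append(
                VariantRecord(
                    variant_id=_parse(row, "variant_id", str, line),
                    chrom=_parse(row, "chrom", str, line),
                    pos=_parse(row, "pos", int, line),
                    ref=_parse(row, "ref", str, line),
                    alt=_parse(row, "alt", str, line),
                    consequence=_parse(row, "consequence", str, line),
                    alt_depth=_parse(row, "alt_depth", int, line),
                    total_depth=_parse(row, "total_depth", int, line),
                    af_dbsnp=_parse(row, "af_dbsnp", float, line, required=False),
                    af_gnomad=_parse(row, "af_gnomad", float, line, required=False),
                    af_exac=_parse(row, "af_exac", float, line, required=False),
                    vertebrate_hits=_parse(row, "vertebrate_hits", int, line) or 0,
                    cohort_prevalence=_parse(row, "cohort_prevalence", float, line, required=False)
                    or 0.0,
                    label=VariantLabel(label) if label else None,
                )
            )
    return variants


def read_variant_vcf(path, sample: Optional[str] = None) -> list[VariantRecord]:
    """Variant records from a VCF with the pipeline's INFO annotations.

    AD of one sample gives (ref, alt) depths; population frequencies,
    conservation hits, prevalence and consequence come from the INFO keys
    AF_DBSNP / AF_GNOMAD / AF_EXAC / VERT_HITS / PREV / CONSEQ (all
    optional; absent keys stay absent).
    """
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = sample or list(vcf.header.samples)[0]
        for rec in vcf:
            ad = rec.samples[sample].get("AD")
            if ad is None or len(ad) < 2:
                continue

            def info_float(key):
                v = rec.info.get(key)
                if v is None:
                    return None
                return float(v[0] if isinstance(v, tuple) else v)

            conseq = rec.info.get("CONSEQ", "missense_variant")
            if isinstance(conseq, tuple):
                conseq = conseq[0]
            variants.append(
                VariantRecord(
                    variant_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    consequence=str(conseq),
                    alt_depth=int(ad[1]),
                    total_depth=int(ad[0]) + int(ad[1]),
                    af_dbsnp=info_float("AF_DBSNP"),
                    af_gnomad=info_float("AF_GNOMAD"),
                    af_exac=info_float("AF_EXAC"),
                    vertebrate_hits=int(rec.info.get("VERT_HITS", 0)),
                    cohort_prevalence=float(rec.info.get("PREV", 0.0)),
                )
            )
    return variants


# ----------------------------------------------------------------- segments


def write_segment_table(segments: Sequence[SegmentCounts], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["segment_id", "reads_human", "reads_mouse"])
        for s in segments:
            w.writerow([s.segment_id, s.reads_human, s.reads_mouse])


def read_segment_table(path) -> list[SegmentCounts]:
    segments = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line, row in enumerate(reader, start=2):
            segments.append(
                SegmentCounts(
                    segment_id=_parse(row, "segment_id", str, line),
                    reads_human=_parse(row, "reads_human", int, line),
                    reads_mouse=_parse(row, "reads_mouse", int, line),
                )
            )
    return segments


# --------------------------------------------------------------- expression


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# --------------------------------------------------- signatures & orthologs


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise TableFormatError(f"line {line}: GMT rows need name, description, genes")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_ortholog_map(path) -> dict[str, tuple[str, ...]]:
    mapping: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for line, row in enumerate(reader, start=2):
            human = _parse(row, "human_id", str, line)
            mouse = _parse(row, "mouse_id", str, line)
            mapping.setdefault(human, []).append(mouse)
    return {h: tuple(ms) for h, ms in mapping.items()}


def write_ortholog_map(mapping: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["human_id", "mouse_id"])
        for human, mice in mapping.items():
            for mouse in mice:
                w.writerow([human, mouse])


# ---------------------------------------------------------- reference pairs


def write_reference_pairs(ref: ScorePurityReference, path) -> None:
    pd.DataFrame({"estimate_score": ref.scores, "purity": ref.purities}).to_csv(
        path, sep="\t", index=False
    )


def read_reference_pairs(path) -> ScorePurityReference:
    df = pd.read_csv(path, sep="\t")
    return ScorePurityReference(
        scores=df["estimate_score"].to_numpy(dtype=float),
        purities=df["purity"].to_numpy(dtype=float),
    )
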