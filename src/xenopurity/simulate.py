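"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator emits its hidden truth (purity, human fraction, labels)
alongside the data so recovery can be tested without any external download.
The defaults mirror the study designs the pipeline targets: ~500 expressed
cell-line SNPs at RNA-seq depths with strong overdispersion for the
syngeneic estimator, 108 amplicon segments at ~3000x for the species assay,
and PDX-like expression cohorts whose stromal/immune signature signal scales
with (1 - purity).

What is emulated and what is not: read counts are binomial given depth (no
mapping bias, so clonal somatic VAFs center on 0.5 rather than the ~0.47
seen with real aligners), depths are negative binomial (no GC or positional
structure), and expression is TPM-like with log-normal noise (no
batch/library-size effects).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .amplicon import SegmentCounts
from .calibration import ScorePurityReference
from .mle import GenotypeClass, SnpSite
from .scoring import GeneSignature
from .variants import VariantLabel, VariantRecord

__all__ = [
    "SimConfig",
    "make_synthetic_signature",
    "gen_syngeneic_sites",
    "gen_segment_counts",
    "gen_expression_cohort",
    "gen_variant_table",
    "gen_score_purity_reference",
]

# fixed per-generator stream tags so the generators draw decorrelated
# substreams from one config seed
_STREAM = {"sites": 1, "segments": 2, "expression": 3, "variants": 4, "reference": 5}


@dataclass(frozen=True)
class SimConfig:
    """Shared knobs for all generators.

    ``theta_true`` doubles as the tumor purity for syngeneic sites and as
    the true human-cell fraction for amplicon segments. ``depth_dispersion``
    is the negative-binomial size parameter k (variance = mu + mu^2/k), so
    smaller k means more overdispersed depths. ``noise_sd`` is the standard
    deviation of log-normal multiplicative expression noise.
    """

    seed: int = 0
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

    def __post_init__(self) -> None:
        for name in ("theta_true", "het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_sites", "n_segments", "segment_depth", "n_samples", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


def _nb_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def gen_syngeneic_sites(
    cfg: SimConfig, t1: float = 0.5
) -> tuple[list[SnpSite], float]:
    """Tumor read depths at cell-line-specific SNPs in a theta:(1-theta) mix.

    Each site is homozygous TT with probability ``1 - het_fraction``, else
    heterozygous HT with within-cell-line T fraction ``t1``. Total depth is
    negative binomial; the T-allele read count is binomial with success
    probability theta (HOM) or theta * t1 (HET).
    """
    if not 0.0 < t1 < 1.0:
        raise ValueError("t1 must be in (0, 1)")
    rng = cfg.rng("sites")
    depths = _nb_depths(rng, cfg.n_sites, cfg.depth_mean, cfg.depth_dispersion)
    is_het = rng.random(cfg.n_sites) < cfg.het_fraction
    p = np.where(is_het, cfg.theta_true * t1, cfg.theta_true)
    n_t = rng.binomial(depths, p)
    sites = [
        SnpSite(
            site_id=f"snp{i:05d}",
            genotype_class=GenotypeClass.HET_HT if is_het[i] else GenotypeClass.HOM_TT,
            n_H=int(depths[i] - n_t[i]),
            n_T=int(n_t[i]),
            H1=1.0 - t1,
            T1=t1,
        )
        for i in range(cfg.n_sites)
    ]
    return sites, cfg.theta_true


def gen_segment_counts(
    cfg: SimConfig, bias_sd: float = 0.0
) -> tuple[list[SegmentCounts], float]:
    """Per-segment human/mouse read counts at a known human fraction.

    Each segment's human read count is binomial(segment_depth, f) where f is
    the true human fraction, optionally distorted per segment by a
    log-normal amplification-bias multiplier on the human:mouse odds.
    """
    rng = cfg.rng("segments")
    f = cfg.theta_true
    if bias_sd > 0:
        b = rng.lognormal(0.0, bias_sd, size=cfg.n_segments)
        probs = b * f / (b * f + (1.0 - f)) if f < 1.0 else np.ones(cfg.n_segments)
    else:
        probs = np.full(cfg.n_segments, f)
    human = rng.binomial(cfg.segment_depth, probs)
    segments = [
        SegmentCounts(
            segment_id=f"seg{i:03d}",
            reads_human=int(human[i]),
            reads_mouse=int(cfg.segment_depth - human[i]),
        )
        for i in range(cfg.n_segments)
    ]
    return segments, f


def make_synthetic_signature(
    n_stromal: int = 141,
    n_immune: int = 141,
    n_unmapped_stromal: int = 11,
    n_unmapped_immune: int = 0,
) -> GeneSignature:
    """Synthetic stromal/immune signature with a partial human->mouse map.

    Mirrors the real signature geometry: 141 genes per set, a handful of
    stromal genes without a mouse ortholog, and occasional one-to-many
    ortholog relations (every tenth mapped gene gets two mouse orthologs).
    """
    stromal = [f"STRO{i:04d}" for i in range(n_stromal)]
    immune = [f"IMMU{i:04d}" for i in range(n_immune)]
    ortholog_map: dict[str, tuple[str, ...]] = {}
    for genes, unmapped in ((stromal, n_unmapped_stromal), (immune, n_unmapped_immune)):
        for j, g in enumerate(genes):
            if j < len(genes) - unmapped:
                orthologs = [f"mm-{g.title()}"]
                if j % 10 == 9:
                    orthologs.append(f"mm-{g.title()}b")
                ortholog_map[g] = tuple(orthologs)
    return GeneSignature(
        stromal_genes=frozenset(stromal),
        immune_genes=frozenset(immune),
        ortholog_map=ortholog_map,
    )


def gen_expression_cohort(
    cfg: SimConfig,
    signature: GeneSignature,
    purities: Optional[np.ndarray] = None,
    purity_range: tuple[float, float] = (0.5, 1.0),
    human_signal_share: tuple[float, float] = (0.2, 0.8),
):
    """PDX-like human and mouse expression matrices with known purities.

    Per sample j with purity p_j:

    * each signature gene g carries a stromal/immune signal proportional to
      ``(1 - p_j)``, split between a residual human-compartment share w_j
      (drawn once per sample from ``human_signal_share``: tumors differ in
      how much human stroma remains) and the mouse ortholog(s) with share
      1 - w_j — both species compartments carry signal, and only their sum
      (hybrid expression) recovers it in full, which is exactly why the
      hybrid score version exists;
    * human background genes either scale with p_j (cancer genes, half of
      the background) or are purity-independent;
    * mouse background genes are purity-independent;
    * every value is multiplied by log-normal noise with sd ``noise_sd``.

    Returns ``(human_df, mouse_df, purities)`` with genes x samples frames
    (human gene ids are bare symbols, mouse ids carry the ``mm-`` prefix).
    """
    import pandas as pd

    rng = cfg.rng("expression")
    if purities is None:
        purities = rng.uniform(*purity_range, size=cfg.n_samples)
    purities = np.asarray(purities, dtype=float)
    n_samples = len(purities)
    samples = [f"sample{j:03d}" for j in range(n_samples)]

    sig_genes = sorted(signature.stromal_genes | signature.immune_genes)
    n_background = max(cfg.n_genes - len(sig_genes), 0)
    bg_genes = [f"GENE{i:05d}" for i in range(n_background)]

    def noise(shape):
        if cfg.noise_sd == 0:
            return np.ones(shape)
        return rng.lognormal(0.0, cfg.noise_sd, size=shape)

    # signature genes: signal S_g * (1 - p_j), split human w_j / mouse (1 - w_j)
    s_g = rng.uniform(50.0, 150.0, size=len(sig_genes))
    w_j = rng.uniform(*human_signal_share, size=n_samples)
    baseline_h = rng.uniform(1.0, 3.0, size=len(sig_genes))
    baseline_m = rng.uniform(1.0, 3.0, size=len(sig_genes))
    stroma = 1.0 - purities[None, :]
    human_sig = (baseline_h[:, None] + s_g[:, None] * (w_j[None, :] * stroma)) * noise(
        (len(sig_genes), n_samples)
    )

    mouse_rows: dict[str, np.ndarray] = {}
    for i, g in enumerate(sig_genes):
        orthologs = signature.ortholog_map.get(g, ())
        mouse_signal = s_g[i] * (1.0 - w_j) * stroma[0]
        for mg in orthologs:
            # split the mouse share evenly across a gene's orthologs
            row = (baseline_m[i] + mouse_signal / len(orthologs)) * noise(n_samples)
            mouse_rows[mg] = mouse_rows.get(mg, 0.0) + row

    # background: half cancer genes (scale with p), half flat; mouse flat
    bg_base = rng.uniform(5.0, 50.0, size=n_background)
    is_cancer_gene = (np.arange(n_background) % 2 == 0)[:, None]
    human_bg = bg_base[:, None] * np.where(is_cancer_gene, purities[None, :], 1.0)
    human_bg = human_bg * noise((n_background, n_samples))

    n_mouse_bg = n_background // 2
    mouse_bg_genes = [f"mm-Gene{i:05d}" for i in range(n_mouse_bg)]
    mouse_bg = rng.uniform(5.0, 50.0, size=n_mouse_bg)[:, None] * noise(
        (n_mouse_bg, n_samples)
    )

    human_df = pd.DataFrame(
        np.vstack([human_sig, human_bg]),
        index=sig_genes + bg_genes,
        columns=samples,
    )
    mouse_index = list(mouse_rows) + mouse_bg_genes
    mouse_df = pd.DataFrame(
        np.vstack([np.vstack(list(mouse_rows.values())), mouse_bg])
        if mouse_rows
        else mouse_bg,
        index=mouse_index,
        columns=samples,
    )
    return human_df, mouse_df, purities


def gen_variant_table(
    cfg: SimConfig,
    purity: float = 1.0,
    germline_fraction: float = 0.5,
    clonal_vaf: float = 0.5,
    depth: int = 200,
    consequence: str = "missense_variant",
    ensure_separable: bool = True,
) -> list[VariantRecord]:
    """Annotated variants with hidden germline/somatic truth.

    Germline variants are spread over the four evidence channels (population
    frequency in all three databases, cohort prevalence > 20%, conservation
    in >1 other vertebrate, or sub-10% VAF); somatic variants carry
    near-zero population frequencies, 0-1 vertebrate hits, low prevalence
    and a clonal monoallelic VAF centered at ``clonal_vaf * purity`` (no
    mapping bias is simulated, so the center is 0.5 at purity 1 rather than
    the ~0.47 real aligners produce). With ``ensure_separable`` the binomial
    draws are clamped away from the 10% VAF boundary so the hidden labels
    are perfectly recoverable; disable it to study boundary noise.
    """
    rng = cfg.rng("variants")
    n = cfg.n_sites
    records: list[VariantRecord] = []
    for i in range(n):
        is_germline = rng.random() < germline_fraction
        af = (None, None, None)
        hits = int(rng.integers(0, 2))  # 0 or 1: below the conservation rule
        prevalence = float(rng.uniform(0.0, 0.15))
        if is_germline:
            mech = rng.integers(4)
            vaf_center = 0.5
            if mech == 0:  # population frequency in all three databases
                af = tuple(float(rng.uniform(0.02, 0.5)) for _ in range(3))
            elif mech == 1:  # cohort-prevalent artifact/polymorphism
                prevalence = float(rng.uniform(0.25, 0.9))
            elif mech == 2:  # conserved ancestral allele
                hits = int(rng.integers(2, 11))
            else:  # sub-clonal / noise call caught by the low-VAF rule
                vaf_center = 0.05
            p_alt = vaf_center
        else:
            p_alt = clonal_vaf * purity
        alt = int(rng.binomial(depth, p_alt))
        if ensure_separable:
            low = is_germline and p_alt < 0.10
            if low:
                alt = min(alt, int(0.08 * depth))
            else:
                alt = max(alt, int(np.ceil(0.12 * depth)))
        records.append(
            VariantRecord(
                variant_id=f"var{i:05d}",
                chrom=f"chr{1 + i % 22}",
                pos=1000 + i,
                ref="A",
                alt="G",
                consequence=consequence,
                alt_depth=alt,
                total_depth=depth,
                af_dbsnp=af[0],
                af_gnomad=af[1],
                af_exac=af[2],
                vertebrate_hits=hits,
                cohort_prevalence=prevalence,
                label=VariantLabel.GERMLINE if is_germline else VariantLabel.SOMATIC,
            )
        )
    return records


def _default_score_to_purity(scores: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # strictly decreasing cosine-of-affine map from score range onto [0, 1]
    t = (np.asarray(scores, dtype=float) - lo) / (hi - lo)
    return np.clip(0.5 + 0.5 * np.cos(np.pi * t), 0.0, 1.0)


def gen_score_purity_reference(
    cfg: SimConfig,
    noise_sd: float = 0.02,
    score_range: tuple[float, float] = (-2000.0, 4000.0),
    g: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> tuple[ScorePurityReference, Callable[[np.ndarray], np.ndarray]]:
    """Reference (score, purity) pairs from a monotone decreasing curve.

    Scores are spread uniformly over ``score_range`` (deterministically at
    the range ends, so extrapolation beyond them is exercised only by new
    scores); purity = g(score) + Gaussian noise, clamped to [0, 1]. Returns
    the reference together with the generating function for recovery tests.
    """
    if cfg.n_samples < 20:
        raise ValueError("need at least 20 reference pairs")
    rng = cfg.rng("reference")
    lo, hi = score_range
    if g is None:
        g = lambda s: _default_score_to_purity(s, lo, hi)  # noqa: E731
    scores = np.linspace(lo, hi, cfg.n_samples)
    purities = g(scores)
    if noise_sd > 0:
        purities = purities + rng.normal(0.0, noise_sd, size=cfg.n_samples)
    purities = np.clip(purities, 0.0, 1.0)
    return ScorePurityReference(scores=scores, purities=purities), g
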