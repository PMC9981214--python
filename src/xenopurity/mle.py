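"""Maximum-likelihood tumor purity for syngeneic mouse tumor models.

A syngeneic cell line carries SNPs relative to its inbred host strain; after
implantation the tumor is a mixture of cancer cells (fraction ``theta``) and
host cells (fraction ``1 - theta``). At a SNP site the host genotype is HH
while the cell line is homozygous TT or heterozygous HT with within-cell-line
allele fractions H1 and T1 (H1 + T1 = 1). Sequencing reads drawn from the
mixture then show the cell-line allele T with probability ``theta`` at a HOM
site and ``theta * T1`` at a HET site, so, conditional on total depth, the
read counts are binomial and the per-site log-likelihood (dropping the
theta-independent binomial coefficient) is

    HOM:  n_H * log(1 - theta)      + n_T * log(theta)
    HET:  n_H * log(1 - theta * T1) + n_T * log(theta * T1)

The cohort log-likelihood is the sum over sites and is maximised on a grid of
theta values from 0 to 1. RNA-seq depths vary by orders of magnitude between
sites, so before estimation low-depth sites are removed and very deep sites
are capped at a multiple of the median depth to stop single sites from
dominating the profile.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import xlogy

__all__ = [
    "GenotypeClass",
    "SnpSite",
    "PurityEstimate",
    "site_loglik",
    "cohort_loglik",
    "preprocess_sites",
    "estimate_purity",
    "purity_mle",
    "genotype_from_cellline_fraction",
    "t1_from_cellline_counts",
]


class GenotypeClass(enum.Enum):
    """Cell-line genotype at a host-HH SNP site."""

    HOM_TT = "HOM_TT"
    HET_HT = "HET_HT"


@dataclass(frozen=True)
class SnpSite:
    """Read depths at one cell-line-specific SNP in a tumor sample.

    ``n_H`` counts reads carrying the host allele H, ``n_T`` the cell-line
    allele T. ``H1``/``T1`` are the within-cell-line allele fractions and are
    only meaningful for heterozygous sites (they default to 0.5/0.5).
    """

    site_id: str
    genotype_class: GenotypeClass
    n_H: int
    n_T: int
    H1: float = 0.5
    T1: float = 0.5
    capped: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.genotype_class, GenotypeClass):
            raise TypeError(f"invalid genotype class: {self.genotype_class!r}")
        if self.n_H < 0 or self.n_T < 0:
            raise ValueError(f"negative read count at {self.site_id}")
        if self.genotype_class is GenotypeClass.HET_HT:
            if not (self.H1 > 0 and self.T1 > 0):
                raise ValueError(f"HET site {self.site_id} needs H1 > 0 and T1 > 0")
            if abs(self.H1 + self.T1 - 1.0) > 1e-9:
                raise ValueError(f"HET site {self.site_id} needs H1 + T1 = 1")

    @property
    def depth(self) -> int:
        return self.n_H + self.n_T


@dataclass(frozen=True)
class PurityEstimate:
    """Grid maximum-likelihood estimate of tumor purity theta."""

    theta_hat: float
    thetas: np.ndarray
    logliks: np.ndarray
    n_sites_used: int
    n_sites_capped: int

    @property
    def loglik_grid(self) -> list[tuple[float, float]]:
        return list(zip(self.thetas.tolist(), self.logliks.tolist()))


def site_loglik(site: SnpSite, theta: float) -> float:
    """Log-likelihood (nats) of one site's read counts at purity ``theta``.

    The binomial coefficient is omitted (constant in theta) and
    ``0 * log(0)`` is taken as 0 so the boundaries theta = 0, 1 are evaluable.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    if site.genotype_class is GenotypeClass.HOM_TT:
        p = theta
    elif site.genotype_class is GenotypeClass.HET_HT:
        p = theta * site.T1
    else:  # pragma: no cover - guarded in SnpSite
        raise ValueError(f"invalid genotype class: {site.genotype_class!r}")
    return float(xlogy(site.n_H, 1.0 - p) + xlogy(site.n_T, p))


def cohort_loglik(sites: Sequence[SnpSite], theta: float) -> float:
    """Sum of ``site_loglik`` over all sites."""
    if len(sites) == 0:
        raise ValueError("cohort_loglik requires at least one site")
    return float(_profile(sites, np.asarray([theta], dtype=float))[0])


def _profile(sites: Sequence[SnpSite], thetas: np.ndarray) -> np.ndarray:
    """Cohort log-likelihood on a grid of theta values.

    Sites sharing a genotype class and T1 contribute through their summed
    counts only, so the profile is computed from a handful of aggregated
    terms regardless of cohort size.
    """
    groups: dict[tuple[GenotypeClass, float], list[int]] = {}
    for s in sites:
        t1 = s.T1 if s.genotype_class is GenotypeClass.HET_HT else 1.0
        acc = groups.setdefault((s.genotype_class, t1), [0, 0])
        acc[0] += s.n_H
        acc[1] += s.n_T
    total = np.zeros_like(thetas)
    for (_, t1), (n_h, n_t) in groups.items():
        p = thetas * t1
        total = total + xlogy(n_h, 1.0 - p) + xlogy(n_t, p)
    return total


def preprocess_sites(
    sites: Sequence[SnpSite],
    depth_min: int = 20,
    cap_multiplier: float = 5.0,
    cap_mode: str = "rescale",
) -> list[SnpSite]:
    """Depth-filter and depth-cap SNP sites before estimation.

    Sites with total depth below ``depth_min`` are removed. Among the
    retained sites, any site deeper than ``cap_multiplier`` times the median
    depth is either rescaled to exactly the cap — preserving its allele
    fraction, with nearest-integer rounding (ties rounded up) — or dropped
    when ``cap_mode="drop"``. Input order is preserved.
    """
    if len(sites) == 0:
        raise ValueError("preprocess_sites requires at least one site")
    if cap_mode not in ("rescale", "drop"):
        raise ValueError(f"cap_mode must be 'rescale' or 'drop', got {cap_mode!r}")
    retained = [s for s in sites if s.depth >= depth_min]
    if not retained:
        raise ValueError(
            f"no sites with depth >= {depth_min}; insufficient data for estimation"
        )
    cap = cap_multiplier * statistics.median(s.depth for s in retained)
    out: list[SnpSite] = []
    for s in retained:
        if s.depth <= cap:
            out.append(s)
            continue
        if cap_mode == "drop":
            continue
        new_total = int(cap)
        n_t = int(math.floor(new_total * s.n_T / s.depth + 0.5))  # ties up
        out.append(replace(s, n_H=new_total - n_t, n_T=n_t, capped=True))
    if not out:
        raise ValueError("all sites removed by the depth cap; insufficient data")
    return out


def estimate_purity(sites: Sequence[SnpSite], grid_step: float = 0.001) -> PurityEstimate:
    """Maximise the cohort log-likelihood over a theta grid on [0, 1].

    ``sites`` are expected to be preprocessed already. The grid runs from 0
    to 1 in steps of ``grid_step``; on ties the smallest maximising theta is
    returned together with the full profile.
    """
    if len(sites) == 0:
        raise ValueError("estimate_purity requires at least one site")
    if not 0.0 < grid_step <= 0.1:
        raise ValueError(f"grid_step must be in (0, 0.1], got {grid_step}")
    thetas = np.arange(0.0, 1.0 + grid_step / 2.0, grid_step)
    if thetas[-1] < 1.0:
        thetas = np.append(thetas, 1.0)
    logliks = _profile(sites, thetas)
    if not np.isfinite(logliks).any():
        raise ValueError("log-likelihood is non-finite on the whole grid")
    best = int(np.argmax(logliks))  # first maximum -> smallest theta on ties
    return PurityEstimate(
        theta_hat=float(thetas[best]),
        thetas=thetas,
        logliks=logliks,
        n_sites_used=len(sites),
        n_sites_capped=sum(1 for s in sites if s.capped),
    )


def purity_mle(
    sites: Sequence[SnpSite],
    depth_min: int = 20,
    cap_multiplier: float = 5.0,
    grid_step: float = 0.001,
    cap_mode: str = "rescale",
) -> PurityEstimate:
    """Convenience chain: ``preprocess_sites`` then ``estimate_purity``."""
    kept = preprocess_sites(sites, depth_min=depth_min, cap_multiplier=cap_multiplier, cap_mode=cap_mode)
    return estimate_purity(kept, grid_step=grid_step)


def genotype_from_cellline_fraction(
    alt_fraction: float, hom_threshold: float = 0.85, het_threshold: float = 0.15
) -> GenotypeClass:
    """Assign HOM/HET class from the cell line's own alt-allele fraction.

    Fractions at or above ``hom_threshold`` are called homozygous TT, fractions
    in [het_threshold, hom_threshold) heterozygous HT; lower fractions look
    host-like and are rejected.
    """
    if alt_fraction >= hom_threshold:
        return GenotypeClass.HOM_TT
    if alt_fraction >= het_threshold:
        return GenotypeClass.HET_HT
    raise ValueError(
        f"alt fraction {alt_fraction:.3f} below HET threshold {het_threshold}; not a cell-line SNP"
    )


def t1_from_cellline_counts(n_ref: int, n_alt: int) -> float:
    """Estimate the within-cell-line T allele fraction from cell-line reads."""
    if n_ref < 0 or n_alt < 0 or n_ref + n_alt == 0:
        raise ValueError("need non-negative counts with positive total")
    return n_alt / (n_ref + n_alt)
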