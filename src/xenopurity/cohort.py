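"""Cohort-level purity statistics for PDX and syngeneic collections.

Given per-sample purities with model, cancer, strain and passage metadata,
these functions reproduce the standard cohort analyses: within- versus
between-model purity differences (is purity a model-intrinsic property?),
early/late passage concordance, host-strain comparison on a cancer-balanced
subset, per-cancer purity summaries, and the rank correlation between
syngeneic model purity and somatic mutation burden. Rank tests and
correlations are delegated to scipy; exact enumeration oracles for small
inputs live in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TumorSample",
    "NOD_SCID",
    "BALBC_NUDE",
    "WithinBetweenResult",
    "EarlyLateResult",
    "StrainComparison",
    "within_between_differences",
    "early_late_pairing",
    "balanced_strain_subset",
    "strain_comparison",
    "cancer_purity_summary",
    "purity_mutation_correlation",
    "load_syngeneic_table",
    "rank_sum_test",
]

NOD_SCID = "NOD_SCID"
BALBC_NUDE = "BALBC_NUDE"


@dataclass(frozen=True)
class TumorSample:
    """One tumor sample with its purity and cohort metadata."""

    sample_id: str
    model_id: str
    cancer: str
    strain: str
    passage: int
    purity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity out of [0, 1] for {self.sample_id}")
        if self.passage < 0:
            raise ValueError(f"negative passage for {self.sample_id}")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null below n = 20 without ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class WithinBetweenResult:
    within: np.ndarray  # |purity difference| for same-model, same-passage pairs
    between: np.ndarray  # |purity difference| for different-model, same-passage pairs
    median_within: float
    median_between: float
    u_statistic: float
    p_value: float


def within_between_differences(samples: Sequence[TumorSample]) -> WithinBetweenResult:
    """Same-passage purity differences within versus between models.

    All pairs of samples sharing a passage are split into same-model and
    different-model pairs; the absolute purity differences of the two groups
    are compared by a two-sided Mann-Whitney U test. A clearly larger
    between-model median marks purity as a model-intrinsic property.
    """
    within: list[float] = []
    between: list[float] = []
    by_passage: dict[int, list[TumorSample]] = {}
    for s in samples:
        by_passage.setdefault(s.passage, []).append(s)
    for group in by_passage.values():
        for a, b in itertools.combinations(group, 2):
            d = abs(a.purity - b.purity)
            (within if a.model_id == b.model_id else between).append(d)
    if not within or not between:
        raise ValueError("need both same-model and different-model same-passage pairs")
    w = np.asarray(within)
    b = np.asarray(between)
    u, p = rank_sum_test(w, b)
    return WithinBetweenResult(
        within=w,
        between=b,
        median_within=float(np.median(w)),
        median_between=float(np.median(b)),
        u_statistic=u,
        p_value=p,
    )


@dataclass(frozen=True)
class EarlyLateResult:
    model_ids: list[str]
    early: np.ndarray
    late: np.ndarray
    pearson_r: float
    mean_diff: float  # late - early
    sd_diff: float
    t_statistic: float
    p_value: float


def early_late_pairing(samples: Sequence[TumorSample], seed: int = 0) -> EarlyLateResult:
    """Pair one early- and one late-passage sample per model.

    For every model with at least two samples, one sample is drawn (seeded)
    among those at the earliest passage and one among those at the latest
    passage; the same physical sample is never used twice. Reports the
    Pearson correlation and a paired t test on late - early.
    """
    rng = np.random.default_rng(seed)
    by_model: dict[str, list[TumorSample]] = {}
    for s in samples:
        by_model.setdefault(s.model_id, []).append(s)
    model_ids, early, late = [], [], []
    for model_id in sorted(by_model):
        group = by_model[model_id]
        if len(group) < 2:
            continue
        passages = [s.passage for s in group]
        lo, hi = min(passages), max(passages)
        early_candidates = [s for s in group if s.passage == lo]
        e = early_candidates[rng.integers(len(early_candidates))]
        late_candidates = [s for s in group if s.passage == hi and s is not e]
        if not late_candidates:  # only possible when lo == hi with a single sample there
            continue
        l = late_candidates[rng.integers(len(late_candidates))]
        model_ids.append(model_id)
        early.append(e.purity)
        late.append(l.purity)
    if len(model_ids) < 3:
        raise ValueError("need at least three models with two or more samples")
    early_a = np.asarray(early)
    late_a = np.asarray(late)
    diffs = late_a - early_a
    if np.ptp(early_a) == 0 or np.ptp(late_a) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(early_a, late_a).statistic)
    if np.ptp(diffs) == 0:
        t_stat, p = float("nan"), float("nan")
    else:
        t_res = stats.ttest_rel(late_a, early_a)
        t_stat, p = float(t_res.statistic), float(t_res.pvalue)
    return EarlyLateResult(
        model_ids=model_ids,
        early=early_a,
        late=late_a,
        pearson_r=r,
        mean_diff=float(diffs.mean()),
        sd_diff=float(diffs.std(ddof=1)),
        t_statistic=t_stat,
        p_value=p,
    )


def balanced_strain_subset(
    samples: Sequence[TumorSample], seed: int = 0
) -> tuple[list[TumorSample], pd.DataFrame]:
    """Downsample to equal per-cancer counts in both host strains.

    For every cancer present in both strains, both strains are randomly
    downsampled (seeded, without replacement) to the smaller count. Returns
    the subset and a composition table (cancer x strain counts).
    """
    rng = np.random.default_rng(seed)
    strains = sorted({s.strain for s in samples})
    if len(strains) != 2:
        raise ValueError(f"expected exactly two strains, found {strains}")
    by_cancer_strain: dict[tuple[str, str], list[TumorSample]] = {}
    for s in samples:
        by_cancer_strain.setdefault((s.cancer, s.strain), []).append(s)
    cancers = sorted({c for (c, _) in by_cancer_strain})
    subset: list[TumorSample] = []
    rows = []
    for cancer in cancers:
        groups = [by_cancer_strain.get((cancer, st), []) for st in strains]
        if not all(groups):
            continue
        n = min(len(g) for g in groups)
        for st, g in zip(strains, groups):
            idx = rng.choice(len(g), size=n, replace=False)
            subset.extend(g[i] for i in sorted(idx))
        rows.append({"cancer": cancer, strains[0]: n, strains[1]: n})
    if not subset:
        raise ValueError("no cancer is present in both strains")
    return subset, pd.DataFrame(rows)


@dataclass(frozen=True)
class StrainComparison:
    pooled_medians: dict[str, float]
    pooled_u: float
    pooled_p: float
    per_cancer: pd.DataFrame  # cancer, median per strain, U, p
    cross_strain_pearson_r: float


def strain_comparison(subset: Sequence[TumorSample]) -> StrainComparison:
    """Compare purity between the two host strains on a balanced subset.

    Reports pooled and per-cancer medians with two-sided rank-sum tests, and
    the Pearson correlation of per-cancer medians across strains (cancer
    specificity preserved in both hosts shows up as a high correlation).
    """
    strains = sorted({s.strain for s in subset})
    if len(strains) != 2:
        raise ValueError(f"expected exactly two strains, found {strains}")
    a, b = strains
    purities = {st: [s.purity for s in subset if s.strain == st] for st in strains}
    u, p = rank_sum_test(purities[a], purities[b])
    pooled_medians = {st: float(np.median(v)) for st, v in purities.items()}
    rows = []
    for cancer in sorted({s.cancer for s in subset}):
        pa = [s.purity for s in subset if s.cancer == cancer and s.strain == a]
        pb = [s.purity for s in subset if s.cancer == cancer and s.strain == b]
        cu, cp = rank_sum_test(pa, pb)
        rows.append(
            {
                "cancer": cancer,
                f"median_{a}": float(np.median(pa)),
                f"median_{b}": float(np.median(pb)),
                "u_statistic": cu,
                "p_value": cp,
            }
        )
    per_cancer = pd.DataFrame(rows)
    ma = per_cancer[f"median_{a}"].to_numpy()
    mb = per_cancer[f"median_{b}"].to_numpy()
    if len(per_cancer) >= 3 and np.ptp(ma) > 0 and np.ptp(mb) > 0:
        r = float(stats.pearsonr(ma, mb).statistic)
    else:
        r = float("nan")
    return StrainComparison(
        pooled_medians=pooled_medians,
        pooled_u=u,
        pooled_p=p,
        per_cancer=per_cancer,
        cross_strain_pearson_r=r,
    )


def cancer_purity_summary(
    samples: Sequence[TumorSample], min_n: int = 20
) -> tuple[pd.DataFrame, float]:
    """Per-cancer purity quartiles for cancers with at least ``min_n`` samples.

    Also returns the mean of the per-cancer medians, the cohort-level
    headline number.
    """
    by_cancer: dict[str, list[float]] = {}
    for s in samples:
        by_cancer.setdefault(s.cancer, []).append(s.purity)
    rows = []
    for cancer in sorted(by_cancer):
        vals = np.asarray(by_cancer[cancer])
        if len(vals) < min_n:
            continue
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "cancer": cancer,
                "n": len(vals),
                "q25": float(q25),
                "median": float(q50),
                "q75": float(q75),
            }
        )
    table = pd.DataFrame(rows, columns=["cancer", "n", "q25", "median", "q75"])
    mean_of_medians = float(table["median"].mean()) if len(table) else float("nan")
    return table, mean_of_medians


def purity_mutation_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties) of purity vs mutation count.

    ``table`` needs columns ``purity_pct`` and ``n_somatic`` (one row per
    syngeneic model).
    """
    if len(table) < 3:
        raise ValueError("need at least three models")
    res = stats.spearmanr(table["purity_pct"], table["n_somatic"])
    return float(res.statistic), float(res.pvalue)


def load_syngeneic_table() -> pd.DataFrame:
    """Packaged reference table of 19 syngeneic models.

    Columns: model_name, purity_pct (median of five tumors, percent),
    n_somatic (somatic mutation count), cancer.
    """
    with resources.files("xenopurity").joinpath("data/syngeneic_models.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return table
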