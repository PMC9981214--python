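"""ESTIMATE-style stromal/immune scoring in human, mouse and hybrid versions.

The ESTIMATE method scores two 141-gene signatures (stromal, immune) in a
single sample by a rank-based single-sample enrichment statistic (ssGSEA);
their sum, the ESTIMATE score, rises with stromal/immune infiltration and
therefore falls with tumor purity. For mouse tumor models three versions are
needed: the *human* version scores the human signature genes only (in PDX,
the human cells), the *mouse* version scores their mouse orthologs (the
mouse stroma), and the *hybrid* version scores the summed expression of each
human signature gene and its mouse ortholog(s), covering all cells of the
xenograft. The enrichment statistic is implemented here directly (rank
weighting exponent 0.25, no cross-sample normalisation) so no external R
dependency is required; tests check it against a brute-force running-sum
oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "GeneSignature",
    "PURITY_INTERPRETATION",
    "hybridize_expression",
    "ssgsea_score",
    "estimate_scores",
]

#: What the purity derived from each score version measures.
PURITY_INTERPRETATION = {
    "human": "cancer-cell fraction among the human cells of the tumor",
    "mouse": "cancer-cell fraction among the mouse cells of the tumor",
    "hybrid": "cancer-cell fraction among all (human + mouse) cells of the tumor",
}


@dataclass(frozen=True)
class GeneSignature:
    """Stromal and immune signature gene sets with a human->mouse ortholog map.

    ``ortholog_map`` may be partial: signature genes without a mouse ortholog
    are simply unavailable to the mouse version and pass through unchanged in
    hybrid expression.
    """

    stromal_genes: frozenset[str]
    immune_genes: frozenset[str]
    ortholog_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stromal_genes or not self.immune_genes:
            raise ValueError("signature gene sets must be non-empty")

    def mouse_genes(self, human_genes: Iterable[str]) -> frozenset[str]:
        """Union of mouse orthologs of the given human genes."""
        out: set[str] = set()
        for g in human_genes:
            out.update(self.ortholog_map.get(g, ()))
        return frozenset(out)


def hybridize_expression(
    human: pd.DataFrame,
    mouse: pd.DataFrame,
    ortholog_map: Mapping[str, tuple[str, ...]],
) -> pd.DataFrame:
    """Sum each human gene's expression with its mouse ortholog(s).

    Both matrices are genes x samples over the same sample set. The result
    is indexed by the human gene identifiers; genes without an ortholog (or
    whose orthologs are absent from the mouse matrix) keep their human
    value. Mouse genes orthologous to several human genes are credited to
    each (a warning is emitted for such collisions).
    """
    if set(human.columns) != set(mouse.columns):
        raise ValueError("human and mouse matrices must share the same samples")
    mouse = mouse.loc[:, human.columns]
    hybrid = human.astype(float).copy()
    used: dict[str, str] = {}
    for hg, orthologs in ortholog_map.items():
        if hg not in hybrid.index:
            continue
        present = [mg for mg in orthologs if mg in mouse.index]
        for mg in present:
            if mg in used and used[mg] != hg:
                warnings.warn(
                    f"mouse gene {mg} maps to multiple human genes ({used[mg]}, {hg})",
                    stacklevel=2,
                )
            used.setdefault(mg, hg)
        if present:
            hybrid.loc[hg] = hybrid.loc[hg] + mouse.loc[present].sum(axis=0)
    return hybrid


def ssgsea_score(values: pd.Series, gene_set: Iterable[str], alpha: float = 0.25) -> float:
    """Single-sample enrichment of ``gene_set`` in one expression profile.

    Genes are ordered by decreasing expression; a running sum accumulates the
    rank-weighted in-set empirical CDF (weight = ascending rank ** alpha)
    minus the uniform out-of-set CDF, and the score is the sum of that
    difference over all positions. Being rank-based, the score is invariant
    under monotone transforms of the expression values.
    """
    values = values.astype(float)
    n = len(values)
    in_set = values.index.isin(set(gene_set))
    n_set = int(in_set.sum())
    if n_set == 0:
        raise ValueError("gene set has no overlap with the expression profile")
    if n_set == n:
        raise ValueError("gene set covers every expressed gene; out-of-set ECDF undefined")
    ranks = rankdata(values.to_numpy())  # ascending, average ties
    order = np.argsort(-ranks, kind="stable")
    ind = in_set[order]
    w = ranks[order] ** alpha
    p_in = np.cumsum(np.where(ind, w, 0.0)) / np.sum(w[ind])
    p_out = np.cumsum(~ind) / (n - n_set)
    return float(np.sum(p_in - p_out))


def _resolve_set(
    matrix: pd.DataFrame, gene_set: frozenset[str], name: str
) -> list[str]:
    found = [g for g in matrix.index if g in gene_set]
    if not found:
        raise ValueError(f"no {name} signature genes found in the expression matrix")
    if len(found) < 0.5 * len(gene_set):
        warnings.warn(
            f"only {len(found)}/{len(gene_set)} {name} signature genes found in the matrix",
            stacklevel=3,
        )
    return found


def estimate_scores(
    matrix: pd.DataFrame,
    sig: GeneSignature,
    version: str = "human",
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Per-sample stromal, immune and ESTIMATE scores.

    ``matrix`` is genes x samples. For the ``mouse`` version the signature
    is translated through the ortholog map and the matrix must be indexed by
    mouse gene identifiers; for ``human`` and ``hybrid`` the matrix carries
    human identifiers (the hybrid matrix is produced by
    :func:`hybridize_expression`). The ESTIMATE score is exactly
    stromal + immune. The returned frame's ``attrs`` record the version and
    the matching purity interpretation.
    """
    if version not in PURITY_INTERPRETATION:
        raise ValueError(f"version must be one of {sorted(PURITY_INTERPRETATION)}")
    if version == "mouse":
        stromal = frozenset(sig.mouse_genes(sig.stromal_genes))
        immune = frozenset(sig.mouse_genes(sig.immune_genes))
        if not stromal or not immune:
            raise ValueError("ortholog map yields an empty mouse signature")
    else:
        stromal, immune = sig.stromal_genes, sig.immune_genes
    stromal_found = _resolve_set(matrix, stromal, "stromal")
    immune_found = _resolve_set(matrix, immune, "immune")
    rows = []
    for sample in matrix.columns:
        col = matrix[sample]
        s = ssgsea_score(col, stromal_found, alpha=alpha)
        i = ssgsea_score(col, immune_found, alpha=alpha)
        rows.append({"stromal_score": s, "immune_score": i, "estimate_score": s + i})
    out = pd.DataFrame(rows, index=pd.Index(matrix.columns, name="sample"))
    out.attrs["version"] = version
    out.attrs["purity_interpretation"] = PURITY_INTERPRETATION[version]
    return out
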