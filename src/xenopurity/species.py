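"""Species assignment of xenograft reads from comparative alignment scores.

Each read of a PDX sample is aligned to both the human and the mouse
reference; the read is attributed to the species where it aligns better.
Equal scores (within an optional margin) are ambiguous and discarded, as are
reads mapping to neither genome. The proportion of human reads among the
species-assigned reads is a crude purity estimate — it tracks cell fractions
only up to platform bias (e.g. human-targeted exome capture inflates it).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = ["ReadClass", "ReadScorePair", "classify_read", "classify_reads", "read_fraction_purity"]


class ReadClass(enum.Enum):
    HUMAN = "HUMAN"
    MOUSE = "MOUSE"
    AMBIGUOUS = "AMBIGUOUS"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class ReadScorePair:
    """Best alignment score of one read against each genome (None = unmapped)."""

    read_id: str
    score_human: Optional[float] = None
    score_mouse: Optional[float] = None


def classify_read(pair: ReadScorePair, margin: float = 0.0) -> ReadClass:
    """Assign a read to HUMAN/MOUSE/AMBIGUOUS/UNMAPPED.

    A read mapping to a single genome takes that species. A read mapping to
    both is assigned to the higher-scoring genome when the score difference
    exceeds ``margin``, otherwise it is ambiguous.
    """
    h, m = pair.score_human, pair.score_mouse
    if h is None and m is None:
        return ReadClass.UNMAPPED
    if m is None:
        return ReadClass.HUMAN
    if h is None:
        return ReadClass.MOUSE
    if h - m > margin:
        return ReadClass.HUMAN
    if m - h > margin:
        return ReadClass.MOUSE
    return ReadClass.AMBIGUOUS


def classify_reads(
    pairs: Sequence[ReadScorePair], margin: float = 0.0
) -> list[tuple[str, ReadClass]]:
    return [(p.read_id, classify_read(p, margin=margin)) for p in pairs]


def read_fraction_purity(pairs: Sequence[ReadScorePair], margin: float = 0.0) -> float:
    """Proportion of human reads among species-assigned reads.

    Ambiguous and unmapped reads are excluded from the denominator.
    """
    n_human = n_mouse = 0
    for p in pairs:
        cls = classify_read(p, margin=margin)
        if cls is ReadClass.HUMAN:
            n_human += 1
        elif cls is ReadClass.MOUSE:
            n_mouse += 1
    if n_human + n_mouse == 0:
        raise ValueError("no unambiguously species-assigned reads")
    return n_human / (n_human + n_mouse)
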