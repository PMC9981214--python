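"""Deep amplicon-assay purity: median of per-segment human read fractions.

The assay amplifies homologous human/mouse genomic segments with common
primer pairs and sequences them deeply; every mapped read is assignable to a
species because the amplified segments diverge strongly between human and
mouse. The human-cell fraction of a PDX tumor is taken as the median of the
per-segment human read fractions, which is robust to a minority of segments
with amplification or mapping bias.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["SegmentCounts", "segment_fraction", "assay_purity"]


@dataclass(frozen=True)
class SegmentCounts:
    """Species-resolved read counts for one homologous amplicon segment."""

    segment_id: str
    reads_human: int
    reads_mouse: int

    def __post_init__(self) -> None:
        if self.reads_human < 0 or self.reads_mouse < 0:
            raise ValueError(f"negative read count in segment {self.segment_id}")

    @property
    def depth(self) -> int:
        return self.reads_human + self.reads_mouse


def segment_fraction(seg: SegmentCounts) -> float:
    """Human read fraction of one segment; zero-depth segments are unusable."""
    if seg.depth == 0:
        raise ValueError(f"segment {seg.segment_id} has no reads")
    return seg.reads_human / seg.depth


def assay_purity(
    segments: Sequence[SegmentCounts], min_depth: int = 100
) -> tuple[float, pd.DataFrame]:
    """Median human fraction over usable segments, with a per-segment report.

    Segments below ``min_depth`` total reads are excluded. The median of an
    even number of fractions is the mean of the central pair. Returns the
    purity together with a table of every input segment (``used`` marks the
    ones entering the median).
    """
    if len(segments) == 0:
        raise ValueError("assay_purity requires at least one segment")
    rows = []
    fractions = []
    for seg in segments:
        used = seg.depth >= min_depth and seg.depth > 0
        frac = segment_fraction(seg) if seg.depth > 0 else float("nan")
        rows.append(
            {
                "segment_id": seg.segment_id,
                "reads_human": seg.reads_human,
                "reads_mouse": seg.reads_mouse,
                "fraction_human": frac,
                "used": used,
            }
        )
        if used:
            fractions.append(frac)
    if not fractions:
        raise ValueError(f"no usable segments at min_depth={min_depth}")
    report = pd.DataFrame(rows)
    return float(statistics.median(fractions)), report
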