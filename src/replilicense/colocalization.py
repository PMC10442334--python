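"""Venn-style overlap summaries and the random-region permutation null.

The single "overlapping peaks" count reported for two peak sets is defined
as the number of connected components of the pairwise-overlap graph, so
one number can be expressed as a percentage of either set.  Per-set
matched-peak counts are reported alongside.

Reported percentages are *truncated* (not rounded) at the displayed
precision; full-precision values are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .genome import GenomeLayout, PeakSet, intersect, sample_random_regions

__all__ = [
    "VennCounts",
    "NullOverlapResult",
    "overlap_venn",
    "venn_percentages",
    "permutation_overlap_null",
    "truncate",
]


def truncate(x: float, decimals: int = 0) -> float:
    """Truncate (floor toward zero for non-negative x) at *decimals* places."""
    scale = 10 ** decimals
    return math.floor(x * scale) / scale


@dataclass(frozen=True)
class VennCounts:
    n_a: int
    n_b: int
    n_overlap_components: int
    n_a_matched: int
    n_b_matched: int

    def __post_init__(self):
        if not (
            self.n_a_matched >= self.n_overlap_components
            and self.n_b_matched >= self.n_overlap_components
            and self.n_a_matched <= self.n_a
            and self.n_b_matched <= self.n_b
        ):
            raise ValueError(f"inconsistent Venn counts: {self}")

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_overlap_components": self.n_overlap_components,
            "n_a_matched": self.n_a_matched,
            "n_b_matched": self.n_b_matched,
        }


@dataclass(frozen=True)
class NullOverlapResult:
    """Per-draw overlap percentages of randomly placed regions and their median."""

    draw_pcts: tuple[float, ...]
    median_pct: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if any(p < 0 or p > 100 for p in self.draw_pcts):
            raise ValueError("overlap percentages must lie in [0, 100]")
        object.__setattr__(self, "median_pct", float(np.median(self.draw_pcts)))


def overlap_venn(a: PeakSet, b: PeakSet, layout: GenomeLayout) -> VennCounts:
    components, a_norm, b_norm = intersect(a, b, layout)
    a_matched = set()
    b_matched = set()
    for c in components:
        a_matched.update(c.a_indices)
        b_matched.update(c.b_indices)
    return VennCounts(
        n_a=len(a_norm),
        n_b=len(b_norm),
        n_overlap_components=len(components),
        n_a_matched=len(a_matched),
        n_b_matched=len(b_matched),
    )


def venn_percentages(
    v: VennCounts, decimals: Optional[int] = None
) -> tuple[float, float]:
    """Overlap count as a percentage of each set.

    With ``decimals`` given, percentages are truncated at that precision
    (``decimals=0`` reproduces integer-percent figure labels); with
    ``decimals=None`` full-precision values are returned.
    """
    if v.n_a == 0 or v.n_b == 0:
        raise ZeroDivisionError("venn_percentages undefined for an empty set")
    pct_a = 100.0 * v.n_overlap_components / v.n_a
    pct_b = 100.0 * v.n_overlap_components / v.n_b
    if decimals is None:
        return pct_a, pct_b
    return truncate(pct_a, decimals), truncate(pct_b, decimals)


def permutation_overlap_null(
    reference: PeakSet,
    target: PeakSet,
    layout: GenomeLayout,
    n_draws: int = 10,
    seed: Union[int, np.random.Generator] = 0,
) -> NullOverlapResult:
    """Random-region null for peak colocalization.

    Each draw places ``len(reference)`` regions uniformly on the genome
    with lengths resampled from the reference length multiset, and scores
    the percentage of placed regions that overlap *target* by >= 1 bp.
    The draw medians summarize how much overlap chance alone produces.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = reference.lengths()
    n = len(reference)
    target = target.normalized(layout)
    draws = []
    for _ in range(n_draws):
        regions = sample_random_regions(layout, n, lengths, rng)
        hits = target.overlaps_any(regions)
        draws.append(100.0 * float(hits.sum()) / n if n else 0.0)
    return NullOverlapResult(tuple(draws))
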