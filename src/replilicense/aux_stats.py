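"""EM nucleosome-occupancy R-values and copy-number co-occurrence analysis.

The R-value summarizes electron-microscopy spreads of chromatin fibers:
the combined contour length of all nucleosome "bubbles" on a DNA stretch
divided by the stretch's total contour length, i.e. the occupied fraction
in [0, 1].

The CNA stage classifies clone-level copy-number segments (diploid
baseline 2; gain above 2.3, loss below 1.7 by default - thresholds are
config-exposed), removes gains that also arise spontaneously in control
clones, extracts regions recurrently gained across clones, and tests
per-locus co-amplification with NFIB in patient cohorts by a one-sided
Fisher exact test with BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import PeakSet
from .origins import bh_adjust

__all__ = [
    "EMTrace",
    "r_value",
    "mean_r_value",
    "CNAConfig",
    "classify_segments",
    "gain_peaks",
    "subtract_control_gains",
    "recurrent_amplifications",
    "cooccurrence_with_nfib",
    "cohort_validation_fraction",
]


@dataclass(frozen=True)
class EMTrace:
    """One EM-traced DNA stretch: nucleosome bubble lengths and total length.

    Lengths are contour units (nm or bp-equivalents); only ratios matter.
    """

    bubble_lengths: tuple[float, ...]
    total_length: float

    def __post_init__(self):
        if self.total_length <= 0:
            raise ValueError("total_length must be > 0")
        if any(b <= 0 for b in self.bubble_lengths):
            raise ValueError("bubble lengths must be > 0")
        if sum(self.bubble_lengths) > self.total_length * (1 + 1e-9):
            raise ValueError("combined bubble length exceeds total length")


def r_value(trace: EMTrace) -> float:
    """Nucleosome occupancy: summed bubble length / total contour length."""
    return float(sum(trace.bubble_lengths)) / trace.total_length


def mean_r_value(traces: Sequence[EMTrace]) -> float:
    return float(np.mean([r_value(t) for t in traces]))


@dataclass(frozen=True)
class CNAConfig:
    gain_threshold: float = 2.3
    loss_threshold: float = 1.7
    min_clones: int = 2

    def __post_init__(self):
        if not self.loss_threshold < self.gain_threshold:
            raise ValueError("loss_threshold must be below gain_threshold")


def classify_segments(segments: pd.DataFrame, cfg: CNAConfig = CNAConfig()) -> pd.DataFrame:
    """Label SEG-like rows (chrom, start, end, clone, copy_number) gain/loss/neutral."""
    out = segments.copy()
    cn = out["copy_number"].to_numpy(dtype=float)
    cls = np.full(len(out), "neutral", dtype=object)
    cls[cn > cfg.gain_threshold] = "gain"
    cls[cn < cfg.loss_threshold] = "loss"
    out["class"] = cls
    return out


def gain_peaks(segments: pd.DataFrame, cfg: CNAConfig = CNAConfig()) -> PeakSet:
    """Merged gain intervals of one clone's classified segment table."""
    labelled = classify_segments(segments, cfg)
    gains = labelled.loc[labelled["class"] == "gain", ["chrom", "start", "end"]]
    return PeakSet(gains).merge(0)


def subtract_control_gains(sample: PeakSet, control: PeakSet) -> PeakSet:
    """Sample gain intervals minus (merged) control gain intervals, base-pair-wise."""
    return sample.subtract(control)


def recurrent_amplifications(
    clone_gains: Sequence[PeakSet], min_clones: int = 2
) -> PeakSet:
    """Maximal regions gained in at least *min_clones* clones.

    Each clone's gains are merged first so a clone contributes depth 1
    anywhere it is gained.  With min_clones above the clone count the
    result is empty (with a warning).
    """
    if len(clone_gains) == 0:
        raise ValueError("need at least one clone")
    if min_clones > len(clone_gains):
        warnings.warn(
            f"min_clones={min_clones} exceeds the {len(clone_gains)} clones; "
            "no region can recur", stacklevel=2,
        )
        return PeakSet()
    events: dict[str, list[tuple[int, int]]] = {}
    for gains in clone_gains:
        for row in gains.merge(0).df.itertuples(index=False):
            events.setdefault(row.chrom, []).append((int(row.start), +1))
            events[row.chrom].append((int(row.end), -1))
    rows = []
    for chrom in sorted(events):
        depth = 0
        region_start: Optional[int] = None
        for pos, delta in sorted(events[chrom]):
            new_depth = depth + delta
            if depth < min_clones <= new_depth:
                region_start = pos
            elif new_depth < min_clones <= depth and region_start is not None:
                if pos > region_start:
                    rows.append((chrom, region_start, pos))
                region_start = None
            depth = new_depth
    # adjacent events at the same position are handled by processing in
    # position order; a +1/-1 at the same pos nets out before emission
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"])).merge(0)


def cooccurrence_with_nfib(
    matrix: pd.DataFrame, nfib_col: str = "NFIB_amplified"
) -> pd.DataFrame:
    """Per-locus co-amplification with NFIB across patients.

    *matrix* is patients x loci boolean amplification calls plus a boolean
    NFIB-amplified column.  Each locus gets a one-sided Fisher exact test
    (alternative: amplification enriched among NFIB-amplified patients) on
    the 2x2 locus-by-NFIB table, with BH adjustment across loci.
    """
    if nfib_col not in matrix.columns:
        raise KeyError(f"missing {nfib_col!r} column")
    nfib = matrix[nfib_col].to_numpy(dtype=bool)
    if nfib.all() or (~nfib).all():
        raise ValueError("degenerate margins: all patients share one NFIB class")
    loci = [c for c in matrix.columns if c != nfib_col]
    rows = []
    for locus in loci:
        amp = matrix[locus].to_numpy(dtype=bool)
        table = [
            [int((amp & nfib).sum()), int((amp & ~nfib).sum())],
            [int((~amp & nfib).sum()), int((~amp & ~nfib).sum())],
        ]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "locus": locus,
                "n_amp_nfib": table[0][0],
                "n_amp_other": table[0][1],
                "odds_ratio": float(odds),
                "p_fisher": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["q_bh"] = bh_adjust(out["p_fisher"].to_numpy())
    return out


def cohort_validation_fraction(
    sample_regions: PeakSet, significant_cohort_loci: Sequence[PeakSet]
) -> Optional[float]:
    """Fraction of sample regions overlapping a significant locus in any cohort.

    The cohort union is taken first (a region validated in one cohort
    counts).  Returns None for an empty sample set (undefined).
    """
    if len(sample_regions) == 0:
        warnings.warn("empty sample region set: validation fraction undefined", stacklevel=2)
        return None
    if len(significant_cohort_loci) == 0:
        return 0.0
    union = PeakSet(
        pd.concat([p.df for p in significant_cohort_loci], ignore_index=True)
    ).merge(0)
    hits = union.overlaps_any(sample_regions)
    return float(hits.sum()) / len(sample_regions)
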