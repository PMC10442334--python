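"""Control-vs-knockdown differential signal over peaks.

Implements the fold-change rule used to call binding changes upon factor
depletion (cutoff 1.2 by default), the derivation of N1 peaks (overlapped
ORC1 peaks whose ORC1 *and* NFIB signals both drop on NFIB knockdown), and
a simplified differential-accessibility caller for ATAC-style replicate
count matrices (library-size normalization + two-sample t-test on logs at
|log2FC| > log2(1.2), p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import BinnedTrack, OverlapComponent, PeakSet

__all__ = [
    "DifferentialConfig",
    "quantify_peaks",
    "classify_fold_change",
    "derive_n1",
    "classify_accessibility",
]

LABELS = ("decreased", "increased", "unchanged")


@dataclass(frozen=True)
class DifferentialConfig:
    fc_cutoff: float = 1.2
    pseudocount: float = 0.5
    accessibility_alpha: float = 0.01

    def __post_init__(self):
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must be > 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def quantify_peaks(
    peaks: PeakSet, control: BinnedTrack, knockdown: BinnedTrack
) -> pd.DataFrame:
    """Mean control/knockdown signal over each peak, as a differential table."""
    tbl = peaks.df[["chrom", "start", "end"]].copy()
    tbl["signal_control"] = control.mean_signal_many(peaks)
    tbl["signal_kd"] = knockdown.mean_signal_many(peaks)
    return tbl


def classify_fold_change(
    tbl: pd.DataFrame, cfg: DifferentialConfig = DifferentialConfig()
) -> pd.DataFrame:
    """Label each peak decreased / increased / unchanged (knockdown vs control).

    decreased iff (control+pc)/(kd+pc) > fc_cutoff; increased iff
    (kd+pc)/(control+pc) > fc_cutoff; otherwise unchanged.  The three
    labels partition any table.  ``log2fc`` is knockdown over control.
    """
    out = tbl.copy()
    pc = cfg.pseudocount
    ctrl = out["signal_control"].to_numpy(dtype=float) + pc
    kd = out["signal_kd"].to_numpy(dtype=float) + pc
    if (ctrl <= 0).any() or (kd <= 0).any():
        raise ValueError("signals must be >= 0")
    out["log2fc"] = np.log2(kd / ctrl)
    label = np.full(len(out), "unchanged", dtype=object)
    label[ctrl / kd > cfg.fc_cutoff] = "decreased"
    label[kd / ctrl > cfg.fc_cutoff] = "increased"
    out["label"] = label
    return out


def derive_n1(
    nfib_tbl: pd.DataFrame,
    orc1_tbl: pd.DataFrame,
    components: Sequence[OverlapComponent],
    orc1_peaks: PeakSet,
) -> tuple[PeakSet, Optional[float]]:
    """N1 peaks: overlapped ORC1 peaks where both factors lose signal.

    ``nfib_tbl``/``orc1_tbl`` must be labelled tables whose row order
    matches the normalized peak sets the overlap components index into
    (``orc1_peaks`` being the normalized ORC1 set).  An ORC1 peak enters
    N1 when it is labelled decreased and at least one directly overlapping
    NFIB peak is labelled decreased too.

    Returns the N1 peak set (on ORC1 intervals) and the consistency
    percentage: N1 as a share of all overlapped, decreased ORC1 peaks
    (``None`` when that denominator is empty).
    """
    nfib_dec = nfib_tbl["label"].to_numpy() == "decreased"
    orc1_dec = orc1_tbl["label"].to_numpy() == "decreased"
    partners: dict[int, list[int]] = {}
    overlapped_orc1: set[int] = set()
    for comp in components:
        overlapped_orc1.update(comp.b_indices)
        for ai, bi in comp.pairs:
            partners.setdefault(bi, []).append(ai)
    denominator = [j for j in overlapped_orc1 if orc1_dec[j]]
    n1_idx = sorted(
        j for j in denominator if any(nfib_dec[i] for i in partners.get(j, ()))
    )
    consistency = (
        100.0 * len(n1_idx) / len(denominator) if denominator else None
    )
    return orc1_peaks.select(n1_idx), consistency


def classify_accessibility(
    counts: pd.DataFrame,
    control_cols: Sequence[str],
    knockdown_cols: Sequence[str],
    cfg: DifferentialConfig = DifferentialConfig(),
) -> pd.DataFrame:
    """Group peaks as open / close / unchanged upon factor depletion.

    Counts are normalized to the mean library size, compared by a
    two-sided pooled t-test on log(normalized count + pseudocount).
    "open" = accessibility falls on depletion (the factor was needed to
    keep the region open); "close" = accessibility rises.  Both calls
    require |log2FC| > log2(fc_cutoff) and p < accessibility_alpha.
    """
    if len(control_cols) < 2 or len(knockdown_cols) < 2:
        raise ValueError("need >= 2 replicates per condition for the t-test")
    out = counts.copy()
    all_cols = list(control_cols) + list(knockdown_cols)
    mat = counts[all_cols].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be >= 0")
    libs = mat.sum(axis=0)
    norm = mat / libs * libs.mean()
    pc = cfg.pseudocount
    nc = len(control_cols)
    log_norm = np.log(norm + pc)
    tt = stats.ttest_ind(log_norm[:, :nc], log_norm[:, nc:], axis=1, equal_var=True)
    mean_ctrl = norm[:, :nc].mean(axis=1)
    mean_kd = norm[:, nc:].mean(axis=1)
    log2fc = np.log2((mean_kd + pc) / (mean_ctrl + pc))
    pvals = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
    sig = (pvals < cfg.accessibility_alpha) & (
        np.abs(log2fc) > np.log2(cfg.fc_cutoff)
    )
    group = np.full(len(out), "unchanged", dtype=object)
    group[sig & (log2fc < 0)] = "open"
    group[sig & (log2fc > 0)] = "close"
    out["mean_control"] = mean_ctrl
    out["mean_kd"] = mean_kd
    out["log2fc"] = log2fc
    out["p_ttest"] = pvals
    out["group"] = group
    return out
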