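"""Nascent-strand origin filtering, S1/S2/S3 classes, and replication timing.

Nascent-strand sequencing (NS-seq) maps fired replication origins from
short RNA-primed DNA; an RNase-treated half-library serves as the negative
control.  A candidate peak is kept as a true origin when it is enriched in
the untreated library by a one-sided Fisher exact test (BH FDR <= 0.05)
AND its library-normalized log2(untreated/treated) ratio is >= log2(1.2).

Kept origins are then classified by their response to factor knockdown
with the shared fold-change rule (cutoff 1.2): S1 = signal decreased,
S2 = increased, S3 = unchanged.  Replication timing is assigned from
three S-phase-fraction coverage tracks (early / mid / late) by argmax of
the library-normalized mean signal over each peak, ties resolved toward
the earlier fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import BinnedTrack, GenomicInterval, PeakSet

__all__ = [
    "NSFilterConfig",
    "TimingProfile",
    "fisher_rnase_test",
    "bh_adjust",
    "ns_log2_ratio",
    "filter_true_ns",
    "classify_s123",
    "assign_timing",
    "timing_distribution",
]

TIMING_CLASSES = ("early", "mid", "late")
S_CLASSES = {"decreased": "S1", "increased": "S2", "unchanged": "S3"}


@dataclass(frozen=True)
class NSFilterConfig:
    fdr: float = 0.05
    fc: float = 1.2
    pseudocount: float = 0.5

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.fc <= 1:
            raise ValueError("fc must be > 1")


def fisher_rnase_test(
    count_untreated: int, count_treated: int, lib_untreated: int, lib_treated: int
) -> float:
    """One-sided Fisher exact p for untreated enrichment at one peak.

    The 2x2 table is [(in-peak, rest-of-library) x (untreated, treated)];
    the alternative is enrichment in the untreated library.  Computed as
    the upper hypergeometric tail P(X >= count_untreated) with
    X ~ HG(N = lib_u + lib_t, K = count_u + count_t, n = lib_u).
    """
    cu, ct, lu, lt = map(int, (count_untreated, count_treated, lib_untreated, lib_treated))
    if cu > lu or ct > lt:
        raise ValueError("peak count exceeds its library total")
    if min(cu, ct) < 0 or min(lu, lt) <= 0:
        raise ValueError("counts must be non-negative and library totals positive")
    return float(stats.hypergeom.sf(cu - 1, lu + lt, cu + ct, lu))


def _fisher_vec(cu: np.ndarray, ct: np.ndarray, lu: int, lt: int) -> np.ndarray:
    return stats.hypergeom.sf(cu - 1, lu + lt, cu + ct, lu)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ns_log2_ratio(
    cu: np.ndarray, ct: np.ndarray, lu: float, lt: float, pseudocount: float = 0.5
) -> np.ndarray:
    """log2 untreated/treated on library-size-normalized, pseudocounted counts."""
    cu = np.asarray(cu, dtype=float)
    ct = np.asarray(ct, dtype=float)
    return np.log2(((cu + pseudocount) / lu) / ((ct + pseudocount) / lt))


def filter_true_ns(
    records: pd.DataFrame, cfg: NSFilterConfig = NSFilterConfig()
) -> pd.DataFrame:
    """RNase-control filter: flag candidate peaks that are true NS peaks.

    *records* needs columns count_untreated, count_treated, lib_untreated,
    lib_treated.  Adds p_fisher, q_bh, log2_ratio and is_true_ns (kept iff
    q_bh <= fdr AND log2_ratio >= log2(fc)).
    """
    out = records.copy()
    cu = out["count_untreated"].to_numpy()
    ct = out["count_treated"].to_numpy()
    lu = out["lib_untreated"].to_numpy()
    lt = out["lib_treated"].to_numpy()
    if (cu > lu).any() or (ct > lt).any():
        raise ValueError("peak count exceeds its library total")
    if len(np.unique(lu)) == 1 and len(np.unique(lt)) == 1:
        p = _fisher_vec(cu.astype(np.int64), ct.astype(np.int64), int(lu[0]), int(lt[0]))
    else:
        p = np.array(
            [fisher_rnase_test(a, b, c, d) for a, b, c, d in zip(cu, ct, lu, lt)]
        )
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    out["p_fisher"] = p
    out["q_bh"] = bh_adjust(p)
    out["log2_ratio"] = ns_log2_ratio(cu, ct, lu.astype(float), lt.astype(float), cfg.pseudocount)
    out["is_true_ns"] = (out["q_bh"] <= cfg.fdr) & (
        out["log2_ratio"] >= np.log2(cfg.fc)
    )
    return out


def classify_s123(
    tbl: pd.DataFrame, fc_cutoff: float = 1.2, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Partition true NS peaks into S1/S2/S3 by knockdown response.

    Uses the same pseudocounted fold-change rule as the binding
    differential: S1 iff control/kd > cutoff, S2 iff kd/control > cutoff,
    S3 otherwise.  Requires signal_control and signal_kd columns.
    """
    from .differential import DifferentialConfig, classify_fold_change

    cfg = DifferentialConfig(fc_cutoff=fc_cutoff, pseudocount=pseudocount)
    out = classify_fold_change(tbl, cfg)
    out["s_class"] = out["label"].map(S_CLASSES)
    return out


@dataclass
class TimingProfile:
    """Library-normalized early/mid/late S-phase-fraction coverage tracks."""

    early: BinnedTrack
    mid: BinnedTrack
    late: BinnedTrack

    @classmethod
    def from_tracks(
        cls, early: BinnedTrack, mid: BinnedTrack, late: BinnedTrack
    ) -> "TimingProfile":
        """Normalize each fraction to global mean 1 (per-library scaling)."""
        tracks = []
        for t in (early, mid, late):
            gm = t.global_mean()
            if gm <= 0:
                raise ValueError("cannot normalize an all-zero timing track")
            tracks.append(t.scaled(1.0 / gm))
        return cls(*tracks)

    def tracks(self) -> tuple[BinnedTrack, BinnedTrack, BinnedTrack]:
        return self.early, self.mid, self.late


def assign_timing(peaks: PeakSet, profile: TimingProfile, tol: float = 1e-12) -> np.ndarray:
    """Per-peak timing label: argmax of the three mean fraction signals.

    Ties break toward the earlier fraction; a peak with no signal in any
    fraction is labelled "unassigned".
    """
    labels = np.full(len(peaks), "unassigned", dtype=object)
    for i, row in enumerate(peaks.df.itertuples(index=False)):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        sig = np.array([t.mean_signal(iv) for t in profile.tracks()])
        if np.all(sig <= tol):
            continue
        labels[i] = TIMING_CLASSES[int(np.argmax(sig))]
    return labels


def timing_distribution(
    categories: Mapping[str, np.ndarray], labels: np.ndarray
) -> pd.DataFrame:
    """Per-category fractions of peaks replicating early / mid / late.

    *categories* maps a name to an index or boolean mask into *labels*.
    Fractions are over assigned peaks and sum to 1 per non-empty category;
    the unassigned share is reported separately.  Empty categories get NaN
    fractions and are flagged via n = 0.
    """
    labels = np.asarray(labels, dtype=object)
    rows = []
    for name, idx in categories.items():
        sub = labels[np.asarray(idx)]
        n = len(sub)
        assigned = sub[sub != "unassigned"]
        row = {"category": name, "n": n, "n_assigned": len(assigned)}
        for cls in TIMING_CLASSES:
            row[cls] = (
                float((assigned == cls).sum()) / len(assigned)
                if len(assigned)
                else float("nan")
            )
        row["unassigned_fraction"] = (n - len(assigned)) / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")
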