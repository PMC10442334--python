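"""A/B compartment dynamics from per-bin PC1 eigenvector tables.

Compartments are taken at a fixed bin size (250 kb by default) with the
first principal eigenvector (PC1) of the contact matrix supplied as input
per replicate and condition.  PC1 sign is arbitrary per chromosome, so it
is first oriented against gene density (A = positive = gene-dense).  Bins
are then classified between conditions with a per-bin two-sample t-test
(pooled variance, p < 0.05 by default) and a seven-way category scheme
covering every sign/magnitude case, and N1-peak enrichment per category is
scored against the unchanged bins with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import PeakSet

__all__ = [
    "CompartmentConfig",
    "CATEGORIES",
    "orient_pc1",
    "classify_bins",
    "n1_count_per_bin",
    "n1_enrichment",
    "EnrichmentResult",
]

CATEGORIES = (
    "A-weakened",
    "A-strengthened",
    "B-weakened",
    "B-strengthened",
    "A-to-B",
    "B-to-A",
    "unchanged",
)


@dataclass(frozen=True)
class CompartmentConfig:
    bin: int = 250_000
    alpha: float = 0.05
    welch: bool = False          # Welch t-test instead of pooled-variance
    midpoint_assignment: bool = False  # count a peak only in its midpoint bin

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def orient_pc1(
    tbl: pd.DataFrame,
    pc1_cols: Sequence[str],
    density_col: str = "gene_density",
) -> pd.DataFrame:
    """Flip PC1 sign per chromosome so that A (positive) is gene-dense.

    The mean PC1 across all replicate columns is correlated with gene
    density per chromosome; a negative correlation flips every PC1 column
    on that chromosome.  Zero-variance PC1 on a chromosome is an error.
    """
    if density_col not in tbl.columns:
        raise KeyError(f"missing {density_col!r} column")
    out = tbl.copy()
    for chrom, sub in out.groupby("chrom", sort=False):
        pc1_mean = sub[list(pc1_cols)].mean(axis=1).to_numpy()
        if np.std(pc1_mean) == 0:
            raise ValueError(f"zero-variance PC1 on chromosome {chrom!r}")
        dens = sub[density_col].to_numpy(dtype=float)
        if np.std(dens) == 0:
            continue  # orientation undefined; leave as-is
        r = np.corrcoef(pc1_mean, dens)[0, 1]
        if r < 0:
            out.loc[sub.index, list(pc1_cols)] = -sub[list(pc1_cols)]
    return out


def classify_bins(
    tbl: pd.DataFrame,
    control_cols: Sequence[str],
    knockdown_cols: Sequence[str],
    cfg: CompartmentConfig = CompartmentConfig(),
) -> pd.DataFrame:
    """Classify each bin's compartment change between conditions.

    A two-sided two-sample t-test compares replicate PC1 values; bins with
    p >= alpha are unchanged.  Significant bins are categorized from the
    condition means: same positive sign -> A-weakened / A-strengthened by
    |mean| shrinking / growing, same negative sign analogously for B, and
    a sign change -> A-to-B or B-to-A.  Bins where both conditions have
    zero variance are unchanged when the means agree and flagged
    significant (p reported as 0) when they differ.
    """
    if len(control_cols) < 2 or len(knockdown_cols) < 2:
        raise ValueError("need >= 2 replicates per condition for the t-test")
    out = tbl.copy()
    ctrl = out[list(control_cols)].to_numpy(dtype=float)
    kd = out[list(knockdown_cols)].to_numpy(dtype=float)
    mc = ctrl.mean(axis=1)
    mk = kd.mean(axis=1)
    tt = stats.ttest_ind(ctrl, kd, axis=1, equal_var=not cfg.welch)
    p = np.asarray(tt.pvalue, dtype=float)
    degenerate = (ctrl.var(axis=1) == 0) & (kd.var(axis=1) == 0)
    zero_var_diff = degenerate & ~np.isclose(mc, mk)
    p = np.where(degenerate, np.where(zero_var_diff, 0.0, 1.0), p)

    category = np.full(len(out), "unchanged", dtype=object)
    sig = p < cfg.alpha
    pos_pos = sig & (mc >= 0) & (mk >= 0)
    neg_neg = sig & (mc < 0) & (mk < 0)
    category[pos_pos & (np.abs(mk) < np.abs(mc))] = "A-weakened"
    category[pos_pos & (np.abs(mk) >= np.abs(mc))] = "A-strengthened"
    category[neg_neg & (np.abs(mk) < np.abs(mc))] = "B-weakened"
    category[neg_neg & (np.abs(mk) >= np.abs(mc))] = "B-strengthened"
    category[sig & (mc >= 0) & (mk < 0)] = "A-to-B"
    category[sig & (mc < 0) & (mk >= 0)] = "B-to-A"

    out["mean_ctrl"] = mc
    out["mean_kd"] = mk
    out["p_ttest"] = p
    out["zero_variance"] = degenerate
    out["category"] = category
    return out


def n1_count_per_bin(
    change_tbl: pd.DataFrame, n1: PeakSet, midpoint: bool = False
) -> np.ndarray:
    """Number of N1 peaks per bin.

    By default a peak spanning a bin boundary is counted in every bin it
    overlaps; with ``midpoint=True`` it is counted only in the bin holding
    its midpoint (making bin counts sum exactly to the peak count).
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in n1.df.groupby("chrom", sort=False):
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        if midpoint:
            mids = np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
            by_chrom[chrom] = (mids, mids)
        else:
            by_chrom[chrom] = (starts, ends)
    counts = np.zeros(len(change_tbl), dtype=int)
    for i, row in enumerate(change_tbl.itertuples(index=False)):
        if row.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[row.chrom]
        if midpoint:
            counts[i] = int(
                np.searchsorted(starts, row.end, side="left")
                - np.searchsorted(starts, row.start, side="left")
            )
        else:
            n = len(starts)
            n_right = n - int(np.searchsorted(starts, row.end, side="left"))
            n_left = int(np.searchsorted(ends, row.start, side="right"))
            counts[i] = n - n_right - n_left
    return counts


@dataclass
class EnrichmentResult:
    counts_per_bin: np.ndarray
    per_category: dict[str, np.ndarray]
    tests: pd.DataFrame  # category, n_bins, U, p, skipped

    def significant(self, category: str, alpha: float = 0.05) -> bool:
        row = self.tests.set_index("category").loc[category]
        return bool(not row["skipped"] and row["p"] < alpha)


def n1_enrichment(
    change_tbl: pd.DataFrame,
    n1: PeakSet,
    cfg: CompartmentConfig = CompartmentConfig(),
) -> EnrichmentResult:
    """Per-category distribution of N1 peaks per bin, tested vs unchanged.

    Each non-unchanged category's per-bin N1 counts are compared with the
    unchanged bins by a two-sided Mann-Whitney U test.  Categories with
    fewer than two bins (or an unchanged reference with fewer than two)
    are skipped and flagged.
    """
    counts = n1_count_per_bin(change_tbl, n1, midpoint=cfg.midpoint_assignment)
    cats = change_tbl["category"].to_numpy()
    per_cat = {c: counts[cats == c] for c in CATEGORIES}
    ref = per_cat["unchanged"]
    rows = []
    for c in CATEGORIES:
        if c == "unchanged":
            continue
        vals = per_cat[c]
        if len(vals) < 2 or len(ref) < 2:
            rows.append({"category": c, "n_bins": len(vals), "U": np.nan, "p": np.nan, "skipped": True})
            continue
        u, p = stats.mannwhitneyu(vals, ref, alternative="two-sided")
        rows.append({"category": c, "n_bins": len(vals), "U": float(u), "p": float(p), "skipped": False})
    return EnrichmentResult(counts, per_cat, pd.DataFrame(rows))
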