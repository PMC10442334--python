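"""Genome model, interval algebra, binned signal tracks, and text-format I/O.

Coordinates are 0-based, half-open (BED convention) throughout.  Strand is
ignored: none of the analyses in this package are strand-aware.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "PeakSet",
    "BinnedTrack",
    "OverlapComponent",
    "intersect",
    "sample_random_regions",
    "coverage_fraction",
]


class GenomeLayout:
    """An ordered set of named chromosomes with lengths in bp.

    The chromosome order given at construction defines the sort order used
    when normalizing :class:`PeakSet` objects.
    """

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = [(str(n), int(l)) for n, l in chromosomes]
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")
        self.chromosomes: tuple[tuple[str, int], ...] = tuple(chroms)
        self._order = {n: i for i, (n, _) in enumerate(chroms)}
        self._length = dict(chroms)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def __contains__(self, name: str) -> bool:
        return name in self._length

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self.chromosomes == other.chromosomes

    def length(self, name: str) -> int:
        try:
            return self._length[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def order(self, name: str) -> int:
        try:
            return self._order[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def n_bins(self, bin_width: int, chrom: str) -> int:
        return -(-self.length(chrom) // bin_width)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_chrom_sizes(cls, path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(zip(df["chrom"].astype(str), df["length"].astype(int)))

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for n, l in self.chromosomes:
                fh.write(f"{n}\t{l}\n")

    def __repr__(self) -> str:
        return f"GenomeLayout({list(self.chromosomes)!r})"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


_BED_COLS = ["chrom", "start", "end", "name", "score"]


class PeakSet:
    """An ordered collection of genomic intervals (peaks).

    Internally a DataFrame with columns chrom/start/end/name/score.  Most
    operations require a *normalized* set: sorted by (layout chromosome
    order, start, end) with all intervals inside the layout.
    """

    def __init__(self, df: Optional[pd.DataFrame] = None, *, is_sorted: bool = False):
        if df is None:
            df = pd.DataFrame({c: [] for c in _BED_COLS})
        df = df.copy()
        for col in ("name", "score"):
            if col not in df.columns:
                df[col] = None
        df = df[_BED_COLS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative coordinates in peak set")
        if (df["end"] <= df["start"]).any():
            raise ValueError("empty or inverted interval in peak set")
        self.df = df
        self.is_sorted = is_sorted

    # -- construction ------------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "PeakSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.name, iv.score) for iv in intervals]
        return cls(pd.DataFrame(rows, columns=_BED_COLS)) if rows else cls()

    @classmethod
    def from_arrays(cls, chroms, starts, ends, names=None, scores=None) -> "PeakSet":
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        if names is not None:
            df["name"] = names
        if scores is not None:
            df["score"] = scores
        return cls(df)

    @classmethod
    def read_bed(cls, path) -> "PeakSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise ValueError(f"{path}: not a BED3+ file")
        df = df.iloc[:, : min(df.shape[1], 5)]
        df.columns = _BED_COLS[: df.shape[1]]
        df["chrom"] = df["chrom"].astype(str)
        return cls(df)

    def write_bed(self, path) -> None:
        df = self.df
        has_name = df["name"].notna().any()
        has_score = df["score"].notna().any()
        out = df[["chrom", "start", "end"]].copy()
        if has_name or has_score:
            out["name"] = df["name"].fillna(".")
        if has_score:
            out["score"] = df["score"].fillna(0)
        out.to_csv(path, sep="\t", header=False, index=False)

    # -- basics ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), row.name, row.score)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def select(self, indices) -> "PeakSet":
        return PeakSet(self.df.iloc[np.asarray(indices, dtype=int)], is_sorted=False)

    def normalized(self, layout: GenomeLayout) -> "PeakSet":
        """Sort by (chromosome order, start, end) and bounds-check.

        Raises ``KeyError`` naming any chromosome absent from *layout* and
        ``ValueError`` for out-of-bounds intervals.
        """
        df = self.df
        for c in pd.unique(df["chrom"]):
            if c not in layout:
                raise KeyError(f"unknown chromosome {c!r}")
        lengths = df["chrom"].map(layout.length)
        if (df["end"] > lengths).any():
            bad = df.loc[df["end"] > lengths].iloc[0]
            raise ValueError(
                f"interval {bad.chrom}:{bad.start}-{bad.end} exceeds chromosome length"
            )
        order = df["chrom"].map(layout.order)
        idx = np.lexsort((df["end"].to_numpy(), df["start"].to_numpy(), order.to_numpy()))
        return PeakSet(df.iloc[idx], is_sorted=True)

    # -- algebra -----------------------------------------------------------
    def merge(self, gap: int = 0) -> "PeakSet":
        """Merge intervals closer than or equal to *gap* bp apart.

        With gap=0 the merged set covers exactly the same bases as the
        input.  Input need not be normalized; output is sorted by
        (chromosome name, start) and pairwise separated by more than *gap*.
        """
        if gap < 0:
            raise ValueError(f"negative gap {gap}")
        if len(self) == 0:
            return PeakSet(is_sorted=True)
        out_rows = []
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        for chrom, sub in df.groupby("chrom", sort=True):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e + gap:
                    cur_e = max(cur_e, e)
                else:
                    out_rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out_rows.append((chrom, cur_s, cur_e))
        return PeakSet(pd.DataFrame(out_rows, columns=["chrom", "start", "end"]), is_sorted=True)

    def subtract(self, other: "PeakSet") -> "PeakSet":
        """Base-pair set difference: pieces of self not covered by other."""
        mask = other.merge(0)
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in mask.df.groupby("chrom", sort=False):
            by_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        rows = []
        for row in self.df.itertuples(index=False):
            pieces = [(row.start, row.end)]
            if row.chrom in by_chrom:
                ms, me = by_chrom[row.chrom]
                new = []
                for s, e in pieces:
                    lo = np.searchsorted(me, s, side="right")
                    hi = np.searchsorted(ms, e, side="left")
                    cur = s
                    for k in range(lo, hi):
                        if ms[k] > cur:
                            new.append((cur, int(ms[k])))
                        cur = max(cur, int(me[k]))
                    if cur < e:
                        new.append((cur, e))
                pieces = new
            rows.extend((row.chrom, s, e) for s, e in pieces)
        return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def overlaps_any(self, regions: "PeakSet") -> np.ndarray:
        """Boolean array: does each interval of *regions* overlap this set?"""
        merged = self.merge(0)
        by_chrom = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
            for chrom, sub in merged.df.groupby("chrom", sort=False)
        }
        hits = np.zeros(len(regions), dtype=bool)
        for i, row in enumerate(regions.df.itertuples(index=False)):
            if row.chrom not in by_chrom:
                continue
            ms, me = by_chrom[row.chrom]
            k = np.searchsorted(me, row.start, side="right")
            hits[i] = k < len(ms) and ms[k] < row.end
        return hits


@dataclass(frozen=True)
class OverlapComponent:
    """A maximal connected component of the pairwise-overlap graph.

    ``a_indices``/``b_indices`` are row positions into the *normalized*
    input sets; ``pairs`` lists the direct (a, b) overlap edges.
    """

    a_indices: tuple[int, ...]
    b_indices: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]


def intersect(a: PeakSet, b: PeakSet, layout: GenomeLayout) -> tuple[list[OverlapComponent], PeakSet, PeakSet]:
    """Connected components of the bipartite overlap graph of two peak sets.

    Two intervals are connected when they share at least 1 bp.  Returns the
    component list plus the normalized copies of ``a`` and ``b`` that the
    component indices refer to.  Intervals overlapping no member of the
    other set are not reported.
    """
    a = a if a.is_sorted else a.normalized(layout)
    b = b if b.is_sorted else b.normalized(layout)

    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    pairs: list[tuple[int, int]] = []
    adf, bdf = a.df, b.df
    for chrom in pd.unique(pd.concat([adf["chrom"], bdf["chrom"]], ignore_index=True)):
        rows = []
        sub_a = adf.index[adf["chrom"] == chrom]
        sub_b = bdf.index[bdf["chrom"] == chrom]
        for i in sub_a:
            rows.append((int(adf.at[i, "start"]), int(adf.at[i, "end"]), "a", int(i)))
        for j in sub_b:
            rows.append((int(bdf.at[j, "start"]), int(bdf.at[j, "end"]), "b", int(j)))
        rows.sort(key=lambda r: (r[0], r[1]))
        active = {"a": [], "b": []}  # heaps of (end, idx)
        for start, end, side, idx in rows:
            for h in active.values():
                while h and h[0][0] <= start:
                    heapq.heappop(h)
            other = "b" if side == "a" else "a"
            for e2, idx2 in active[other]:
                # all remaining actives end after `start`, so they overlap
                pair = (idx, idx2) if side == "a" else (idx2, idx)
                pairs.append(pair)
                union((side, idx), (other, idx2))
            for e2, idx2 in active[side]:
                # same-set overlaps chain components but are not a/b pairs
                union((side, idx), (side, idx2))
            heapq.heappush(active[side], (end, idx))

    groups: dict[tuple[str, int], dict] = {}
    for node in list(parent):
        side, idx = node
        root = find(node)
        g = groups.setdefault(root, {"a": set(), "b": set(), "pairs": []})
        g[side].add(idx)
    for ai, bi in pairs:
        groups[find(("a", ai))]["pairs"].append((ai, bi))
    components = [
        OverlapComponent(
            tuple(sorted(g["a"])), tuple(sorted(g["b"])), tuple(sorted(set(g["pairs"])))
        )
        for g in groups.values()
        if g["a"] and g["b"]
    ]
    components.sort(key=lambda c: c.a_indices[0])
    return components, a, b


class BinnedTrack:
    """Fixed-bin-width signal over a genome: one float array per chromosome.

    Bin ``k`` of a chromosome covers ``[k*w, min((k+1)*w, chrom_len))``;
    arrays have ``ceil(chrom_len / w)`` entries.
    """

    def __init__(self, bin_width: int, values: dict[str, np.ndarray], layout: GenomeLayout):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bin_width = int(bin_width)
        self.layout = layout
        self.values: dict[str, np.ndarray] = {}
        for chrom, arr in values.items():
            arr = np.asarray(arr, dtype=float)
            expected = layout.n_bins(bin_width, chrom)
            if len(arr) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins of {bin_width} bp, got {len(arr)}"
                )
            self.values[chrom] = arr

    @classmethod
    def zeros(cls, layout: GenomeLayout, bin_width: int) -> "BinnedTrack":
        return cls(
            bin_width,
            {n: np.zeros(layout.n_bins(bin_width, n)) for n in layout.names},
            layout,
        )

    @classmethod
    def constant(cls, layout: GenomeLayout, bin_width: int, value: float) -> "BinnedTrack":
        t = cls.zeros(layout, bin_width)
        for arr in t.values.values():
            arr[:] = value
        return t

    def _bin_extents(self, chrom: str) -> np.ndarray:
        n = len(self.values[chrom])
        ends = np.minimum(
            (np.arange(n) + 1) * self.bin_width, self.layout.length(chrom)
        )
        starts = np.arange(n) * self.bin_width
        return ends - starts

    def mean_signal(self, iv: GenomicInterval) -> float:
        """Length-weighted mean of bin values overlapping *iv*."""
        if iv.chrom not in self.values:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.layout.length(iv.chrom):
            raise ValueError(f"interval end {iv.end} beyond chromosome {iv.chrom}")
        w = self.bin_width
        b0 = iv.start // w
        b1 = (iv.end - 1) // w
        idx = np.arange(b0, b1 + 1)
        left = np.maximum(iv.start, idx * w)
        right = np.minimum(iv.end, (idx + 1) * w)
        return float(np.average(self.values[iv.chrom][b0 : b1 + 1], weights=right - left))

    def mean_signal_many(self, peaks: PeakSet) -> np.ndarray:
        return np.array(
            [self.mean_signal(GenomicInterval(r.chrom, r.start, r.end)) for r in peaks.df.itertuples(index=False)]
        ) if len(peaks) else np.array([])

    def global_mean(self) -> float:
        """Bin-extent-weighted mean over the whole genome."""
        tot = 0.0
        bp = 0
        for chrom, arr in self.values.items():
            ext = self._bin_extents(chrom)
            tot += float(np.dot(arr, ext))
            bp += int(ext.sum())
        return tot / bp

    def scaled(self, factor: float) -> "BinnedTrack":
        return BinnedTrack(
            self.bin_width, {c: a * factor for c, a in self.values.items()}, self.layout
        )

    # -- I/O ---------------------------------------------------------------
    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.layout.names:
                if chrom not in self.values:
                    continue
                arr = self.values[chrom]
                w = self.bin_width
                clen = self.layout.length(chrom)
                for k, v in enumerate(arr):
                    fh.write(f"{chrom}\t{k * w}\t{min((k + 1) * w, clen)}\t{v:g}\n")

    @classmethod
    def read_bedgraph(cls, path, layout: GenomeLayout, bin_width: Optional[int] = None) -> "BinnedTrack":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
        df["chrom"] = df["chrom"].astype(str)
        spans = (df["end"] - df["start"]).to_numpy()
        if bin_width is None:
            bin_width = int(np.bincount(spans).argmax())
        track = cls.zeros(layout, bin_width)
        for row in df.itertuples(index=False):
            if row.start % bin_width != 0:
                raise ValueError(f"bedGraph row not aligned to {bin_width}-bp grid: {row}")
            expected_end = min(row.start + bin_width, layout.length(row.chrom))
            if row.end != expected_end:
                raise ValueError(f"bedGraph row has irregular bin width: {row}")
            track.values[row.chrom][row.start // bin_width] = row.value
        return track


def sample_random_regions(
    layout: GenomeLayout,
    n: int,
    lengths: Sequence[int],
    rng_seed: Union[int, np.random.Generator],
) -> PeakSet:
    """Draw *n* random regions, lengths sampled with replacement from *lengths*.

    Start positions are uniform over all valid placements genome-wide
    (chromosomes weighted by their number of valid starts for the drawn
    length).  Deterministic for a given seed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    lengths = np.asarray(lengths, dtype=np.int64)
    if n == 0 or len(lengths) == 0:
        return PeakSet()
    max_len = max(l for _, l in layout.chromosomes)
    if lengths.max() > max_len:
        raise ValueError("region length exceeds the longest chromosome")
    clens = np.array([l for _, l in layout.chromosomes], dtype=np.int64)
    names = layout.names
    drawn = lengths[rng.integers(0, len(lengths), size=n)]
    rows = []
    for L in drawn:
        placements = np.clip(clens - L + 1, 0, None)
        total = placements.sum()
        u = rng.integers(0, total)
        ci = int(np.searchsorted(np.cumsum(placements), u, side="right"))
        start = int(u - np.concatenate(([0], np.cumsum(placements)))[ci])
        rows.append((names[ci], start, start + int(L)))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def coverage_fraction(p: PeakSet, layout: GenomeLayout) -> float:
    """Fraction of the genome covered by the (merged) peak set."""
    merged = p.normalized(layout).merge(0)
    return float(merged.lengths().sum()) / layout.total_bp
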