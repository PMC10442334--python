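import numpy as np
import pandas as pd
import pytest

from replilicense.genome import GenomeLayout, PeakSet


@pytest.fixture
def toy_layout():
    return GenomeLayout([("chr1", 10_000), ("chr2", 8_000)])


@pytest.fixture
def tiny_layout():
    return GenomeLayout([("chrT", 1_000)])


def make_peaks(rows):
    """rows: iterable of (chrom, start, end)."""
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def random_peaks(rng, layout, n, max_len=200):
    rows = []
    for _ in range(n):
        chrom, clen = layout.chromosomes[rng.integers(0, len(layout.chromosomes))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, max(clen - length, 0) + 1))
        rows.append((chrom, start, start + length))
    return make_peaks(rows)


# ---------------------------------------------------------------------------
# per-base brute-force oracles (independent of the sweep implementations)

def oracle_component_count(a, b, layout):
    """Connected components of the overlap graph, via per-base union-find."""
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    base_owner = {}
    for side, peaks in (("a", a), ("b", b)):
        for i, row in enumerate(peaks.df.itertuples(index=False)):
            for pos in range(row.start, row.end):
                base_owner.setdefault((row.chrom, pos), []).append((side, i))
    for members in base_owner.values():
        for m in members[1:]:
            union(members[0], m)
    comps = {}
    for node in parent:
        comps.setdefault(find(node), set()).add(node)
    mixed = [c for c in comps.values() if {s for s, _ in c} == {"a", "b"}]
    a_matched = {i for c in mixed for s, i in c if s == "a"}
    b_matched = {i for c in mixed for s, i in c if s == "b"}
    return len(mixed), a_matched, b_matched


def oracle_merge(peaks, layout, gap=0):
    """Merged intervals via a per-base mask, then joining runs <= gap apart."""
    out = []
    for chrom, clen in layout.chromosomes:
        mask = np.zeros(clen, dtype=bool)
        for row in peaks.df.itertuples(index=False):
            if row.chrom == chrom:
                mask[row.start : row.end] = True
        covered = np.flatnonzero(mask)
        if len(covered) == 0:
            continue
        breaks = np.flatnonzero(np.diff(covered) > 1)
        starts = covered[np.concatenate(([0], breaks + 1))]
        ends = covered[np.concatenate((breaks, [len(covered) - 1]))] + 1
        merged = []
        for s, e in zip(starts, ends):
            if merged and s - merged[-1][1] <= gap:
                merged[-1][1] = max(merged[-1][1], int(e))
            else:
                merged.append([int(s), int(e)])
        out.extend((chrom, s, e) for s, e in merged)
    return sorted(out)


def oracle_subtract(a, b, layout):
    """Per-base set difference as sorted maximal runs."""
    out = []
    for chrom, clen in layout.chromosomes:
        keep = np.zeros(clen, dtype=bool)
        for row in a.df.itertuples(index=False):
            if row.chrom == chrom:
                keep[row.start : row.end] = True
        for row in b.df.itertuples(index=False):
            if row.chrom == chrom:
                keep[row.start : row.end] = False
        covered = np.flatnonzero(keep)
        if len(covered) == 0:
            continue
        breaks = np.flatnonzero(np.diff(covered) > 1)
        starts = covered[np.concatenate(([0], breaks + 1))]
        ends = covered[np.concatenate((breaks, [len(covered) - 1]))] + 1
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return sorted(out)


def oracle_depth_regions(peak_sets, layout, min_depth):
    """Maximal regions covered by >= min_depth of the given sets (per-base)."""
    out = []
    for chrom, clen in layout.chromosomes:
        depth = np.zeros(clen, dtype=int)
        for peaks in peak_sets:
            mask = np.zeros(clen, dtype=bool)
            for row in peaks.df.itertuples(index=False):
                if row.chrom == chrom:
                    mask[row.start : row.end] = True
            depth += mask
        covered = np.flatnonzero(depth >= min_depth)
        if len(covered) == 0:
            continue
        breaks = np.flatnonzero(np.diff(covered) > 1)
        starts = covered[np.concatenate(([0], breaks + 1))]
        ends = covered[np.concatenate((breaks, [len(covered) - 1]))] + 1
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return sorted(out)


def peaks_as_tuples(peaks):
    return sorted(
        (r.chrom, int(r.start), int(r.end)) for r in peaks.df.itertuples(index=False)
    )
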