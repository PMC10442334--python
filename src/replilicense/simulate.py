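"""Synthetic multi-omics study generator with a known planted truth.

Emulates, on a toy genome (3 chromosomes x 10 Mb by default), the study
design every downstream stage consumes:

* NFIB binding sites; ORC1 sites that either depend on NFIB (placed on an
  NFIB site, attenuated on knockdown) or bind independently;
* control / knockdown coverage tracks for both factors (negative-binomial
  counts per 1-kb bin, dispersion from config);
* an ATAC-style replicate count matrix with planted open/close/unchanged
  peaks;
* a nascent-strand count table with RNase-treated background and planted
  S1 (knockdown-decreased) / S2 (compensatory, increased) / S3 (stable)
  origin classes plus dormant origins and pure-background decoy peaks;
* early / mid / late S-phase Repli-seq fraction tracks over planted timing
  domains (chromosome thirds by default);
* replicate PC1 tables at 250-kb compartment bins with planted weakened-A
  bins, into which NFIB-dependent sites are preferentially placed;
* clone-level copy-number segments with planted recurrent co-amplified
  regions plus spontaneous gains shared with control clones, and patient
  cohort amplification matrices with planted NFIB co-occurrence.

One global seed drives everything; each output draws from its own named
sub-stream so adding an output never perturbs earlier ones.  Dispersion 0
(and PC1 noise 0) is the exact zero-noise limit: emitted values equal
their planted means and downstream classification recovers the truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import BinnedTrack, GenomeLayout, PeakSet

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "StudyData",
    "simulate_study",
    "simulate_ns_counts",
    "simulate_em_traces",
    "nb_sample",
    "default_layout",
]

# fixed sub-stream ids: one per output family
_STREAMS = {
    "structure": 1,
    "sites": 2,
    "tracks": 3,
    "atac": 4,
    "ns": 5,
    "repliseq": 6,
    "pc1": 7,
    "cna": 8,
    "cohort": 9,
}


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON-serializable: {o!r}")


def default_layout() -> GenomeLayout:
    return GenomeLayout([("chr1", 10_000_000), ("chr2", 10_000_000), ("chr3", 10_000_000)])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Effect sizes mirror the analysed experiment: a two-fold knockdown
    effect against a 1.2 fold-change calling cutoff, negative-binomial
    count noise (dispersion 0.1), nascent-strand fragments of 0.5-2 kb,
    250-kb compartment bins, and a Gaussian PC1 replicate error.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    track_bin: int = 1000
    # binding sites
    n_nfib_sites: int = 300
    frac_orc1_dependent: float = 0.45   # per NFIB site: hosts a dependent ORC1 site
    n_orc1_independent: int = 120
    site_width: tuple[int, int] = (5000, 8000)
    signal_amplitude: float = 120.0     # per-bin mean coverage at a site
    background_level: float = 2.0
    knockdown_fc: float = 2.0
    noise_dispersion: float = 0.1       # NB overdispersion; 0 = exact means
    # ATAC
    n_atac_close_sites: int = 80
    n_atac_unchanged_sites: int = 600
    atac_mean_count: float = 100.0
    # nascent strands
    ns_fragment_range: tuple[int, int] = (500, 2000)
    ns_mean_count: float = 60.0
    rnase_background_rate: float = 0.1
    ns_library_size: int = 500_000
    n_s2_origins: int = 140
    n_s3_origins: int = 100
    n_dormant_origins: int = 60
    n_ns_decoys: int = 100
    # replication timing
    timing_domains: Optional[list[tuple[str, int, int, str]]] = None  # (chrom, start, end, class)
    p_dependent_early: float = 0.7
    repliseq_amplitude: float = 50.0
    # compartments
    compartment_bin: int = 250_000
    n_weakened_A_bins: int = 15
    p_dependent_in_weakened: float = 0.5
    weakening_factor: float = 0.4       # kd PC1 = factor * ctrl PC1 in weakened bins
    pc1_noise_sd: float = 0.1
    n_replicates: int = 2
    # copy-number clones and cohorts
    n_clones: int = 3                   # NFIB-overexpressing clones
    n_control_clones: int = 3
    n_planted_cnas: int = 12
    n_fragile_sites: int = 8            # spontaneous-gain pool shared with controls
    n_spontaneous_losses: int = 3
    n_cohorts: int = 4
    n_patients: int = 200
    frac_nfib_amplified: float = 0.3
    p_coamp_given_nfib: float = 0.55
    p_coamp_background: float = 0.08
    n_decoy_loci: int = 30
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_orc1_dependent", "p_dependent_early",
                     "p_dependent_in_weakened", "frac_nfib_amplified",
                     "p_coamp_given_nfib", "p_coamp_background"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.knockdown_fc <= 1:
            raise ValueError(f"knockdown_fc must be > 1, got {self.knockdown_fc}")
        if self.noise_dispersion < 0:
            raise ValueError(f"noise_dispersion must be >= 0, got {self.noise_dispersion}")
        if self.pc1_noise_sd < 0:
            raise ValueError(f"pc1_noise_sd must be >= 0, got {self.pc1_noise_sd}")
        if not self.ns_fragment_range[0] < self.ns_fragment_range[1]:
            raise ValueError("ns_fragment_range must be an increasing (lo, hi) pair")
        if self.track_bin <= 0:
            raise ValueError("track_bin must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def nb_sample(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with var = m + dispersion * m^2.

    dispersion 0 degenerates to the exact mean (the zero-noise limit used
    by recovery tests), not to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return mean.copy()
    lam = np.where(
        mean > 0, rng.gamma(1.0 / dispersion, mean * dispersion), 0.0
    )
    return rng.poisson(lam).astype(float)


@dataclass
class PlantedTruth:
    """Ground-truth ledger for recovery tests."""

    nfib_sites: PeakSet
    orc1_sites: PeakSet
    orc1_dependent: np.ndarray          # bool per ORC1 site (row order of orc1_sites)
    origins: pd.DataFrame               # chrom/start/end/origin_class/timing
    weakened_A_bins: pd.DataFrame       # chrom/start/end
    clone_cnas: pd.DataFrame            # chrom/start/end/clone/copy_number/planted
    coamp_loci: pd.DataFrame            # chrom/start/end/locus/coamplified

    def validate(self) -> None:
        dep = self.orc1_sites.df.loc[np.asarray(self.orc1_dependent)]
        nfib = self.nfib_sites.df
        for row in dep.itertuples(index=False):
            sub = nfib[nfib["chrom"] == row.chrom]
            if not ((sub["start"] < row.end) & (sub["end"] > row.start)).any():
                raise AssertionError(
                    f"dependent ORC1 site {row.chrom}:{row.start}-{row.end} "
                    "overlaps no NFIB site"
                )

    def to_json(self, path) -> None:
        payload = {
            "nfib_sites": self.nfib_sites.df[["chrom", "start", "end"]].to_dict("records"),
            "orc1_sites": self.orc1_sites.df[["chrom", "start", "end"]].to_dict("records"),
            "orc1_dependent": [bool(x) for x in self.orc1_dependent],
            "origins": self.origins.to_dict("records"),
            "weakened_A_bins": self.weakened_A_bins.to_dict("records"),
            "clone_cnas": self.clone_cnas.to_dict("records"),
            "coamp_loci": self.coamp_loci.to_dict("records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default))


@dataclass
class StudyData:
    """All simulated tracks and tables, plus the truth ledger."""

    config: SimulationConfig
    nfib_peaks: PeakSet
    orc1_peaks: PeakSet
    tracks: dict[str, BinnedTrack]      # nfib_ctrl, nfib_kd, orc1_ctrl, orc1_kd
    atac_counts: pd.DataFrame
    ns_table: pd.DataFrame
    repliseq: dict[str, BinnedTrack]    # early, mid, late
    pc1_table: pd.DataFrame
    clone_segments: pd.DataFrame        # all clones, SEG-like
    control_clones: list[str]
    overexpressing_clones: list[str]
    cohorts: list[pd.DataFrame]
    truth: PlantedTruth

    def write(self, outdir) -> None:
        """Emit every input file in its standard text format."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.layout.write_chrom_sizes(out / "genome.chrom.sizes")
        self.nfib_peaks.write_bed(out / "nfib_peaks.bed")
        self.orc1_peaks.write_bed(out / "orc1_peaks.bed")
        for name, track in {**self.tracks, **{f"repliseq_{k}": v for k, v in self.repliseq.items()}}.items():
            track.write_bedgraph(out / f"{name}.bedgraph")
        self.atac_counts.to_csv(out / "atac_counts.tsv", sep="\t", index=False)
        self.ns_table.to_csv(out / "ns_counts.tsv", sep="\t", index=False)
        self.pc1_table.to_csv(out / "pc1_table.tsv", sep="\t", index=False)
        self.clone_segments.to_csv(out / "clone_cna.seg.tsv", sep="\t", index=False)
        for i, cohort in enumerate(self.cohorts, start=1):
            cohort.to_csv(out / f"cohort_{i}_amplification.tsv", sep="\t", index=False)
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# placement helpers

def _default_timing_domains(layout: GenomeLayout) -> list[tuple[str, int, int, str]]:
    domains = []
    for chrom, clen in layout.chromosomes:
        third = clen // 3
        domains.append((chrom, 0, third, "early"))
        domains.append((chrom, third, 2 * third, "mid"))
        domains.append((chrom, 2 * third, clen, "late"))
    return domains


def _uniform_position(rng, layout, width) -> tuple[str, int]:
    clens = np.array([l for _, l in layout.chromosomes])
    placements = np.clip(clens - width + 1, 0, None)
    u = rng.integers(0, placements.sum())
    ci = int(np.searchsorted(np.cumsum(placements), u, side="right"))
    offset = int(u - np.concatenate(([0], np.cumsum(placements)))[ci])
    return layout.names[ci], offset


def _position_in_regions(rng, regions: Sequence[tuple[str, int, int]], width: int):
    spans = np.array([max(e - s - width, 1) for _, s, e in regions])
    k = int(rng.choice(len(regions), p=spans / spans.sum()))
    chrom, s, e = regions[k]
    start = int(s + rng.integers(0, max(e - s - width, 1)))
    return chrom, start


class _SitePlacer:
    """Rejection-samples non-overlapping intervals (with a small guard gap)."""

    def __init__(self, layout: GenomeLayout, gap: int = 500):
        self.layout = layout
        self.gap = gap
        self.taken: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.names}

    def _free(self, chrom, start, end) -> bool:
        for s, e in self.taken[chrom]:
            if start < e + self.gap and s < end + self.gap:
                return False
        return True

    def reserve(self, chrom, start, end) -> bool:
        if end > self.layout.length(chrom):
            return False
        if not self._free(chrom, start, end):
            return False
        self.taken[chrom].append((start, end))
        return True


def _place_sites(rng, layout, placer, n, width_range, region_chooser, max_tries=200):
    rows = []
    for _ in range(n):
        for _attempt in range(max_tries):
            width = int(rng.integers(width_range[0], width_range[1] + 1))
            chrom, start = region_chooser(rng, width)
            if placer.reserve(chrom, start, start + width):
                rows.append((chrom, start, start + width))
                break
        else:
            raise RuntimeError("could not place all sites; genome too crowded")
    return rows


# ---------------------------------------------------------------------------
# stage generators

def _add_site_coverage(mean: dict[str, np.ndarray], sites, amplitudes, bin_width, layout):
    for (chrom, start, end), amp in zip(sites, amplitudes):
        b0 = start // bin_width
        b1 = (end - 1) // bin_width
        idx = np.arange(b0, b1 + 1)
        left = np.maximum(start, idx * bin_width)
        right = np.minimum(end, (idx + 1) * bin_width)
        frac = (right - left) / np.minimum(
            bin_width, layout.length(chrom) - idx * bin_width
        )
        mean[chrom][b0 : b1 + 1] += amp * frac


def _coverage_track(rng, layout, bin_width, sites, amplitudes, background, dispersion):
    mean = {c: np.full(layout.n_bins(bin_width, c), float(background)) for c in layout.names}
    _add_site_coverage(mean, sites, amplitudes, bin_width, layout)
    return BinnedTrack(
        bin_width, {c: nb_sample(rng, m, dispersion) for c, m in mean.items()}, layout
    )


def simulate_ns_counts(
    origins: pd.DataFrame, cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Untreated/RNase-treated counts per candidate nascent-strand peak.

    Active origins (activity > 0) draw untreated counts around
    ``activity * ns_mean_count`` while treated counts come from the RNase
    background (``rnase_background_rate * ns_mean_count``); dormant
    origins and decoys draw both from background.
    """
    rng = rng if rng is not None else cfg.rng("ns")
    activity = origins["activity"].to_numpy(dtype=float)
    bg = cfg.rnase_background_rate * cfg.ns_mean_count
    untreated_mean = np.where(activity > 0, activity * cfg.ns_mean_count, bg)
    treated_mean = np.full(len(origins), bg)
    out = origins.copy()
    out["count_untreated"] = np.rint(nb_sample(rng, untreated_mean, cfg.noise_dispersion)).astype(int)
    out["count_treated"] = np.rint(nb_sample(rng, treated_mean, cfg.noise_dispersion)).astype(int)
    out["lib_untreated"] = cfg.ns_library_size
    out["lib_treated"] = cfg.ns_library_size
    return out


def simulate_em_traces(
    occupancy: float, n_traces: int, total_len_bp: int, seed: int
) -> list:
    """EM-style traces: nucleosome bubbles on DNA stretches.

    Each trace is divided into 147-bp nucleosome footprints occupied
    independently with probability *occupancy*; runs of occupied units
    form bubbles.  The mean R-value converges to *occupancy*.
    """
    from .aux_stats import EMTrace

    if not 0 <= occupancy <= 1:
        raise ValueError("occupancy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    unit = 147
    n_units = max(total_len_bp // unit, 1)
    traces = []
    for _ in range(n_traces):
        occ = rng.random(n_units) < occupancy
        bubbles = []
        run = 0
        for o in occ:
            if o:
                run += 1
            elif run:
                bubbles.append(float(run * unit))
                run = 0
        if run:
            bubbles.append(float(run * unit))
        traces.append(EMTrace(tuple(bubbles), float(n_units * unit)))
    return traces


# ---------------------------------------------------------------------------

def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Generate the full synthetic study; deterministic for a given seed."""
    cfg.validate()
    layout = cfg.layout
    timing_domains = cfg.timing_domains or _default_timing_domains(layout)
    early_domains = [(c, s, e) for c, s, e, t in timing_domains if t == "early"]

    # -- compartment structure (A/B blocks, gene density, weakened-A bins) --
    rng = cfg.rng("structure")
    cw = cfg.compartment_bin
    bins = []
    for chrom, clen in layout.chromosomes:
        n = -(-clen // cw)
        for k in range(n):
            is_a = (k // 5) % 2 == 0  # alternate A/B blocks of 5 bins
            bins.append((chrom, k * cw, min((k + 1) * cw, clen), is_a))
    bin_df = pd.DataFrame(bins, columns=["chrom", "start", "end", "is_A"])
    dens = np.where(
        bin_df["is_A"], rng.gamma(4.0, 3.0, len(bin_df)), rng.gamma(2.0, 1.0, len(bin_df))
    )
    bin_df["gene_density"] = dens
    base_pc1 = np.where(bin_df["is_A"], 1.0, -1.0) + rng.normal(0, 0.08, len(bin_df))
    base_pc1 = np.where(bin_df["is_A"], np.abs(base_pc1), -np.abs(base_pc1))
    bin_df["pc1_base"] = base_pc1

    early_mask = np.zeros(len(bin_df), dtype=bool)
    for chrom, s, e in early_domains:
        early_mask |= (
            (bin_df["chrom"] == chrom) & (bin_df["start"] < e) & (bin_df["end"] > s)
        ).to_numpy()
    candidates = np.flatnonzero(bin_df["is_A"].to_numpy() & early_mask)
    if cfg.n_weakened_A_bins > len(candidates):
        raise ValueError(
            f"n_weakened_A_bins={cfg.n_weakened_A_bins} exceeds the "
            f"{len(candidates)} early A-compartment bins available"
        )
    weak_idx = np.sort(rng.choice(candidates, size=cfg.n_weakened_A_bins, replace=False))
    weakened_bins = bin_df.iloc[weak_idx][["chrom", "start", "end"]].reset_index(drop=True)
    weak_regions = [(r.chrom, int(r.start), int(r.end)) for r in weakened_bins.itertuples(index=False)]

    # -- binding sites ------------------------------------------------------
    rng = cfg.rng("sites")
    placer = _SitePlacer(layout)
    dependent_flags = rng.random(cfg.n_nfib_sites) < cfg.frac_orc1_dependent

    def choose_dependent(r, width):
        if r.random() < cfg.p_dependent_in_weakened:
            return _position_in_regions(r, weak_regions, width)
        if r.random() < cfg.p_dependent_early:
            return _position_in_regions(r, early_domains, width)
        return _uniform_position(r, layout, width)

    def choose_uniform(r, width):
        return _uniform_position(r, layout, width)

    nfib_rows = []
    orc1_rows = []
    orc1_dep_flags = []
    for dep in dependent_flags:
        chooser = choose_dependent if dep else choose_uniform
        (row,) = _place_sites(rng, layout, placer, 1, cfg.site_width, chooser)
        nfib_rows.append(row)
        if dep:
            # dependent ORC1 site: offset within the NFIB site, guaranteed overlap
            chrom, s, e = row
            width = int(rng.integers(cfg.site_width[0], cfg.site_width[1] + 1))
            shift = int(rng.integers(-(e - s) // 3, (e - s) // 3 + 1))
            o_start = max(s + shift, 0)
            o_end = min(o_start + width, layout.length(chrom))
            if o_end <= s or o_start >= e:  # paranoid: force overlap
                o_start, o_end = s, e
            orc1_rows.append((chrom, o_start, o_end))
            orc1_dep_flags.append(True)
    indep_rows = _place_sites(
        rng, layout, placer, cfg.n_orc1_independent, cfg.site_width, choose_uniform
    )
    orc1_rows.extend(indep_rows)
    orc1_dep_flags.extend([False] * len(indep_rows))

    nfib_peaks = PeakSet(pd.DataFrame(nfib_rows, columns=["chrom", "start", "end"])).normalized(layout)
    orc1_df = pd.DataFrame(orc1_rows, columns=["chrom", "start", "end"])
    orc1_df["dependent"] = orc1_dep_flags
    order = np.lexsort(
        (orc1_df["start"].to_numpy(), orc1_df["chrom"].map(layout.order).to_numpy())
    )
    orc1_df = orc1_df.iloc[order].reset_index(drop=True)
    orc1_peaks = PeakSet(orc1_df[["chrom", "start", "end"]], is_sorted=True)
    orc1_dependent = orc1_df["dependent"].to_numpy()

    # -- factor coverage tracks --------------------------------------------
    rng = cfg.rng("tracks")
    amp = cfg.signal_amplitude
    fc = cfg.knockdown_fc
    nfib_sites = [tuple(r) for r in nfib_peaks.df[["chrom", "start", "end"]].itertuples(index=False)]
    orc1_sites = [tuple(r) for r in orc1_df[["chrom", "start", "end"]].itertuples(index=False)]
    tracks = {
        "nfib_ctrl": _coverage_track(
            rng, layout, cfg.track_bin, nfib_sites, [amp] * len(nfib_sites),
            cfg.background_level, cfg.noise_dispersion,
        ),
        # knockdown depletes the factor: every NFIB site drops
        "nfib_kd": _coverage_track(
            rng, layout, cfg.track_bin, nfib_sites, [amp / fc] * len(nfib_sites),
            cfg.background_level, cfg.noise_dispersion,
        ),
        "orc1_ctrl": _coverage_track(
            rng, layout, cfg.track_bin, orc1_sites, [amp] * len(orc1_sites),
            cfg.background_level, cfg.noise_dispersion,
        ),
        # only NFIB-dependent ORC1 sites lose binding
        "orc1_kd": _coverage_track(
            rng, layout, cfg.track_bin, orc1_sites,
            [amp / fc if d else amp for d in orc1_dependent],
            cfg.background_level, cfg.noise_dispersion,
        ),
    }

    # -- ATAC count matrix --------------------------------------------------
    rng = cfg.rng("atac")
    atac_placer = placer  # keep ATAC decoys off the binding sites too
    close_rows = _place_sites(rng, layout, atac_placer, cfg.n_atac_close_sites, cfg.site_width, choose_uniform)
    stable_rows = _place_sites(rng, layout, atac_placer, cfg.n_atac_unchanged_sites, cfg.site_width, choose_uniform)
    a = cfg.atac_mean_count
    atac_rows = (
        [(c, s, e, "open", a, a / fc) for c, s, e in nfib_sites]
        + [(c, s, e, "close", a / fc, a) for c, s, e in close_rows]
        + [(c, s, e, "unchanged", a, a) for c, s, e in stable_rows]
    )
    atac = pd.DataFrame(atac_rows, columns=["chrom", "start", "end", "true_group", "mu_ctrl", "mu_kd"])
    for cond, mu_col in (("ctrl", "mu_ctrl"), ("kd", "mu_kd")):
        for rep in range(1, cfg.n_replicates + 1):
            atac[f"{cond}_{rep}"] = np.rint(
                nb_sample(rng, atac[mu_col].to_numpy(), cfg.noise_dispersion)
            ).astype(int)
    atac_counts = atac.drop(columns=["mu_ctrl", "mu_kd"])

    # -- nascent-strand origins ---------------------------------------------
    rng = cfg.rng("ns")
    frag_lo, frag_hi = cfg.ns_fragment_range
    origin_rows = []  # chrom,start,end,origin_class,activity_ctrl,activity_kd
    for (chrom, s, e), dep in zip(orc1_sites, orc1_dependent):
        if dep:
            mid = (s + e) // 2
            w = int(rng.integers(frag_lo, frag_hi + 1))
            start = max(mid - w // 2, 0)
            origin_rows.append((chrom, start, start + w, "S1-dependent", 1.0, 1.0 / fc))
    for cls, n, act_ctrl, act_kd in (
        ("S2-compensatory", cfg.n_s2_origins, 1.0, fc),
        ("S3-stable", cfg.n_s3_origins, 1.0, 1.0),
        ("dormant", cfg.n_dormant_origins, 0.0, 0.0),
    ):
        rows = _place_sites(rng, layout, placer, n, (frag_lo, frag_hi), choose_uniform)
        origin_rows.extend((c, s, e, cls, act_ctrl, act_kd) for c, s, e in rows)
    decoy_rows = _place_sites(rng, layout, placer, cfg.n_ns_decoys, (frag_lo, frag_hi), choose_uniform)
    origin_rows.extend((c, s, e, "decoy", 0.0, 0.0) for c, s, e in decoy_rows)
    origins = pd.DataFrame(
        origin_rows, columns=["chrom", "start", "end", "origin_class", "activity", "activity_kd"]
    )
    ns_table = simulate_ns_counts(origins, cfg, rng)
    # per-condition NS signal: mean coverage over the peak's bins
    # NS coverage is quantified at fragment-pile resolution (250 bp),
    # finer than the track bin, so a peak's mean averages several units
    ns_sub_bin = 250
    k_bins = np.maximum((ns_table["end"] - ns_table["start"]) // ns_sub_bin, 1).to_numpy()
    bg = cfg.rnase_background_rate * cfg.ns_mean_count

    def _signal(mean_per_bin):
        return np.array(
            [
                nb_sample(rng, np.full(k, m), cfg.noise_dispersion).mean()
                for m, k in zip(mean_per_bin, k_bins)
            ]
        )

    ns_table["signal_control"] = _signal(
        np.where(origins["activity"] > 0, origins["activity"] * cfg.ns_mean_count, bg)
    )
    ns_table["signal_kd"] = _signal(
        np.where(origins["activity_kd"] > 0, origins["activity_kd"] * cfg.ns_mean_count, bg)
    )
    ns_table = ns_table.drop(columns=["activity", "activity_kd"])

    # -- Repli-seq fraction tracks -------------------------------------------
    rng = cfg.rng("repliseq")
    repliseq = {}
    for phase in ("early", "mid", "late"):
        domains = [(c, s, e) for c, s, e, t in timing_domains if t == phase]
        mean = {
            c: np.full(layout.n_bins(cfg.track_bin, c), cfg.background_level)
            for c in layout.names
        }
        for chrom, s, e in domains:
            b0 = s // cfg.track_bin
            b1 = (e - 1) // cfg.track_bin
            mean[chrom][b0 : b1 + 1] += cfg.repliseq_amplitude
        repliseq[phase] = BinnedTrack(
            cfg.track_bin,
            {c: nb_sample(rng, m, cfg.noise_dispersion) for c, m in mean.items()},
            layout,
        )

    # planted timing label per origin = the domain holding its midpoint
    def timing_of(chrom, start, end):
        mid = (start + end) // 2
        for c, s, e, t in timing_domains:
            if c == chrom and s <= mid < e:
                return t
        return "unassigned"

    origins_truth = origins[["chrom", "start", "end", "origin_class"]].copy()
    origins_truth["timing"] = [
        timing_of(r.chrom, r.start, r.end) for r in origins_truth.itertuples(index=False)
    ]

    # -- PC1 replicate tables -------------------------------------------------
    rng = cfg.rng("pc1")
    pc1 = bin_df[["chrom", "start", "end", "gene_density"]].copy()
    base = bin_df["pc1_base"].to_numpy()
    kd_base = base.copy()
    kd_base[weak_idx] = base[weak_idx] * cfg.weakening_factor
    for rep in range(1, cfg.n_replicates + 1):
        pc1[f"pc1_ctrl_{rep}"] = base + rng.normal(0, cfg.pc1_noise_sd, len(base))
    for rep in range(1, cfg.n_replicates + 1):
        pc1[f"pc1_kd_{rep}"] = kd_base + rng.normal(0, cfg.pc1_noise_sd, len(base))

    # -- clone CNAs ------------------------------------------------------------
    rng = cfg.rng("cna")
    cna_placer = _SitePlacer(layout, gap=10_000)
    planted = _place_sites(rng, layout, cna_placer, cfg.n_planted_cnas, (150_000, 300_000), choose_uniform)
    fragile = _place_sites(rng, layout, cna_placer, cfg.n_fragile_sites, (100_000, 250_000), choose_uniform)
    over_names = [f"nfib_oe_{i}" for i in range(1, cfg.n_clones + 1)]
    ctrl_names = [f"control_{i}" for i in range(1, cfg.n_control_clones + 1)]
    seg_rows = []
    for chrom, s, e in planted:
        k = int(rng.integers(2, cfg.n_clones + 1)) if cfg.n_clones >= 2 else cfg.n_clones
        for clone in rng.choice(over_names, size=k, replace=False):
            seg_rows.append((chrom, s, e, clone, 3.6, True))
    for clone in over_names + ctrl_names:
        for chrom, s, e in fragile:
            if rng.random() < 0.5:
                seg_rows.append((chrom, s, e, clone, 3.2, False))
        losses = _place_sites(
            rng, layout, cna_placer, cfg.n_spontaneous_losses,
            (50_000, 150_000), choose_uniform,
        )
        seg_rows.extend((c, s, e, clone, 1.1, False) for c, s, e in losses)
    clone_segments = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "clone", "copy_number", "planted"]
    )

    # -- patient cohorts --------------------------------------------------------
    rng = cfg.rng("cohort")
    locus_rows = [(c, s, e, f"AMP{j + 1}", True) for j, (c, s, e) in enumerate(planted)]
    decoy_loci = _place_sites(
        rng, layout, cna_placer, cfg.n_decoy_loci, (150_000, 300_000), choose_uniform
    )
    locus_rows += [
        (c, s, e, f"DEC{j + 1}", False) for j, (c, s, e) in enumerate(decoy_loci)
    ]
    coamp_loci = pd.DataFrame(locus_rows, columns=["chrom", "start", "end", "locus", "coamplified"])
    cohorts = []
    for _ in range(cfg.n_cohorts):
        nfib_amp = rng.random(cfg.n_patients) < cfg.frac_nfib_amplified
        cohort = pd.DataFrame({"NFIB_amplified": nfib_amp})
        for row in coamp_loci.itertuples(index=False):
            p_amp = np.where(
                nfib_amp & row.coamplified, cfg.p_coamp_given_nfib, cfg.p_coamp_background
            )
            cohort[row.locus] = rng.random(cfg.n_patients) < p_amp
        cohorts.append(cohort)

    truth = PlantedTruth(
        nfib_sites=nfib_peaks,
        orc1_sites=orc1_peaks,
        orc1_dependent=orc1_dependent,
        origins=origins_truth,
        weakened_A_bins=weakened_bins,
        clone_cnas=clone_segments,
        coamp_loci=coamp_loci,
    )
    truth.validate()

    return StudyData(
        config=cfg,
        nfib_peaks=nfib_peaks,
        orc1_peaks=orc1_peaks,
        tracks=tracks,
        atac_counts=atac_counts,
        ns_table=ns_table,
        repliseq=repliseq,
        pc1_table=pc1,
        clone_segments=clone_segments,
        control_clones=ctrl_names,
        overexpressing_clones=over_names,
        cohorts=cohorts,
        truth=truth,
    )
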