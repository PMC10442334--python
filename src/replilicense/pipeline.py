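"""Config-driven orchestration of all analysis stages with one JSON report.

Stages run in dependency order: simulate -> colocalization -> differential
-> origins -> compartments -> aux.  Every number in the report is
re-derivable from the per-stage TSV/BED artifacts written next to it, and
the report is byte-identical across runs with the same config and seed
(no timestamps inside; timings go to the log only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aux_stats import (
    CNAConfig,
    cohort_validation_fraction,
    cooccurrence_with_nfib,
    gain_peaks,
    mean_r_value,
    recurrent_amplifications,
    subtract_control_gains,
)
from .colocalization import overlap_venn, permutation_overlap_null, truncate, venn_percentages
from .compartments import CATEGORIES, CompartmentConfig, classify_bins, n1_enrichment, orient_pc1
from .differential import DifferentialConfig, classify_accessibility, classify_fold_change, derive_n1, quantify_peaks
from .genome import GenomeLayout, PeakSet, intersect
from .origins import NSFilterConfig, TimingProfile, assign_timing, classify_s123, filter_true_ns, timing_distribution
from .simulate import SimulationConfig, simulate_em_traces, simulate_study

log = logging.getLogger("replilicense")

STAGE_ORDER = ["colocalization", "differential", "origins", "compartments", "aux"]
STAGE_DEPS = {
    "colocalization": [],
    "differential": [],
    "origins": ["differential"],
    "compartments": ["differential"],
    "aux": [],
}


@dataclass
class RunConfig:
    """Full pipeline configuration (YAML-loadable)."""

    seed: int = 0
    outdir: Optional[str] = None
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    ns_filter: NSFilterConfig = field(default_factory=NSFilterConfig)
    compartment: CompartmentConfig = field(default_factory=CompartmentConfig)
    cna: CNAConfig = field(default_factory=CNAConfig)
    null_draws: int = 10
    em_occupancy_control: float = 0.55
    em_occupancy_depleted: float = 0.75
    em_n_traces: int = 200
    em_trace_len_bp: int = 30_000
    cohort_fdr: float = 0.05
    write_inputs: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        cfg = cls()
        sim_over = raw.pop("simulate", {})
        known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
        for k, v in sim_over.items():
            if k not in known_sim:
                raise ValueError(f"invalid simulate config field {k!r}")
            if k == "layout":
                v = GenomeLayout(v)
            if k in ("site_width", "ns_fragment_range"):
                v = tuple(v)
            setattr(cfg.simulate, k, v)
        for section, klass in (
            ("differential", DifferentialConfig),
            ("ns_filter", NSFilterConfig),
            ("compartment", CompartmentConfig),
            ("cna", CNAConfig),
        ):
            if section in raw:
                setattr(cfg, section, klass(**raw.pop(section)))
        if "stages" in raw:
            stages = raw.pop("stages")
            unknown = set(stages) - set(STAGE_ORDER)
            if unknown:
                raise ValueError(f"unknown stages {sorted(unknown)}")
            cfg.stages.update(stages)
        known = {f.name for f in dataclasses.fields(cls)}
        for k, v in raw.items():
            if k not in known:
                raise ValueError(f"invalid config field {k!r}")
            setattr(cfg, k, v)
        cfg.simulate.seed = cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_canonical(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"]["layout"] = list(self.simulate.layout.chromosomes)
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_canonical(), sort_keys=True, default=str).encode()
        ).hexdigest()

    def check_dependencies(self) -> None:
        for stage, deps in STAGE_DEPS.items():
            if self.stages.get(stage, False):
                for dep in deps:
                    if not self.stages.get(dep, False):
                        raise ValueError(
                            f"stage {stage!r} requires stage {dep!r}, which is disabled"
                        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run(config: RunConfig, outdir=None) -> dict:
    """Execute all enabled stages; write artifacts + report.json to *outdir*."""
    t0 = time.time()
    config.check_dependencies()
    outdir = Path(outdir or config.outdir or "replilicense_run")
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_sha256": config.sha256(),
            "version": __version__,
        }
    }
    try:
        log.info("simulating study (seed=%d)", config.seed)
        study = simulate_study(config.simulate)
        layout = config.simulate.layout
        if config.write_inputs:
            study.write(outdir / "inputs")

        n1_peaks: Optional[PeakSet] = None

        if config.stages.get("colocalization"):
            t = time.time()
            venn = overlap_venn(study.nfib_peaks, study.orc1_peaks, layout)
            pct_a, pct_b = venn_percentages(venn)
            null = permutation_overlap_null(
                study.nfib_peaks, study.orc1_peaks, layout,
                n_draws=config.null_draws, seed=np.random.default_rng([config.seed, 101]),
            )
            report["colocalization"] = {
                **venn.to_dict(),
                "pct_nfib": pct_a,
                "pct_orc1": pct_b,
                "pct_nfib_truncated": truncate(pct_a),
                "pct_orc1_truncated": truncate(pct_b),
                "null_draw_pcts": list(null.draw_pcts),
                "null_median_pct": null.median_pct,
            }
            pd.DataFrame([report["colocalization"]]).drop(columns=["null_draw_pcts"]).to_csv(
                outdir / "colocalization.tsv", sep="\t", index=False
            )
            log.info("colocalization done in %.2fs", time.time() - t)

        if config.stages.get("differential"):
            t = time.time()
            nfib_tbl = classify_fold_change(
                quantify_peaks(study.nfib_peaks, study.tracks["nfib_ctrl"], study.tracks["nfib_kd"]),
                config.differential,
            )
            orc1_tbl = classify_fold_change(
                quantify_peaks(study.orc1_peaks, study.tracks["orc1_ctrl"], study.tracks["orc1_kd"]),
                config.differential,
            )
            components, _, orc1_norm = intersect(study.nfib_peaks, study.orc1_peaks, layout)
            n1_peaks, consistency = derive_n1(nfib_tbl, orc1_tbl, components, orc1_norm)
            rep_cols = [c for c in study.atac_counts.columns if c.startswith(("ctrl_", "kd_"))]
            atac = classify_accessibility(
                study.atac_counts,
                [c for c in rep_cols if c.startswith("ctrl_")],
                [c for c in rep_cols if c.startswith("kd_")],
                config.differential,
            )
            group_counts = atac["group"].value_counts().to_dict()
            report["differential"] = {
                "n_nfib_decreased": int((nfib_tbl["label"] == "decreased").sum()),
                "n_orc1_decreased": int((orc1_tbl["label"] == "decreased").sum()),
                "n1_count": len(n1_peaks),
                "n1_consistency_pct": consistency,
                "n1_consistency_pct_truncated": truncate(consistency) if consistency is not None else None,
                "atac_open": int(group_counts.get("open", 0)),
                "atac_close": int(group_counts.get("close", 0)),
                "atac_unchanged": int(group_counts.get("unchanged", 0)),
            }
            nfib_tbl.to_csv(outdir / "nfib_differential.tsv", sep="\t", index=False)
            orc1_tbl.to_csv(outdir / "orc1_differential.tsv", sep="\t", index=False)
            atac.to_csv(outdir / "atac_groups.tsv", sep="\t", index=False)
            n1_peaks.write_bed(outdir / "n1_peaks.bed")
            log.info("differential done in %.2fs", time.time() - t)

        if config.stages.get("origins"):
            t = time.time()
            ns = filter_true_ns(study.ns_table, config.ns_filter)
            kept = ns[ns["is_true_ns"]].reset_index(drop=True)
            kept = classify_s123(
                kept, config.differential.fc_cutoff, config.differential.pseudocount
            )
            profile = TimingProfile.from_tracks(
                study.repliseq["early"], study.repliseq["mid"], study.repliseq["late"]
            )
            kept_peaks = PeakSet(kept[["chrom", "start", "end"]])
            labels = assign_timing(kept_peaks, profile)
            kept["timing"] = labels
            s1_mask = (kept["s_class"] == "S1").to_numpy()
            s1_idx = np.flatnonzero(s1_mask)
            if len(s1_idx) and len(n1_peaks):
                comps, s1_norm, _ = intersect(kept_peaks.select(s1_idx), n1_peaks, layout)
                matched_rows = sorted({i for c in comps for i in c.a_indices})
                # map normalized-order back to kept-row order via coordinates
                key = s1_norm.df.iloc[matched_rows][["chrom", "start", "end"]]
                merged = kept.loc[s1_idx].reset_index().merge(key, on=["chrom", "start", "end"])
                s1n1_rows = merged["index"].to_numpy()
            else:
                s1n1_rows = np.array([], dtype=int)
            in_n1 = np.zeros(len(kept), dtype=bool)
            in_n1[s1n1_rows] = True
            kept["s1_n1"] = s1_mask & in_n1
            categories = {
                "S1.N1": np.flatnonzero(s1_mask & in_n1),
                "S1.non-N1": np.flatnonzero(s1_mask & ~in_n1),
                "S2": np.flatnonzero((kept["s_class"] == "S2").to_numpy()),
                "all": np.arange(len(kept)),
            }
            timing = timing_distribution(categories, labels)
            counts = kept["s_class"].value_counts().to_dict()
            report["origins"] = {
                "n_candidates": len(ns),
                "n_true_ns": len(kept),
                "s1": int(counts.get("S1", 0)),
                "s2": int(counts.get("S2", 0)),
                "s3": int(counts.get("S3", 0)),
                "s1_n1": int(kept["s1_n1"].sum()),
                "timing": {
                    cat: {
                        "n": int(row["n"]),
                        "early": row["early"],
                        "mid": row["mid"],
                        "late": row["late"],
                        "unassigned_fraction": row["unassigned_fraction"],
                    }
                    for cat, row in timing.iterrows()
                },
            }
            ns.to_csv(outdir / "ns_filtered.tsv", sep="\t", index=False)
            kept.to_csv(outdir / "origin_classes.tsv", sep="\t", index=False)
            timing.to_csv(outdir / "timing_distribution.tsv", sep="\t")
            log.info("origins done in %.2fs", time.time() - t)

        if config.stages.get("compartments"):
            t = time.time()
            pc1_cols = [c for c in study.pc1_table.columns if c.startswith("pc1_")]
            ctrl_cols = [c for c in pc1_cols if c.startswith("pc1_ctrl")]
            kd_cols = [c for c in pc1_cols if c.startswith("pc1_kd")]
            oriented = orient_pc1(study.pc1_table, pc1_cols)
            changes = classify_bins(oriented, ctrl_cols, kd_cols, config.compartment)
            enrich = n1_enrichment(changes, n1_peaks, config.compartment)
            hist = {c: int((changes["category"] == c).sum()) for c in CATEGORIES}
            tests = {
                row["category"]: {
                    "n_bins": int(row["n_bins"]),
                    "U": row["U"],
                    "p": row["p"],
                    "skipped": bool(row["skipped"]),
                }
                for _, row in enrich.tests.iterrows()
            }
            report["compartments"] = {"category_counts": hist, "n1_enrichment": tests}
            changes.to_csv(outdir / "compartment_changes.tsv", sep="\t", index=False)
            weak = changes[changes["category"] == "A-weakened"]
            PeakSet(weak[["chrom", "start", "end"]]).write_bed(outdir / "weakened_A_bins.bed")
            enrich.tests.to_csv(outdir / "n1_enrichment_tests.tsv", sep="\t", index=False)
            log.info("compartments done in %.2fs", time.time() - t)

        if config.stages.get("aux"):
            t = time.time()
            traces_ctrl = simulate_em_traces(
                config.em_occupancy_control, config.em_n_traces,
                config.em_trace_len_bp, seed=config.seed * 1000 + 11,
            )
            traces_kd = simulate_em_traces(
                config.em_occupancy_depleted, config.em_n_traces,
                config.em_trace_len_bp, seed=config.seed * 1000 + 12,
            )
            segs = study.clone_segments
            control_gains = PeakSet(
                pd.concat(
                    [gain_peaks(segs[segs["clone"] == c], config.cna).df for c in study.control_clones],
                    ignore_index=True,
                )
            ).merge(0)
            residuals = []
            for clone in study.overexpressing_clones:
                gains = gain_peaks(segs[segs["clone"] == clone], config.cna)
                residuals.append(subtract_control_gains(gains, control_gains))
            recurrent = recurrent_amplifications(residuals, config.cna.min_clones)
            sig_loci = []
            cooc_tables = []
            for cohort in study.cohorts:
                cooc = cooccurrence_with_nfib(cohort)
                cooc_tables.append(cooc)
                keep = cooc.loc[cooc["q_bh"] < config.cohort_fdr, "locus"]
                loci = study.truth.coamp_loci.set_index("locus").loc[keep]
                sig_loci.append(PeakSet(loci.reset_index()[["chrom", "start", "end"]]))
            validation = cohort_validation_fraction(recurrent, sig_loci)
            report["aux"] = {
                "em_mean_r_control": mean_r_value(traces_ctrl),
                "em_mean_r_depleted": mean_r_value(traces_kd),
                "n_recurrent_amplifications": len(recurrent),
                "significant_loci_per_cohort": [len(p) for p in sig_loci],
                "cohort_validation_fraction": validation,
            }
            recurrent.write_bed(outdir / "recurrent_amplifications.bed")
            pd.concat(
                [t.assign(cohort=i + 1) for i, t in enumerate(cooc_tables)], ignore_index=True
            ).to_csv(outdir / "cohort_cooccurrence.tsv", sep="\t", index=False)
            log.info("aux done in %.2fs", time.time() - t)

        report = _jsonable(report)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        log.info("pipeline complete in %.2fs", time.time() - t0)
        return report
    finally:
        log.removeHandler(fh)
        fh.close()
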