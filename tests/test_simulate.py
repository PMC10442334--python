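"""Synthetic study generator: determinism, truth invariants, round-trips."""

import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from replilicense.genome import BinnedTrack, GenomeLayout, PeakSet
from replilicense.simulate import (
    SimulationConfig,
    nb_sample,
    simulate_em_traces,
    simulate_ns_counts,
    simulate_study,
)
from replilicense.aux_stats import r_value, mean_r_value


def small_config(**overrides):
    """Scaled-down study used where full defaults are unnecessary."""
    base = dict(
        layout=GenomeLayout([("chr1", 4_000_000), ("chr2", 4_000_000)]),
        n_nfib_sites=60,
        n_orc1_independent=25,
        n_atac_close_sites=15,
        n_atac_unchanged_sites=60,
        n_s2_origins=25,
        n_s3_origins=20,
        n_dormant_origins=10,
        n_ns_decoys=20,
        n_weakened_A_bins=4,
        n_planted_cnas=5,
        n_fragile_sites=4,
        n_decoy_loci=6,
        n_spontaneous_losses=2,
        n_cohorts=2,
        n_patients=80,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfig:
    def test_invalid_fields_named_in_error(self):
        with pytest.raises(ValueError, match="frac_orc1_dependent"):
            simulate_study(small_config(frac_orc1_dependent=1.5))
        with pytest.raises(ValueError, match="knockdown_fc"):
            simulate_study(small_config(knockdown_fc=0.9))
        with pytest.raises(ValueError, match="noise_dispersion"):
            simulate_study(small_config(noise_dispersion=-0.1))


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for d in ("run_a", "run_b"):
            simulate_study(small_config(seed=5)).write(tmp_path / d)
        files_a = sorted(p.name for p in (tmp_path / "run_a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "run_b").iterdir())
        assert files_a == files_b
        for name in files_a:
            assert filecmp.cmp(
                tmp_path / "run_a" / name, tmp_path / "run_b" / name, shallow=False
            ), name

    def test_different_seed_differs(self):
        s1 = simulate_study(small_config(seed=1))
        s2 = simulate_study(small_config(seed=2))
        assert not s1.nfib_peaks.df.equals(s2.nfib_peaks.df)


class TestTruthLedger:
    def test_dependent_orc1_overlaps_nfib(self):
        study = simulate_study(small_config(seed=3))
        study.truth.validate()  # asserts the dependence invariant

    def test_dependent_count_matches_binomial_expectation(self):
        """Each NFIB site hosts a dependent ORC1 site w.p. frac; over 20
        seeds the mean count sits within 3 SE of n * frac."""
        n, frac = 200, 0.5
        counts = []
        for seed in range(20):
            cfg = small_config(
                seed=seed, n_nfib_sites=n, frac_orc1_dependent=frac,
                layout=GenomeLayout([("chr1", 6_000_000), ("chr2", 6_000_000)]),
            )
            counts.append(int(simulate_study(cfg).truth.orc1_dependent.sum()))
        se = np.sqrt(n * frac * (1 - frac)) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - n * frac) <= 3 * se

    def test_weakened_bins_hold_more_dependent_sites(self):
        study = simulate_study(small_config(seed=11))
        truth = study.truth
        dep = truth.orc1_sites.df.loc[np.asarray(truth.orc1_dependent)]
        weak = {(r.chrom, r.start) for r in truth.weakened_A_bins.itertuples(index=False)}
        cw = study.config.compartment_bin
        in_weak = sum(
            1
            for r in dep.itertuples(index=False)
            if (r.chrom, ((r.start + r.end) // 2) // cw * cw) in weak
        )
        n_bins = len(study.pc1_table)
        expected_uniform = len(dep) * len(weak) / n_bins
        assert in_weak > expected_uniform


class TestRoundTrips:
    def test_emitted_files_load_through_core_readers(self, tmp_path):
        study = simulate_study(small_config(seed=7))
        study.write(tmp_path)
        layout = GenomeLayout.read_chrom_sizes(tmp_path / "genome.chrom.sizes")
        assert layout == study.config.layout
        peaks = PeakSet.read_bed(tmp_path / "nfib_peaks.bed")
        assert len(peaks) == len(study.nfib_peaks)
        track = BinnedTrack.read_bedgraph(tmp_path / "nfib_ctrl.bedgraph", layout)
        np.testing.assert_allclose(
            track.values["chr1"], study.tracks["nfib_ctrl"].values["chr1"], rtol=1e-5
        )
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert len(truth["nfib_sites"]) == len(study.nfib_peaks)
        pc1 = pd.read_csv(tmp_path / "pc1_table.tsv", sep="\t")
        assert len(pc1) == len(study.pc1_table)


class TestNSCounts:
    def _origins(self, activity):
        n = len(activity)
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": np.arange(n) * 5_000,
                "end": np.arange(n) * 5_000 + 1_000,
                "activity": activity,
            }
        )

    def test_zero_background_means_zero_treated_counts(self):
        cfg = small_config(rnase_background_rate=0.0)
        out = simulate_ns_counts(self._origins([1.0] * 50), cfg, np.random.default_rng(1))
        assert (out["count_treated"] == 0).all()

    def test_inactive_origin_counts_match_background(self):
        cfg = small_config(noise_dispersion=0.0)
        out = simulate_ns_counts(self._origins([0.0] * 10), cfg, np.random.default_rng(2))
        assert (out["count_untreated"] == out["count_treated"]).all()

    def test_strong_origins_pass_filter_with_high_power(self):
        """At a 4-fold untreated/treated ratio and dispersion 0.1, nearly all
        of 200 true origins should survive the RNase filter (fixed seeds)."""
        from replilicense.origins import NSFilterConfig, filter_true_ns

        rates = []
        for seed in range(5):
            cfg = small_config(rnase_background_rate=0.25)
            out = simulate_ns_counts(
                self._origins([1.0] * 200), cfg, np.random.default_rng(50 + seed)
            )
            kept = filter_true_ns(out, NSFilterConfig())["is_true_ns"]
            rates.append(kept.mean())
        assert np.mean(rates) >= 0.95


class TestEMTraces:
    def test_zero_occupancy_no_bubbles(self):
        traces = simulate_em_traces(0.0, 50, 30_000, seed=1)
        assert all(r_value(t) == 0.0 for t in traces)

    def test_full_occupancy_r_is_one(self):
        traces = simulate_em_traces(1.0, 50, 30_000, seed=2)
        assert all(r_value(t) == 1.0 for t in traces)

    def test_mean_r_tracks_occupancy(self):
        occ = 0.4
        traces = simulate_em_traces(occ, 500, 30_000, seed=3)
        n_units = 30_000 // 147
        se = np.sqrt(occ * (1 - occ) / n_units) / np.sqrt(500)
        assert abs(mean_r_value(traces) - occ) <= 3 * se


class TestNoiseModel:
    def test_zero_dispersion_returns_exact_means(self):
        rng = np.random.default_rng(0)
        means = np.array([0.0, 3.5, 100.0])
        np.testing.assert_array_equal(nb_sample(rng, means, 0.0), means)

    def test_dispersion_controls_variance(self):
        rng = np.random.default_rng(1)
        m, d = 50.0, 0.2
        draws = nb_sample(rng, np.full(20_000, m), d)
        assert abs(draws.mean() - m) < 1.0
        expected_var = m + d * m * m
        assert abs(draws.var() / expected_var - 1) < 0.1

    def test_zero_noise_limit_recovers_planted_labels(self):
        """Dispersion 0 + PC1 noise 0: every stage's classification equals
        the planted truth exactly."""
        from replilicense.differential import (
            DifferentialConfig, classify_fold_change, derive_n1, quantify_peaks,
        )
        from replilicense.genome import intersect
        from replilicense.origins import NSFilterConfig, classify_s123, filter_true_ns

        cfg = small_config(seed=13, noise_dispersion=0.0, pc1_noise_sd=0.0)
        study = simulate_study(cfg)
        layout = cfg.layout
        dcfg = DifferentialConfig()
        nfib_tbl = classify_fold_change(
            quantify_peaks(study.nfib_peaks, study.tracks["nfib_ctrl"], study.tracks["nfib_kd"]), dcfg
        )
        orc1_tbl = classify_fold_change(
            quantify_peaks(study.orc1_peaks, study.tracks["orc1_ctrl"], study.tracks["orc1_kd"]), dcfg
        )
        comps, _, orc1_n = intersect(study.nfib_peaks, study.orc1_peaks, layout)
        n1, consistency = derive_n1(nfib_tbl, orc1_tbl, comps, orc1_n)
        dep = study.truth.orc1_sites.df.loc[np.asarray(study.truth.orc1_dependent)]
        got = set(map(tuple, n1.df[["chrom", "start", "end"]].itertuples(index=False)))
        want = set(map(tuple, dep[["chrom", "start", "end"]].itertuples(index=False)))
        assert got == want
        assert consistency == 100.0

        ns = filter_true_ns(study.ns_table, NSFilterConfig())
        truth_cls = study.ns_table["origin_class"]
        assert (ns["is_true_ns"] == truth_cls.isin(["S1-dependent", "S2-compensatory", "S3-stable"])).all()
        kept = ns[ns["is_true_ns"]].reset_index(drop=True)
        s = classify_s123(kept)
        mapping = {"S1-dependent": "S1", "S2-compensatory": "S2", "S3-stable": "S3"}
        assert (s["s_class"] == s["origin_class"].map(mapping)).all()
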