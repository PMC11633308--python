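"""Synthetic-data generators: determinism, planted-parameter contracts."""

import numpy as np
import pytest

from zfpkit import simulate as sim
from zfpkit.io_formats import write_bed12


class TestAnnotation:
    def test_seed_repeat_is_byte_identical(self, tmp_path):
        for name in ("a", "b"):
            genes = sim.make_annotation(sim.SimConfig(seed=1, n_genes=100))
            write_bed12(genes.values(), tmp_path / f"{name}.bed12")
        assert (tmp_path / "a.bed12").read_bytes() == (tmp_path / "b.bed12").read_bytes()

    def test_utrs_and_cds_tile_exons(self):
        genes = sim.make_annotation(sim.SimConfig(seed=2, n_genes=30))
        for g in genes.values():
            parts = sorted(g.utr5 + g.cds + g.utr3)
            assert sum(e - s for s, e in parts) == sum(e - s for s, e in g.exons)
            # disjoint
            assert all(a[1] <= b[0] for a, b in zip(parts, parts[1:]))

    def test_genes_non_overlapping_per_chrom(self):
        genes = sim.make_annotation(sim.SimConfig(seed=3, n_genes=80))
        by_chrom: dict = {}
        for g in genes.values():
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_infeasible_exon_request_is_error(self):
        with pytest.raises(ValueError, match="too small"):
            sim.make_annotation(sim.SimConfig(seed=1, n_genes=1,
                                              gene_length_range=(200, 200)))


class TestBinding:
    def test_null_or_matches_feature_fraction(self):
        cfg = sim.SimConfig(seed=4, n_genes=100)
        genes = sim.make_annotation(cfg)
        ip, bg, _, truth = sim.simulate_binding(cfg, genes, planted_or=1.0,
                                                n_windows=10_000)
        # with OR=1 the IP in-feature fraction equals the genomic fraction
        def frac_in(ws):
            n = 0
            for w in ws:
                g = genes[w.gene_id]
                n += any(s <= w.midpoint < e for s, e in g.utr3)
            return n / len(ws)
        f = truth.base_feature_fraction
        se3 = 3 * np.sqrt(f * (1 - f) / 10_000)
        assert abs(frac_in(ip) - f) < se3 + 0.01

    def test_unknown_feature_is_error(self):
        cfg = sim.SimConfig(seed=4, n_genes=10)
        genes = sim.make_annotation(cfg)
        with pytest.raises(ValueError, match="plant"):
            sim.simulate_binding(cfg, genes, planted_feature="SS5_ADJ")

    def test_or_below_one_is_error(self):
        cfg = sim.SimConfig(seed=4, n_genes=10)
        genes = sim.make_annotation(cfg)
        with pytest.raises(ValueError, match="planted_or"):
            sim.simulate_binding(cfg, genes, planted_or=0.5)

    def test_peaks_concentrate_near_tss(self):
        cfg = sim.SimConfig(seed=5, n_genes=100)
        genes = sim.make_annotation(cfg)
        _, _, peaks, _ = sim.simulate_binding(cfg, genes, n_peaks=1_000,
                                              tss_fraction=0.8)
        near = sum(abs(p.dist_to_tss) <= 1_000 for p in peaks)
        assert near / len(peaks) > 0.7


class TestKdTables:
    def test_null_batch_means_within_3se(self):
        cfg = sim.SimConfig(seed=6)
        m, _, _ = sim.simulate_kd_tables(cfg, {"A": 100.0, "B": 1000.0},
                                         datasets_per_batch=30, tables=False)
        for batch, mean in (("A", 100.0), ("B", 1000.0)):
            got = m.loc[m.batch == batch, "DEG"].mean()
            se3 = 3 * np.sqrt(mean / 30)
            assert abs(got - mean) < se3

    def test_outlier_excess_recorded_in_truth(self):
        cfg = sim.SimConfig(seed=6)
        _, _, truth = sim.simulate_kd_tables(cfg, {"A": 1000.0, "B": 100.0},
                                             outlier_zfps={"X": ("A", 0.5)},
                                             tables=False)
        assert truth.outlier_excess["X"] == 0.5
        assert truth.batch_of["X"] == "A"

    def test_unknown_batch_is_error(self):
        cfg = sim.SimConfig(seed=6)
        with pytest.raises(ValueError, match="unknown batch"):
            sim.simulate_kd_tables(cfg, {"A": 100.0}, outlier_zfps={"X": ("Z", 0.5)})

    def test_seed_repeat_identical(self):
        cfg = sim.SimConfig(seed=7)
        m1, _, _ = sim.simulate_kd_tables(cfg, {"A": 100.0, "B": 500.0}, tables=False)
        m2, _, _ = sim.simulate_kd_tables(cfg, {"A": 100.0, "B": 500.0}, tables=False)
        assert m1.equals(m2)

    def test_tables_reproduce_planted_counts(self):
        from zfpkit import kd_events
        cfg = sim.SimConfig(seed=8, n_genes=4_000)
        m, tables, truth = sim.simulate_kd_tables(cfg, {"A": 100.0, "B": 300.0},
                                                  datasets_per_batch=2)
        for zfp, t in tables.items():
            ev = kd_events.call_significant_events(t["expr"], t["splice"], t["apa"])
            assert ev.counts["DEG"] == truth.planted_counts[zfp]["DEG"]
            assert ev.counts["ASE"] == truth.planted_counts[zfp]["ASE"]
            assert ev.counts["APAE"] == truth.planted_counts[zfp]["APAE"]


class TestSlam:
    def test_noiseless_mode_is_exact(self):
        cfg = sim.SimConfig(seed=9)
        df, _ = sim.simulate_slam(cfg, {"g": 4.0}, depth=1_000.0, noise=False)
        t0 = df[(df.timepoint_h == 0) & (df.replicate == 1)].tc_conversions.iloc[0]
        t4 = df[(df.timepoint_h == 4) & (df.replicate == 1)].tc_conversions.iloc[0]
        assert t4 / t0 == 0.5

    def test_low_depth_gene_flagged_as_filter_fail(self):
        cfg = sim.SimConfig(seed=9)
        # depth 1 per 2e6 library = 0.5 CPM <= 5
        _, truth = sim.simulate_slam(cfg, {"g": 4.0}, depth=1.0)
        assert "g" in truth.filter_fail_genes

    def test_invalid_parameters_error(self):
        cfg = sim.SimConfig(seed=9)
        with pytest.raises(ValueError, match="half-lives"):
            sim.simulate_slam(cfg, {"g": -1.0})
        with pytest.raises(ValueError, match="depth"):
            sim.simulate_slam(cfg, {"g": 2.0}, depth=0.0)


class TestRbns:
    def test_seed_repeat_identical(self):
        cfg = sim.SimConfig(seed=10)
        pwm = sim.consensus_pwm("GAAGA")
        a = sim.simulate_rbns(cfg, pwm, 0.3, 500)[0]
        b = sim.simulate_rbns(cfg, pwm, 0.3, 500)[0]
        assert a == b

    def test_motif_longer_than_read_is_error(self):
        cfg = sim.SimConfig(seed=10)
        with pytest.raises(ValueError, match="longer"):
            sim.simulate_rbns(cfg, sim.consensus_pwm("A" * 25), 0.3, 10)

    def test_reads_are_rna(self):
        cfg = sim.SimConfig(seed=10)
        reads, _, _ = sim.simulate_rbns(cfg, sim.consensus_pwm("GAAGA"), 0.3, 100)
        assert all(set(r) <= set("ACGU") and len(r) == 20 for r in reads)


class TestEprAndTethering:
    def test_epr_reps_below_two_is_error(self):
        with pytest.raises(ValueError, match="2 replicates"):
            sim.simulate_epr(sim.SimConfig(seed=11), reps=1)

    def test_nonpositive_ratio_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            sim.simulate_epr(sim.SimConfig(seed=11), effect_genes={"G0000": 0.0})

    def test_tethering_always_emits_control(self):
        df, _ = sim.simulate_tethering(sim.SimConfig(seed=12), {"X": 2.0})
        assert set(df.construct_id) == {"control", "X"}

    def test_independent_streams_are_stable(self):
        """Generating binding data does not perturb the tethering draw."""
        cfg = sim.SimConfig(seed=13, n_genes=20)
        t1, _ = sim.simulate_tethering(cfg, {"X": 2.0})
        genes = sim.make_annotation(cfg)
        sim.simulate_binding(cfg, genes, n_windows=100)
        t2, _ = sim.simulate_tethering(cfg, {"X": 2.0})
        assert t1.equals(t2)
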