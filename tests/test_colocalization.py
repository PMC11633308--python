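"""Dual-binder classification, signed DNA→RNA distances, metagene bins."""

import numpy as np
import pytest

from zfpkit import colocalization as coloc, simulate as sim
from zfpkit.io_formats import DnaPeak, GeneModel

from conftest import make_window


def plus_gene(gene_id="g", start=1000, end=3000):
    return GeneModel(gene_id, "chr1", "+", start, end, exons=[(start, end)])


def minus_gene(gene_id="g", start=1000, end=3000):
    return GeneModel(gene_id, "chr1", "-", start, end, exons=[(start, end)])


def peak(start, end, gene_id=None, chrom="chr1"):
    return DnaPeak(chrom, start, end, gene_id=gene_id)


class TestBindingMode:
    def _genes(self, n):
        genes = {}
        for i in range(n):
            s = 10_000 * i
            genes[f"g{i}"] = plus_gene(f"g{i}", s, s + 2_000)
        return genes

    def _peaks_on(self, genes, ids):
        return [peak(genes[g].start + 100, genes[g].start + 400, gene_id=g) for g in ids]

    def test_drbp_needs_strictly_more_than_500_each(self):
        genes = self._genes(502)
        ids501 = [f"g{i}" for i in range(501)]
        rna = [make_window(genes[g].start + 10, genes[g].start + 60, g) for g in ids501]
        call = coloc.classify_binding_mode(self._peaks_on(genes, ids501), rna, genes)
        assert call.mode == "DRBP" and call.n_dna_genes == 501

        ids500 = ids501[:-1]
        call2 = coloc.classify_binding_mode(self._peaks_on(genes, ids501),
                                            [make_window(genes[g].start + 10,
                                                         genes[g].start + 60, g)
                                             for g in ids500], genes)
        assert call2.mode == "DNA_only"

    def test_distant_intergenic_peak_excluded(self):
        genes = {"g0": plus_gene("g0", 0, 2_000)}
        far = peak(160_000, 160_300)  # 158 kb from the gene
        near = peak(2_500, 2_800)
        call = coloc.classify_binding_mode([far, near], [], genes)
        assert call.n_dna_genes == 1  # only the near peak counts

    def test_empty_annotation_is_error(self):
        with pytest.raises(ValueError, match="annotation"):
            coloc.classify_binding_mode([], [], {})

    def test_counts_match_set_arithmetic(self):
        genes = self._genes(10)
        peaks = self._peaks_on(genes, ["g0", "g1", "g1", "g2"])
        rna = [make_window(10, 60, g) for g in ["g5", "g5", "g6"]]
        call = coloc.classify_binding_mode(peaks, rna, genes)
        assert (call.n_dna_genes, call.n_rna_genes) == (3, 2)
        assert call.mode == "neither"


class TestPeakDistances:
    def test_plus_strand_downstream_window_positive(self):
        genes = {"g": plus_gene()}
        p = peak(100, 120, gene_id="g")  # mid 110
        w = make_window(200, 220, "g")   # mid 210
        assert coloc.peak_distance_profile([p], [w], genes) == [100.0]

    def test_minus_strand_sign_flips(self):
        genes = {"g": minus_gene()}
        p = peak(200, 220, gene_id="g")  # mid 210
        w = make_window(100, 120, "g")   # mid 110, 3' on minus strand
        assert coloc.peak_distance_profile([p], [w], genes) == [100.0]

    def test_nearest_window_by_magnitude(self):
        genes = {"g": plus_gene()}
        p = peak(1000, 1020, gene_id="g")  # mid 1010
        near = make_window(1100, 1120, "g")   # +100
        far = make_window(590, 630, "g")      # -400
        assert coloc.peak_distance_profile([p], [near, far], genes) == [100.0]

    def test_peaks_without_windows_omitted(self):
        genes = {"g": plus_gene(), "h": plus_gene("h", 5000, 8000)}
        p1 = peak(100, 120, gene_id="g")
        p2 = peak(5100, 5120, gene_id="h")
        w = make_window(200, 220, "g")
        assert len(coloc.peak_distance_profile([p1, p2], [w], genes)) == 1

    def test_tie_broken_downstream(self):
        genes = {"g": plus_gene()}
        p = peak(1000, 1020, gene_id="g")  # mid 1010
        up = make_window(900, 920, "g")    # -100
        down = make_window(1100, 1120, "g")  # +100
        assert coloc.peak_distance_profile([p], [up, down], genes) == [100.0]


class TestMetagene:
    def test_plus_strand_position(self):
        genes = {"g": plus_gene()}
        prof = coloc.metagene_density([make_window(1490, 1510, "g")], genes)
        assert prof.density[25] == 1.0

    def test_minus_strand_position(self):
        genes = {"g": minus_gene()}
        prof = coloc.metagene_density([make_window(2490, 2510, "g")], genes)
        assert prof.density[25] == 1.0

    def test_density_sums_to_one(self, small_annotation, rng):
        genes = list(small_annotation.values())
        ws = []
        for _ in range(200):
            g = genes[rng.integers(len(genes))]
            s = int(rng.integers(g.start, g.end - 10))
            ws.append(make_window(s, s + 10, g.gene_id, g.strand, g.chrom))
        prof = coloc.metagene_density(ws, small_annotation)
        assert prof.density.sum() == pytest.approx(1.0)
        assert prof.n_windows == 200

    def test_all_windows_at_tss_fill_bin_zero(self):
        genes = {"g": plus_gene()}
        ws = [make_window(995, 1005, "g") for _ in range(5)]
        prof = coloc.metagene_density(ws, genes)
        assert prof.density[0] == 1.0

    def test_translation_invariance(self):
        g1 = {"g": plus_gene("g", 1000, 3000)}
        g2 = {"g": plus_gene("g", 501000, 503000)}
        p1 = coloc.metagene_density([make_window(1490, 1510, "g")], g1)
        p2 = coloc.metagene_density([make_window(501490, 501510, "g")], g2)
        assert np.array_equal(p1.density, p2.density)

    def test_strand_flip_mirror_symmetry(self):
        gp = {"g": plus_gene()}
        gm = {"g": minus_gene()}
        wp = make_window(1200, 1220, "g")           # 10.5% from '+' TSS
        wm = make_window(2780, 2800, "g", strand="-")  # mirrored on '-'
        pp = coloc.metagene_density([wp], gp)
        pm = coloc.metagene_density([wm], gm)
        assert np.array_equal(pp.density, pm.density)


class TestProximalEnrichment:
    def _profiles(self, seed, bias, n=10):
        cfg = sim.SimConfig(seed=seed, n_genes=60)
        genes = sim.make_annotation(cfg)
        ip, _, _, _ = sim.simulate_binding(cfg, genes, planted_tss_bias=bias,
                                           n_windows=n * 150)
        return [coloc.metagene_density(ip[i * 150:(i + 1) * 150], genes)
                for i in range(n)]

    def test_planted_tss_bias_detected(self):
        biased = self._profiles(31, bias=3.0)
        uniform = self._profiles(32, bias=1.0)
        res = coloc.tss_tts_enrichment_test(biased, uniform)
        assert res["TSS"].p_value < 0.01
        assert res["TSS"].median_a > res["TSS"].median_b

    def test_single_profile_group_is_error(self):
        profs = self._profiles(33, bias=1.0, n=3)
        with pytest.raises(ValueError, match="2 profiles"):
            coloc.tss_tts_enrichment_test(profs[:1], profs[1:])
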