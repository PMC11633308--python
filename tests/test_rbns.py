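"""RBNS k-mer counting, enrichment, priority alignment, weighted PWM."""

import itertools

import numpy as np
import pytest

from zfpkit import rbns, simulate as sim


class TestCountKmers:
    def test_sliding_window(self):
        assert rbns.count_kmers(["GAAGAA"], k=5) == {"GAAGA": 1, "AAGAA": 1}

    def test_20nt_read_gives_16_pentamers(self):
        counts = rbns.count_kmers(["ACGUACGUACGUACGUACGU"], k=5)
        assert sum(counts.values()) == 16

    def test_t_read_as_u_and_bad_reads_skipped(self):
        counts = rbns.count_kmers(["GAAGAT", "GANGA"], k=5)
        assert counts == {"GAAGA": 1, "AAGAU": 1}
        assert rbns.count_kmers.n_skipped == 1

    def test_empty_pool(self):
        assert rbns.count_kmers([], k=5) == {}

    def test_total_equals_window_count(self, rng):
        reads = ["".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 30))))
                 for _ in range(200)]
        counts = rbns.count_kmers(reads, k=5)
        assert sum(counts.values()) == sum(len(r) - 4 for r in reads)

    def test_nonpositive_k_is_error(self):
        with pytest.raises(ValueError):
            rbns.count_kmers(["ACGU"], k=0)


class TestEnrichment:
    def test_identical_pools_give_r_one(self):
        counts = rbns.count_kmers(["ACGUACGUA", "GGGCCCAAA"], k=5)
        table = rbns.kmer_enrichment(counts, dict(counts))
        assert np.allclose(table["R"], 1.0)

    def test_absent_kmer_has_finite_r(self):
        table = rbns.kmer_enrichment({"AAAAA": 10}, {"CCCCC": 10})
        assert np.isfinite(table["R"]).all()
        assert table["kmer"].iloc[0] == "AAAAA"

    def test_sorted_by_r_then_lexicographic(self):
        table = rbns.kmer_enrichment({"AAAAA": 5, "CCCCC": 5, "GGGGG": 1},
                                     {"AAAAA": 1, "CCCCC": 1, "GGGGG": 1})
        assert list(table["kmer"][:2]) == ["AAAAA", "CCCCC"]

    def test_mismatched_k_is_error(self):
        with pytest.raises(ValueError, match="k-mer length"):
            rbns.kmer_enrichment({"AAAA": 1}, {"CCCCC": 1})


def brute_force_align(anchor: str, candidate: str):
    """Enumerate all (offset, mismatch) alignments and apply the priority
    list independently of the implementation."""
    budget = {(0, 0): "exact", (0, 1): "1mm", (1, 0): "1off",
              (1, 1): "1off1mm", (0, 2): "2mm"}
    feasible = []
    for off in (-1, 0, 1):
        if off == 0:
            pairs = list(zip(candidate, anchor))
        elif off == 1:
            pairs = list(zip(candidate[:-1], anchor[1:]))
        else:
            pairs = list(zip(candidate[1:], anchor[:-1]))
        mm = sum(a != b for a, b in pairs)
        key = (abs(off), mm)
        if key in budget:
            feasible.append((rbns.CATEGORY_PRIORITY.index(budget[key]),
                             abs(off), 0 if off < 0 else 1, off, mm, budget[key]))
    if not feasible:
        return None
    feasible.sort()
    _, _, _, off, mm, cat = feasible[0]
    return off, mm, cat


class TestAlignment:
    @pytest.mark.parametrize("anchor,candidate,expect", [
        ("GAAGA", "GAAGA", (0, 0, "exact")),
        ("GAAGA", "GAUGA", (0, 1, "1mm")),
        ("GAAGA", "AAGAA", (1, 0, "1off")),
        ("GAAGA", "AGAAG", (-1, 0, "1off")),
        ("GAAGA", "GACCA", (0, 2, "2mm")),
        ("GAAGA", "CUCUC", None),
    ])
    def test_known_pairs(self, anchor, candidate, expect):
        aln = rbns.align_pair(anchor, candidate)
        if expect is None:
            assert aln is None
        else:
            assert (aln.offset, aln.n_mismatch, aln.category) == expect

    def test_matches_brute_force_on_random_pairs(self, rng):
        bases = list("ACGU")
        for _ in range(1000):
            anchor = "".join(rng.choice(bases, size=5))
            cand = "".join(rng.choice(bases, size=5))
            aln = rbns.align_pair(anchor, cand)
            expect = brute_force_align(anchor, cand)
            if expect is None:
                assert aln is None
            else:
                assert (aln.offset, aln.n_mismatch, aln.category) == expect

    def test_unalignable_kmers_seed_new_group(self):
        table = rbns.kmer_enrichment(
            {"GAAGA": 50, "GAUGA": 30, "CUCUC": 20, "CUCUA": 10},
            {"GAAGA": 1, "GAUGA": 1, "CUCUC": 1, "CUCUA": 1, "AAAAA": 100})
        groups = rbns.align_top_kmers(table, top_n=4)
        assert groups[0].anchor == "GAAGA"
        assert groups[1].anchor == "CUCUC"
        assert {m.kmer for m in groups[1].members} == {"CUCUC", "CUCUA"}

    def test_top_n_below_two_is_error(self):
        table = rbns.kmer_enrichment({"GAAGA": 5}, {"GAAGA": 1})
        with pytest.raises(ValueError):
            rbns.align_top_kmers(table, top_n=1)


class TestWeightedPwm:
    def _table(self, rs: dict):
        import pandas as pd
        return pd.DataFrame({"kmer": list(rs), "R": list(rs.values())})

    def test_direct_accumulation(self):
        group = rbns.KmerGroup("GAAGA", [
            rbns.AlignedKmer("GAAGA", 0, 0, "exact"),
            rbns.AlignedKmer("GAUGA", 0, 1, "1mm"),
        ])
        pwm = rbns.build_weighted_pwm(group, self._table({"GAAGA": 5.0, "GAUGA": 3.0}))
        # position 3 (1-based) holds A from GAAGA (R=5) and U from GAUGA (R=3)
        a = pwm.matrix[2, rbns.RNA_ALPHABET.index("A")]
        u = pwm.matrix[2, rbns.RNA_ALPHABET.index("U")]
        assert (a, u) == pytest.approx((0.625, 0.375))
        assert np.allclose(pwm.support, 8.0)

    def test_singleton_group_is_one_hot(self):
        group = rbns.KmerGroup("ACGUA", [rbns.AlignedKmer("ACGUA", 0, 0, "exact")])
        pwm = rbns.build_weighted_pwm(group, self._table({"ACGUA": 4.0}))
        assert pwm.consensus == "ACGUA"
        assert np.allclose(pwm.counts.sum(axis=1), 4.0)
        assert pwm.counts.shape == (5, 4)  # no trimming of a uniform profile

    def test_offset_column_trimmed_iff_below_threshold(self):
        group = rbns.KmerGroup("GAAGA", [
            rbns.AlignedKmer("GAAGA", 0, 0, "exact"),
            rbns.AlignedKmer("AAGAU", 1, 0, "1off"),
        ])
        # rightmost column support = R of the offset k-mer alone
        weak = rbns.build_weighted_pwm(group, self._table({"GAAGA": 10.0, "AAGAU": 1.0}))
        assert weak.counts.shape[0] == 5  # 1.0 < 0.25 * 11 -> trimmed
        strong = rbns.build_weighted_pwm(group, self._table({"GAAGA": 10.0, "AAGAU": 9.0}))
        assert strong.counts.shape[0] == 6

    def test_column_weights_sum_to_support(self, rng):
        cfg = sim.SimConfig(seed=5)
        reads_pd, reads_in, _ = sim.simulate_rbns(cfg, sim.consensus_pwm("GAAGA"),
                                                  0.3, 5000)
        enr, groups, pwms = rbns.derive_motif(reads_pd, reads_in)
        for pwm in pwms:
            assert np.allclose(pwm.counts.sum(axis=1), pwm.support)
            assert np.allclose(pwm.matrix.sum(axis=1), 1.0)


class TestPlantedRecovery:
    def test_null_fraction_gives_unit_enrichment(self):
        cfg = sim.SimConfig(seed=9)
        reads_pd, reads_in, _ = sim.simulate_rbns(cfg, sim.consensus_pwm("GAAGA"),
                                                  planted_fraction=0.0, n_reads=20_000)
        enr = rbns.kmer_enrichment(rbns.count_kmers(reads_pd),
                                   rbns.count_kmers(reads_in))
        assert abs(np.log(enr["R"])).max() < 0.5  # sampling noise only

    def test_planted_consensus_is_top_pentamer(self):
        cfg = sim.SimConfig(seed=10)
        reads_pd, reads_in, _ = sim.simulate_rbns(cfg, sim.consensus_pwm("GAAGA"),
                                                  planted_fraction=0.3, n_reads=20_000)
        enr, groups, pwms = rbns.derive_motif(reads_pd, reads_in)
        assert enr["kmer"].iloc[0] == "GAAGA"
        assert "GAAGA" in pwms[0].consensus
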