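import dataclasses
from collections import Counter

import numpy as np
import pytest

import picolib as pl
from picolib import simulate as sim_mod
from picolib.community import BP_PER_FG
from picolib.presets import insert_size_for

from conftest import make_preset

REVCOMP = str.maketrans("ACGTN", "TGCAN")


class TestTagment:
    def test_mass_conservation_at_one_picogram(self, small_spec):
        frags = pl.tagment(small_spec, input_mass=1000.0, atm_dilution=10, seed=1)
        target = 1000.0 * BP_PER_FG
        assert frags.total_bases == pytest.approx(target, rel=0.01)

    def test_mean_insert_non_decreasing_in_dilution(self, small_spec):
        means = []
        for dil in (5, 10, 20, 50):
            frags = pl.tagment(small_spec, input_mass=40.0, atm_dilution=dil, seed=2)
            means.append(frags.length.mean())
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_one_to_fifty_dilution_hits_300bp(self, small_spec):
        # ~1e5 fragments at ~300 bp mean requires ~31 fg of input
        frags = pl.tagment(small_spec, input_mass=31.0, atm_dilution=50, seed=3)
        assert len(frags) >= 90_000
        assert frags.length.mean() == pytest.approx(300.0, abs=2.0)

    def test_one_to_five_dilution_under_200bp(self, small_spec):
        frags = pl.tagment(small_spec, input_mass=10.0, atm_dilution=5, seed=4)
        assert frags.length.mean() < 200

    def test_no_fragment_below_steric_bound(self, small_spec):
        frags = pl.tagment(small_spec, input_mass=5.0, atm_dilution=5, seed=5)
        assert frags.length.min() >= 20

    def test_member_base_share_follows_mass_abundance(self, small_spec):
        frags = pl.tagment(small_spec, input_mass=500.0, atm_dilution=10, seed=6)
        shares = pl.expected_abundances(small_spec)["mass_abundance"].to_numpy()
        for i in range(small_spec.n_members):
            got = frags.length[frags.member_idx == i].sum() / frags.total_bases
            assert got == pytest.approx(shares[i], rel=0.02)

    def test_invalid_dilution_rejected(self, small_spec):
        with pytest.raises(ValueError):
            pl.tagment(small_spec, input_mass=10.0, atm_dilution=0.5, seed=0)

    def test_undiluted_sub_nanogram_behaves_like_one_to_ten(self):
        assert insert_size_for(1.0, 1000.0) == insert_size_for(10.0, 1000.0)
        assert insert_size_for(1.0, 1.0e6) == (307.0, 115.0)


class TestBottleneckAndAmplify:
    def _frags(self, small_spec, n=2000):
        return pl.tagment(small_spec, input_mass=n * 240 / BP_PER_FG, atm_dilution=10, seed=8)

    def test_full_retention_zero_cycles_is_identity(self, small_spec):
        frags = self._frags(small_spec)
        pool = pl.bottleneck_and_amplify(frags, retention=1.0, cycles=0, efficiency=0.9, seed=0)
        assert len(pool) == len(frags)
        assert np.all(pool.copy_numbers == 1)

    def test_perfect_efficiency_doubles_every_cycle(self, small_spec):
        frags = self._frags(small_spec)
        pool = pl.bottleneck_and_amplify(frags, retention=1.0, cycles=6, efficiency=1.0, seed=0)
        assert np.all(pool.copy_numbers == 2 ** 6)

    def test_retention_thins_binomially(self, small_spec):
        frags = self._frags(small_spec, n=10_000)
        pool = pl.bottleneck_and_amplify(frags, retention=0.1, cycles=0, efficiency=0.9, seed=3)
        n, p = len(frags), 0.1
        assert abs(len(pool) - n * p) < 4 * np.sqrt(n * p * (1 - p))

    def test_copy_number_moments_match_branching_theory(self, small_spec):
        frags = self._frags(small_spec, n=20_000)
        c, eff = 8, 0.7
        pool = pl.bottleneck_and_amplify(frags, retention=1.0, cycles=c, efficiency=eff, seed=5)
        mu = 1 + eff
        mean_th = mu ** c
        var_th = eff * (1 - eff) * mu ** (c - 1) * (mu ** c - 1) / (mu - 1)
        x = pool.copy_numbers
        assert x.mean() == pytest.approx(mean_th, rel=0.02)
        assert x.var() == pytest.approx(var_th, rel=0.10)

    def test_accepts_plain_tuples(self):
        pool = pl.bottleneck_and_amplify(
            [("a", 0, 200), ("a", 50, 300), ("b", 10, 250)],
            retention=1.0, cycles=0, efficiency=0.5, seed=0,
        )
        assert len(pool) == 3


class TestCopyNumberClassSampler:
    def test_exact_pmf_matches_branching_theory_moments(self):
        values, probs = sim_mod._gw_copy_pmf(12, 0.9)
        mu = 1.9
        mean = float((values * probs).sum())
        var = float((values ** 2 * probs).sum() - mean ** 2)
        assert mean == pytest.approx(mu ** 12, rel=1e-6)
        var_th = 0.09 * mu ** 11 * (mu ** 12 - 1) / 0.9
        assert var == pytest.approx(var_th, rel=1e-6)

    def test_exact_pmf_matches_empirical_recursion(self):
        values, probs = sim_mod._gw_copy_pmf(6, 0.7)
        rng = np.random.default_rng(0)
        emp = sim_mod._gw_recursion(200_000, 6, 0.7, rng)
        counts = Counter(emp.tolist())
        for v, p in zip(values.tolist(), probs.tolist()):
            if p > 5e-3:
                obs = counts.get(v, 0) / len(emp)
                assert obs == pytest.approx(p, abs=4 * np.sqrt(p * (1 - p) / len(emp)))

    def test_class_sampler_reproduces_materialized_duplicate_fraction(
        self, small_spec, small_genomes, monkeypatch
    ):
        # Force the class-based path at a scale where the materialized path
        # is available as the oracle; collision statistics must agree.
        pre = make_preset(50_000, pcr_cycles=12)
        depth = 100_000

        def dup_frac(sim):
            c = Counter(sim.template_ids.tolist())
            return sum(v - 1 for v in c.values()) / depth

        sim_a = pl.simulate_preset_library(
            small_spec, pre, depth, seed=21, error_rate=0.0, genomes=small_genomes
        )
        monkeypatch.setattr(sim_mod, "_MATERIALIZE_LIMIT", 1)
        sim_b = pl.simulate_preset_library(
            small_spec, pre, depth, seed=22, error_rate=0.0, genomes=small_genomes
        )
        fa, fb = dup_frac(sim_a), dup_frac(sim_b)
        # binomial-scale tolerance on the collision fraction
        sd = np.sqrt(max(fa, 1e-6) * (1 - fa) / depth)
        assert fb == pytest.approx(fa, abs=6 * sd)


class TestEmitReads:
    def _single_template_pool(self, genome, start=100, length=200):
        frags = sim_mod.FragmentSet(
            ("g",), np.array([0], dtype=np.int32),
            np.array([start], dtype=np.int64), np.array([length], dtype=np.int64),
        )
        return sim_mod.FragmentPool(frags, np.array([1], dtype=np.int64))

    def test_single_template_yields_identical_pairs(self):
        genome = pl.simulate_genome(1000, 0.5, 1)
        pool = self._single_template_pool(genome)
        reads = list(pl.emit_reads(pool, {"g": genome}, depth=5, error_rate=0.0, seed=0))
        assert len(reads) == 5
        assert len({(r.fwd_seq, r.rev_seq) for r in reads}) == 1
        assert all(r.truth.fragment_end - r.truth.fragment_start == 200 for r in reads)

    def test_mates_overlap_on_short_fragments(self):
        # fragment 200, reads 150 -> mates share the central 100 bases
        genome = pl.simulate_genome(1000, 0.5, 2)
        pool = self._single_template_pool(genome, start=300, length=200)
        (read,) = pl.emit_reads(pool, {"g": genome}, depth=1, error_rate=0.0, seed=0)
        frag = genome[300:500]
        assert read.fwd_seq == frag[:150]
        assert read.rev_seq == frag[-150:].translate(REVCOMP)[::-1]
        rev_rc = read.rev_seq.translate(REVCOMP)[::-1]
        assert read.fwd_seq[50:] == rev_rc[:100]  # 100 bp overlap

    def test_fragment_shorter_than_read_uses_whole_fragment(self):
        genome = pl.simulate_genome(1000, 0.5, 3)
        pool = self._single_template_pool(genome, start=10, length=80)
        (read,) = pl.emit_reads(pool, {"g": genome}, depth=1, error_rate=0.0, seed=0)
        assert len(read.fwd_seq) == 80
        assert read.fwd_seq == genome[10:90]
        assert read.rev_seq == genome[10:90].translate(REVCOMP)[::-1]

    def test_circular_wrap_joins_genome_ends(self):
        genome = pl.simulate_genome(500, 0.5, 4)
        pool = self._single_template_pool(genome, start=450, length=100)
        (read,) = pl.emit_reads(pool, {"g": genome}, depth=1, error_rate=0.0, seed=0)
        assert read.fwd_seq[:50] == genome[450:]
        assert read.fwd_seq[50:100] == genome[:50]

    def test_errors_perturb_reads_at_requested_rate(self):
        genome = pl.simulate_genome(2000, 0.5, 5)
        pool = self._single_template_pool(genome, start=0, length=400)
        reads = list(pl.emit_reads(pool, {"g": genome}, depth=400, error_rate=0.01, seed=1))
        ref = genome[:150]
        mismatches = sum(
            sum(a != b for a, b in zip(r.fwd_seq, ref)) for r in reads
        )
        total = 400 * 150
        assert mismatches / total == pytest.approx(0.01, rel=0.3)

    def test_empty_pool_rejected(self):
        frags = sim_mod.FragmentSet(("g",), np.empty(0, np.int32), np.empty(0, np.int64), np.empty(0, np.int64))
        pool = sim_mod.FragmentPool(frags, np.empty(0, np.int64))
        with pytest.raises(ValueError):
            list(pl.emit_reads(pool, {"g": "ACGT"}, depth=1))


class TestDeterminism:
    def test_identical_seeds_give_byte_identical_outputs(self, small_spec, small_genomes, tmp_path):
        pre = make_preset(5000)
        files = {}
        for tag in ("a", "b"):
            sim = pl.simulate_preset_library(
                small_spec, pre, 2000, seed=77, error_rate=0.001, genomes=small_genomes
            )
            r1, r2, sam = (tmp_path / f"{tag}_R1.fq", tmp_path / f"{tag}_R2.fq", tmp_path / f"{tag}.sam")
            sim.write_fastq(r1, r2)
            sim.write_truth_sam(sam)
            files[tag] = (r1.read_bytes(), r2.read_bytes(), sam.read_bytes())
        assert files["a"] == files["b"]

    def test_different_seeds_differ(self, small_spec, small_genomes):
        pre = make_preset(5000)
        a = pl.simulate_preset_library(small_spec, pre, 500, seed=1, genomes=small_genomes)
        b = pl.simulate_preset_library(small_spec, pre, 500, seed=2, genomes=small_genomes)
        assert not np.array_equal(a.template_ids, b.template_ids)


class TestSignatureTruthEquivalence:
    def test_error_free_signature_duplicates_equal_template_collisions(
        self, small_spec, small_genomes
    ):
        pre = make_preset(3000)
        sim = pl.simulate_preset_library(
            small_spec, pre, 15_000, seed=13, error_rate=0.0, genomes=small_genomes
        )
        res = pl.count_duplicates(sim.read_pairs(), n_sample=15_000, seed=0)
        truth = sum(v - 1 for v in Counter(sim.template_ids.tolist()).values())
        assert res.duplicates == truth


class TestSpikeContaminants:
    def _reads(self, small_spec, small_genomes, n=2000):
        pre = make_preset(100_000)
        sim = pl.simulate_preset_library(
            small_spec, pre, n, seed=31, error_rate=0.0, genomes=small_genomes
        )
        return list(sim.read_pairs())

    def test_zero_fractions_leave_reads_unchanged(self, small_spec, small_genomes):
        reads = self._reads(small_spec, small_genomes)
        contam = [pl.Contaminant("human_like", 100_000, 0.41)]
        out = pl.spike_contaminants(reads, contam, [0.0], seed=0)
        assert out == reads

    def test_contaminant_counts_are_binomial_around_fraction(self, small_spec, small_genomes):
        n = 10_000
        reads = self._reads(small_spec, small_genomes, n=n)
        contam = [pl.Contaminant("human_like", 100_000, 0.41)]
        out = pl.spike_contaminants(reads, contam, [0.3], seed=5)
        got = sum(1 for r in out if r.truth.member_id == "human_like")
        assert abs(got - 0.3 * n) < 4 * np.sqrt(n * 0.3 * 0.7)

    def test_breakdown_partition_sums_to_one(self, small_spec, small_genomes):
        reads = self._reads(small_spec, small_genomes)
        contams = [
            pl.Contaminant("human_like", 100_000, 0.41),
            pl.Contaminant("methylobacterium_like", 100_000, 0.68),
        ]
        out = pl.spike_contaminants(reads, contams, [0.2, 0.1], seed=2)
        spec = pl.MockCommunitySpec(small_spec.members, tuple(contams))
        prof = pl.profile_from_truth([r.truth.member_id for r in out], spec)
        assert sum(prof.breakdown.values()) == pytest.approx(1.0, abs=1e-9)
        assert prof.breakdown["human"] > 0
        assert prof.breakdown["contaminant"] > 0

    def test_fractions_must_sum_below_one(self, small_spec, small_genomes):
        reads = self._reads(small_spec, small_genomes, n=10)
        contam = [pl.Contaminant("x", 1000, 0.5), pl.Contaminant("y", 1000, 0.5)]
        with pytest.raises(ValueError):
            pl.spike_contaminants(reads, contam, [0.6, 0.5], seed=0)


class TestPresets:
    def test_sop_insert_anchor(self):
        p = pl.preset("sop")
        assert (p.insert_mean, p.insert_sd) == (307.0, 115.0)
        assert p.pcr_cycles == 12
        assert p.atm_dilution == 1.0

    def test_100fg_effective_templates_from_occupancy_inversion(self):
        # independently recompute the inversion the preset packages
        expected = pl.invert_occupancy(0.788, 5_000_000)
        assert pl.preset("100fg").effective_templates == pytest.approx(expected, rel=1e-6)

    def test_low_input_insert_means_span_printed_range(self):
        means = [pl.preset(n).insert_mean for n in ("100pg", "10pg", "1pg", "100fg")]
        assert all(204 <= m <= 257 for m in means)

    def test_unknown_name_lists_valid_presets(self):
        with pytest.raises(ValueError, match="sop"):
            pl.preset("500zg")

    def test_duplicate_fraction_monotone_in_input_mass(self):
        # analytic duplicate fraction at the calibration depth decreases
        # (complexity increases) with input mass
        n = 5_000_000
        fracs = [
            1 - pl.expected_unique(pl.preset(name).effective_templates, n) / n
            for name in ("100fg", "1pg", "10pg", "100pg", "sop")
        ]
        assert all(b < a for a, b in zip(fracs, fracs[1:]))


class TestPcrCycleInvariance:
    def test_duplicate_fraction_insensitive_to_cycle_count(self, small_spec, small_genomes):
        # 12 vs 20 cycles at fixed depth and complexity: < 2 pp difference
        depth = 50_000
        fracs = {}
        for cycles in (12, 20):
            pre = make_preset(20_000, pcr_cycles=cycles)
            sim = pl.simulate_preset_library(
                small_spec, pre, depth, seed=55, error_rate=0.0, genomes=small_genomes
            )
            res = pl.count_duplicates(sim.read_pairs(), n_sample=depth, seed=0)
            fracs[cycles] = res.duplicate_fraction
        assert abs(fracs[12] - fracs[20]) < 0.02
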