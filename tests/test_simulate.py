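import numpy as np
import pytest

from achiasma import (
    DivergenceProfile,
    GenomeSpec,
    LengthDistribution,
    MAParams,
    MeiosisParams,
    intratetrad_mate,
    simulate_depths,
    simulate_ma_genealogy,
    simulate_parent_pair,
    simulate_tetrad,
)
from achiasma.simulate import TetradTruth, substitution_probabilities


class TestParentPair:
    def test_zero_rate_yields_zero_snps(self):
        g = GenomeSpec(chromosomes=(("c", 100_000),))
        pair = simulate_parent_pair(g, DivergenceProfile.uniform(g, 0.0), seed=1)
        assert pair.n_snps == 0

    def test_snp_count_matches_binomial_at_high_divergence(self):
        # 1 Mb at 3.3%: count should sit within 3 binomial SDs of 33,000
        g = GenomeSpec(chromosomes=(("c", 1_000_000),))
        sd = np.sqrt(1_000_000 * 0.033 * (1 - 0.033))
        for seed in range(5):
            pair = simulate_parent_pair(g, DivergenceProfile.uniform(g, 0.033), seed=seed)
            assert abs(pair.n_snps - 33_000) < 3 * sd

    def test_fixed_seed_reproduces_snp_set(self):
        g = GenomeSpec(chromosomes=(("c", 1_000_000),))
        prof = DivergenceProfile.uniform(g, 0.002)
        a = simulate_parent_pair(g, prof, seed=42)
        b = simulate_parent_pair(g, prof, seed=42)
        assert np.array_equal(a.positions["c"], b.positions["c"])
        assert np.array_equal(a.alleles["c"], b.alleles["c"])

    def test_masked_sites_excluded(self, small_genome):
        pair = simulate_parent_pair(
            small_genome, DivergenceProfile.uniform(small_genome, 0.01), seed=3)
        pos = pair.positions["chr1"]
        assert not np.any((pos >= 140_000) & (pos < 160_000))

    def test_alleles_always_differ(self, dense_pair):
        for chrom in ("chr1", "chr2"):
            alle = dense_pair.alleles[chrom]
            assert np.all(alle[:, 0] != alle[:, 1])


class TestTetrad:
    def test_achiasmate_markers_all_two_two(self, dense_pair):
        # 2:2 conservation over many meioses without any CO/NCO
        params = MeiosisParams(co_rate=0.0, nco_rate=0.0)
        for seed in range(1000):
            truth = simulate_tetrad(dense_pair, params, seed=seed)
            for chrom, mat in truth.spore_origins.items():
                counts = mat.sum(axis=0)
                assert np.all(counts == 2)
                # each spore's origin vector is constant along the chromosome
                assert np.all(mat.min(axis=1) == mat.max(axis=1))

    def test_single_co_switches_two_spores_reciprocally(self, dense_pair):
        # exhaustive scan of all origin-vector transitions around each breakpoint
        params = MeiosisParams(co_rate=0.6)
        n_checked = 0
        for seed in range(300):
            truth = simulate_tetrad(dense_pair, params, seed=seed)
            cos = [e for e in truth.true_events if e.kind == "CO"]
            if len(cos) != 1:
                continue
            ev = cos[0]
            x = ev.inner_start
            mat = truth.spore_origins[ev.chromosome]
            pos = dense_pair.positions[ev.chromosome]
            before, after = pos < x, pos > x
            if not before.any() or not after.any():
                continue
            n_checked += 1
            switched = []
            for s in range(4):
                vec = mat[s]
                assert np.all(vec[before] == vec[before][0])
                assert np.all(vec[after] == vec[after][0])
                if vec[before][0] != vec[after][0]:
                    switched.append(s)
            assert tuple(sorted(switched)) == ev.spores
            assert len(switched) == 2
            a, b = switched
            # reciprocal: opposite directions
            assert mat[a, after][0] != mat[b, after][0]
            # the other chromosome stays 2:2 constant
            other = [c for c in truth.spore_origins if c != ev.chromosome][0]
            assert np.all(truth.spore_origins[other].sum(axis=0) == 2)
        assert n_checked >= 50

    def test_nco_tract_markers_segregate_three_to_one(self, dense_pair):
        params = MeiosisParams(nco_rate=0.5, tract_length=LengthDistribution("constant", (3000,)))
        n_checked = 0
        for seed in range(200):
            truth = simulate_tetrad(dense_pair, params, seed=seed)
            ncos = [e for e in truth.true_events if e.kind == "NCO"]
            if len(ncos) != 1 or ncos[0].n_markers == 0:
                continue
            n_checked += 1
            ev = ncos[0]
            mat = truth.spore_origins[ev.chromosome]
            pos = dense_pair.positions[ev.chromosome]
            inside = (pos >= ev.inner_start) & (pos < ev.inner_end)
            counts = mat.sum(axis=0)
            assert np.all((counts[inside] == 1) | (counts[inside] == 3))
            assert np.all(counts[~inside] == 2)
            assert int(inside.sum()) == ev.n_markers
        assert n_checked >= 30

    def test_obligate_co_guarantees_one_per_chromosome(self, dense_pair):
        params = MeiosisParams(co_rate=0.3, obligate_co=True)
        truth = simulate_tetrad(dense_pair, params, seed=9)
        per_chrom = {c: 0 for c in truth.spore_origins}
        for ev in truth.true_events:
            if ev.kind == "CO":
                per_chrom[ev.chromosome] += 1
        assert all(n >= 1 for n in per_chrom.values())

    def test_fixed_seed_reproduces_tetrad(self, dense_pair):
        params = MeiosisParams(co_rate=1.0, nco_rate=1.0)
        a = simulate_tetrad(dense_pair, params, seed=5)
        b = simulate_tetrad(dense_pair, params, seed=5)
        for chrom in a.spore_origins:
            assert np.array_equal(a.spore_origins[chrom], b.spore_origins[chrom])


class TestIntratetradMating:
    def test_non_sister_restores_full_heterozygosity(self, dense_pair):
        params = MeiosisParams()
        for seed in range(50):
            truth = simulate_tetrad(dense_pair, params, seed=seed)
            dip = intratetrad_mate(truth, "non-sister", seed=seed)
            assert dip.het_fraction() == 1.0

    def test_sister_mating_fully_homozygous(self, dense_pair):
        truth = simulate_tetrad(dense_pair, MeiosisParams(), seed=1)
        dip = intratetrad_mate(truth, "sister", seed=1)
        assert dip.het_fraction() == 0.0

    def test_invalid_mode_rejected(self, dense_pair):
        truth = simulate_tetrad(dense_pair, MeiosisParams(), seed=1)
        with pytest.raises(ValueError):
            intratetrad_mate(truth, "random")

    def test_single_co_pairings_enumerated_on_toy_chromosome(self):
        # 3 markers; CO between markers 2 and 3 exchanged chromatids 0 (P1)
        # and 2 (P2); centromere at the left end.  Hand enumeration of the
        # four non-sister pairings: the two involving exactly one
        # recombinant chromatid are homozygous distal to the breakpoint,
        # the other two remain fully heterozygous.
        genome = GenomeSpec(chromosomes=(("c", 1000),), centromeres={"c": 0})
        pos = np.array([100, 500, 900])
        alle = np.array([["A", "T"]] * 3)
        pair_obj = type("P", (), {})()
        from achiasma.simulate import ParentalPair

        pair = ParentalPair(genome=genome, positions={"c": pos},
                            alleles={"c": alle.copy()})
        origins = np.array([
            [0, 0, 1],   # chromatid 0: P1 with P2 tail
            [0, 0, 0],   # chromatid 1: intact P1
            [1, 1, 0],   # chromatid 2: P2 with P1 tail
            [1, 1, 1],   # chromatid 3: intact P2
        ], dtype=np.int8)
        truth = TetradTruth(pair=pair, spore_origins={"c": origins})
        het_patterns = set()
        for a, b in TetradTruth.NON_SISTER_PAIRS:
            het = tuple(origins[a] != origins[b])
            het_patterns.add(het)
        assert het_patterns == {
            (True, True, True),     # both recombinants, or both intact
            (True, True, False),    # one recombinant: homozygous distal only
        }
        counts = [tuple(origins[a] != origins[b]) for a, b in TetradTruth.NON_SISTER_PAIRS]
        assert counts.count((True, True, False)) == 2
        assert counts.count((True, True, True)) == 2

    def test_het_fraction_non_increasing_in_co_rate(self, dense_pair):
        means = []
        for co_rate in (0.0, 1.0, 3.0):
            fracs = [
                intratetrad_mate(
                    simulate_tetrad(dense_pair, MeiosisParams(co_rate=co_rate), seed=s),
                    "non-sister", seed=s).het_fraction()
                for s in range(60)
            ]
            means.append(np.mean(fracs))
        assert means[0] >= means[1] >= means[2]
        assert means[0] == 1.0


class TestMAGenealogy:
    def test_zero_mu_gives_zero_mutations(self, small_genome):
        params = MAParams(mu=0.0, n_lines=5, generations=100)
        gen = simulate_ma_genealogy(small_genome, params, seed=1)
        assert gen.snms == []

    def test_total_count_within_three_sd_of_poisson_mean(self):
        # mu=1e-8, 10 lines, 2000 generations, 1 Mb haploid: mean 200
        g = GenomeSpec(chromosomes=(("c", 1_000_000),))
        params = MAParams(mu=1e-8, n_lines=10, generations=2000)
        total = len(simulate_ma_genealogy(g, params, seed=7).snms)
        assert abs(total - 200) < 3 * np.sqrt(200)

    def test_symmetric_bias_on_balanced_genome(self):
        # at_bias=1 on a 50% GC genome: expected GC->AT and AT->GC fluxes equal
        probs = substitution_probabilities(gc=0.5, at_bias=1.0, ts_tv=1.0)
        p_gc_at = sum(v for (r, a), v in probs.items() if r in "GC" and a in "AT")
        p_at_gc = sum(v for (r, a), v in probs.items() if r in "AT" and a in "GC")
        assert p_gc_at == pytest.approx(p_at_gc)

    def test_substitution_scheme_hits_requested_bias_and_tstv(self):
        gc, bias, tstv = 0.296, 3.6, 1.21
        probs = substitution_probabilities(gc, bias, tstv)
        assert sum(probs.values()) == pytest.approx(1.0)
        from achiasma.ma_rates import is_transition

        p_gc_at = sum(v for (r, a), v in probs.items() if r in "GC" and a in "AT")
        p_at_gc = sum(v for (r, a), v in probs.items() if r in "AT" and a in "GC")
        implied_bias = (p_gc_at / gc) / (p_at_gc / (1 - gc))
        assert implied_bias == pytest.approx(bias)
        p_ts = sum(v for (r, a), v in probs.items() if is_transition(r, a))
        assert p_ts / (1 - p_ts) == pytest.approx(tstv)

    def test_het_founder_requires_pair(self, small_genome):
        params = MAParams(mu=1e-9, n_lines=2, generations=10,
                          founder_zygosity="heterozygous-diploid")
        with pytest.raises(ValueError, match="het map"):
            simulate_ma_genealogy(small_genome, params, seed=1)

    def test_mutations_avoid_masked_regions(self, small_genome):
        params = MAParams(mu=5e-8, n_lines=5, generations=500)
        gen = simulate_ma_genealogy(small_genome, params, seed=2)
        # expected count: 5e-8 * 480 kb callable * 500 gen * 5 lines = 60
        assert len(gen.snms) > 30
        for m in gen.snms:
            if m.chromosome == "chr1":
                assert not (140_000 <= m.position < 160_000)


class TestDepths:
    def test_het_allele_balance_near_half(self, rng):
        g = np.ones((2000, 1), dtype=int)
        ref_d, alt_d = simulate_depths(g, mean_depth=1000, error_rate=0.0, seed=rng)
        balance = alt_d / (ref_d + alt_d)
        assert abs(balance.mean() - 0.5) < 3 * np.sqrt(0.25 / 1000 / 2000)

    def test_hom_sites_pure_without_error(self, rng):
        g = np.array([[0, 2]] * 500)
        ref_d, alt_d = simulate_depths(g, mean_depth=30, error_rate=0.0, seed=rng)
        assert np.all(alt_d[:, 0] == 0)
        assert np.all(ref_d[:, 1] == 0)

    def test_fixed_seed_bitwise_identical(self):
        g = np.array([[0, 1, 2]] * 100)
        a = simulate_depths(g, 30, 0.01, seed=5)
        b = simulate_depths(g, 30, 0.01, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_depths(np.zeros((1, 1)), mean_depth=0)
        with pytest.raises(ValueError):
            simulate_depths(np.zeros((1, 1)), mean_depth=10, error_rate=0.7)


class TestLengthDistribution:
    @pytest.mark.parametrize("dist", [
        LengthDistribution("constant", (1500,)),
        LengthDistribution("geometric", (1500,)),
        LengthDistribution("uniform", (100, 2000)),
    ])
    def test_samples_at_least_one_bp(self, dist, rng):
        draws = [dist.sample(rng) for _ in range(500)]
        assert min(draws) >= 1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            LengthDistribution("normal", (10,))
        with pytest.raises(ValueError):
            LengthDistribution("constant", (0.5,))
        with pytest.raises(ValueError):
            LengthDistribution("uniform", (200, 100))
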