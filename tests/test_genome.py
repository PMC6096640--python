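"""Meiosis, doubled haploids, founder simulation and the additive trait."""

import numpy as np
import pytest

from twopartsim.genome import (
    GeneticMap,
    HaplotypePopulation,
    InvalidConfigurationError,
    TraitArchitecture,
    genetic_values,
    genic_variance,
    make_cross,
    make_dh,
    make_dh_lines,
    simulate_founders,
)


class TestGeneticMap:
    def test_regular_map_counts_and_roles(self):
        gm = GeneticMap.regular(3, 7, 5, 1.2)
        assert gm.n_loci == 36
        assert gm.causal_indices.size == 21
        assert gm.marker_indices.size == 15
        for c in range(3):
            p = gm.position[gm.chromosome == c]
            assert np.all(np.diff(p) > 0)

    def test_rejects_empty_and_unsorted(self):
        with pytest.raises(InvalidConfigurationError):
            GeneticMap.regular(0, 5, 5)
        with pytest.raises(InvalidConfigurationError):
            GeneticMap(
                chromosome=[0, 0],
                position=[0.5, 0.2],
                is_causal=[True, True],
                is_marker=[False, False],
                chrom_length=[1.0],
            )


class TestFounders:
    def test_maf_floor_and_determinism(self, small_map):
        pop = simulate_founders(30, small_map, rng_seed=5, maf_floor=0.05)
        freq = pop.allele_frequencies()
        assert np.all(np.minimum(freq, 1 - freq) >= 0.05)
        pop2 = simulate_founders(30, small_map, rng_seed=5, maf_floor=0.05)
        assert np.array_equal(pop.haplotypes, pop2.haplotypes)

    def test_frequencies_match_recount(self, small_map):
        gm = GeneticMap.regular(1, 5, 5, 1.0)
        pop = simulate_founders(2, gm, rng_seed=7)
        manual = pop.haplotypes.reshape(-1, gm.n_loci).mean(axis=0)
        assert np.allclose(pop.allele_frequencies(), manual)

    def test_too_few_individuals(self, small_map):
        with pytest.raises(InvalidConfigurationError):
            simulate_founders(1, small_map, rng_seed=1)


class TestMeiosis:
    def test_progeny_alleles_are_parental(self, founders):
        rng = np.random.default_rng(0)
        prog = make_cross(founders, "f0", "f1", 50, rng)
        i0, i1 = founders.index_of(["f0", "f1"])
        mat = founders.haplotypes[i0]
        pat = founders.haplotypes[i1]
        # maternal gamete allele must be one of the mother's two alleles
        m_ok = (prog.haplotypes[:, 0, :] == mat[0]) | (
            prog.haplotypes[:, 0, :] == mat[1]
        )
        p_ok = (prog.haplotypes[:, 1, :] == pat[0]) | (
            prog.haplotypes[:, 1, :] == pat[1]
        )
        assert m_ok.all() and p_ok.all()

    def test_homozygous_mother_transmits_exactly(self, small_map):
        haps = np.zeros((2, 2, small_map.n_loci), dtype=np.uint8)
        haps[0, :, ::2] = 1  # mother homozygous alternating 1/0
        haps[1, :, :] = np.random.default_rng(3).integers(
            0, 2, (2, small_map.n_loci), dtype=np.uint8
        )
        pop = HaplotypePopulation(np.array(["mom", "dad"]), haps, small_map)
        prog = make_cross(pop, "mom", "dad", 20, np.random.default_rng(1))
        assert np.array_equal(
            prog.haplotypes[:, 0, :], np.tile(haps[0, 0], (20, 1))
        )

    def test_selfing_rejected(self, founders):
        with pytest.raises(InvalidConfigurationError):
            make_cross(founders, "f0", "f0", 3, np.random.default_rng(0))

    def test_haldane_recombinant_fraction(self):
        """Two loci 1 Morgan apart: r = (1 - e^-2)/2 ~ 0.432."""
        gm = GeneticMap(
            chromosome=[0, 0],
            position=[0.0001, 1.0001],
            is_causal=[True, True],
            is_marker=[False, False],
            chrom_length=[1.1],
        )
        haps = np.zeros((1, 2, 2), dtype=np.uint8)
        haps[0, 0] = [1, 1]  # coupling double heterozygote
        parent = HaplotypePopulation(np.array(["p"]), haps, gm)
        n = 10_000
        dh = make_dh(parent, "p", n, np.random.default_rng(123))
        gam = dh.haplotypes[:, 0, :]
        rec_frac = (gam[:, 0] != gam[:, 1]).mean()
        r = 0.5 * (1 - np.exp(-2 * 1.0))
        se = np.sqrt(r * (1 - r) / n)
        assert abs(rec_frac - r) < 3 * se


class TestDoubledHaploids:
    def test_fully_homozygous(self, founders):
        dh = make_dh(founders, "f3", 25, np.random.default_rng(9))
        assert np.all(dh.heterozygosity() == 0.0)

    def test_homozygous_parent_reproduced_exactly(self, small_map):
        haps = np.random.default_rng(5).integers(
            0, 2, (1, 1, small_map.n_loci), dtype=np.uint8
        )
        haps = np.repeat(haps, 2, axis=1)  # homozygous everywhere
        pop = HaplotypePopulation(np.array(["h"]), haps, small_map)
        dh = make_dh(pop, "h", 10, np.random.default_rng(1))
        assert np.all(dh.haplotypes == haps[0, 0])

    def test_dh_frequency_matches_parental_dosage(self, founders):
        """Mean DH allele frequency ~ parental dosage / 2, per locus."""
        n = 5000
        dh = make_dh(founders, "f7", n, np.random.default_rng(77))
        i = founders.index_of("f7")[0]
        expect = founders.haplotypes[i].sum(axis=0) / 2.0
        got = dh.haplotypes[:, 0, :].mean(axis=0)
        se = np.sqrt(np.maximum(expect * (1 - expect), 1e-12) / n)
        assert np.all(np.abs(got - expect) <= 3 * se + 1e-12)


class TestSerialization:
    def test_haplotype_csv_round_trip(self, founders, small_map, tmp_path):
        path = tmp_path / "pop.csv"
        founders.to_haplotype_csv(path)
        back = HaplotypePopulation.from_haplotype_csv(path, small_map)
        assert np.array_equal(back.haplotypes, founders.haplotypes)
        assert back.ids.tolist() == founders.ids.tolist()

    def test_dosage_csv_layout(self, founders, tmp_path):
        import pandas as pd

        path = tmp_path / "dos.csv"
        founders.to_dosage_csv(path)
        df = pd.read_csv(path)
        assert df.shape == (founders.n, founders.gmap.marker_indices.size + 1)
        assert np.array_equal(
            df.drop(columns="id").to_numpy(), founders.marker_dosages()
        )


class TestTrait:
    def test_zero_effects_give_intercept(self, founders, small_map):
        trait = TraitArchitecture(small_map.causal_indices,
                                  np.zeros(small_map.causal_indices.size), 3.5)
        assert np.allclose(genetic_values(founders, trait), 3.5)

    def test_single_locus_closed_form(self, small_map):
        L = small_map.n_loci
        haps = np.zeros((3, 2, L), dtype=np.uint8)
        ci = small_map.causal_indices[0]
        haps[1, 0, ci] = 1
        haps[2, :, ci] = 1
        pop = HaplotypePopulation(np.array(["a", "b", "c"]), haps, small_map)
        trait = TraitArchitecture(np.array([ci]), np.array([2.0]), 1.0)
        assert np.allclose(genetic_values(pop, trait), [1.0, 3.0, 5.0])

    def test_matches_bruteforce_sum(self, founders, small_map):
        rng = np.random.default_rng(8)
        ci = small_map.causal_indices
        trait = TraitArchitecture(ci, rng.normal(0, 1, ci.size), 0.7)
        vals = genetic_values(founders, trait)
        d = founders.dosages()
        manual = [
            0.7 + sum(d[i, j] * a for j, a in zip(ci, trait.alpha))
            for i in range(founders.n)
        ]
        assert np.allclose(vals, manual)


class TestGenicVariance:
    def test_closed_form_half_half(self):
        assert genic_variance([0.5, 0.5], [1.0, 1.0]) == pytest.approx(1.0)

    def test_fixed_loci_give_zero(self):
        assert genic_variance([0.0, 1.0], [2.0, -3.0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(InvalidConfigurationError):
            genic_variance([0.5], [1.0, 2.0])

    def test_matches_hwe_monte_carlo(self):
        """Empirical variance of dosage scores under linkage equilibrium."""
        rng = np.random.default_rng(31)
        p = rng.uniform(0.1, 0.9, 30)
        a = rng.normal(0, 1, 30)
        n = 60_000
        dos = rng.binomial(2, p, size=(n, 30))
        emp = (dos @ a).var()
        assert emp == pytest.approx(genic_variance(p, a), rel=0.05)


class TestNeutralDrift:
    def test_mean_frequency_conserved_under_random_mating(self, small_map):
        """Across replicates of one random-mating generation the mean
        allele-frequency change is zero within Monte-Carlo error."""
        pop = simulate_founders(30, small_map, rng_seed=2)
        base = pop.allele_frequencies().mean()
        rng = np.random.default_rng(99)
        deltas = []
        for _ in range(200):
            mothers = rng.integers(0, pop.n, pop.n)
            fathers = (mothers + rng.integers(1, pop.n, pop.n)) % pop.n
            from twopartsim.genome import _gametes

            child = np.stack(
                [_gametes(pop, mothers, rng), _gametes(pop, fathers, rng)], axis=1
            )
            deltas.append(child.mean() - base)
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) <= 3 * max(se, 1e-9)
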