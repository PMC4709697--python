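"""Wright-Fisher burn-in, meiosis, mating designs, traits and phenotypes."""

import numpy as np
import pandas as pd
import pytest

from radgs import popsim as ps
from radgs.genome import SNPCatalogue, ValidationError

from conftest import make_catalogue


def _single_locus_cat(freq=0.5):
    return SNPCatalogue(pd.DataFrame(
        {"chrom": ["chr1"], "pos": [0], "ref": [0], "alt": [1],
         "freq": [freq]}))


class TestBurnin:
    def test_zero_generations_returns_founders(self):
        cat = make_catalogue(50, seed=1)
        pop = ps.founders_from_catalogue(cat, 20, seed=2)
        out = ps.burnin_fisher_wright(pop, 0, 20, seed=3)
        assert out is pop

    def test_seed_determinism(self):
        cat = make_catalogue(100, seed=4)
        a = ps.burnin_fisher_wright(cat, 30, 40, seed=5)
        b = ps.burnin_fisher_wright(cat, 30, 40, seed=5)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_odd_or_zero_pop_size_rejected(self):
        cat = make_catalogue(10, seed=1)
        with pytest.raises(ValidationError):
            ps.burnin_fisher_wright(cat, 1, 0)
        with pytest.raises(ValidationError):
            ps.burnin_fisher_wright(cat, 1, 21)

    def test_drift_decay_oracle(self):
        # closed form: E[H_t] = H_0 (1 - 1/(2N))^t for neutral WF drift
        N, t, reps = 50, 20, 2000
        hets = np.empty(reps)
        cat = _single_locus_cat(0.5)
        for r in range(reps):
            pop = ps.burnin_fisher_wright(cat, t, N, mutation_rate=0.0,
                                          seed=r)
            f = pop.allele_freqs()[0]
            hets[r] = 2 * f * (1 - f)
        expect = 0.5 * (1 - 1 / (2 * N)) ** t
        # Monte-Carlo 3-sigma band on the replicate mean
        assert abs(hets.mean() - expect) < 3 * hets.std() / np.sqrt(reps)

    def test_fixation_probability_matches_initial_frequency(self):
        # diffusion theory: a neutral allele fixes with prob = p0
        N, t, reps, p0 = 20, 400, 600, 0.3
        cat = _single_locus_cat(p0)
        fixed = alive = 0
        for r in range(reps):
            pop = ps.burnin_fisher_wright(cat, t, N, mutation_rate=0.0,
                                          seed=10_000 + r)
            f = pop.allele_freqs()[0]
            if f == 1.0:
                fixed += 1
            elif f > 0.0:
                alive += 1
        assert alive / reps < 0.05  # essentially all resolved after 20N gens
        sd = np.sqrt(p0 * (1 - p0) / reps)
        assert abs(fixed / reps - p0) < 3.5 * sd

    def test_diploid_init_all_heterozygous(self):
        cat = make_catalogue(60, seed=6)
        pop = ps.founders_from_catalogue(cat, 10, seed=7, init="diploid")
        assert (pop.genotypes() == 1).all()
        assert np.allclose(pop.allele_freqs(), 0.5)


class TestGametes:
    def test_identical_parental_haplotypes_pass_through(self):
        cat = make_catalogue(30, seed=8)
        loci = ps.LocusMap.from_catalogue(cat)
        hap = np.tile(np.random.default_rng(0).integers(0, 2, 30,
                                                        dtype=np.uint8),
                      (1, 2, 1))
        pop = ps.Population(hap, loci, np.array([0]), np.array([-1]),
                            np.array([-1]), np.array([-1]))
        for s in range(5):
            g = ps.make_gamete(pop, 0, np.random.default_rng(s))
            assert np.array_equal(g, hap[0, 0])

    def test_single_locus_mendelian_ratio(self):
        cat = _single_locus_cat()
        loci = ps.LocusMap.from_catalogue(cat)
        hap = np.array([[[0], [1]]], dtype=np.uint8)
        rng = np.random.default_rng(9)
        draws = ps._make_gametes(np.repeat(hap, 1, 0),
                                 np.zeros(4000, dtype=np.int64), loci, rng)
        frac = draws.mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(4000)

    def test_haldane_recombinant_fraction_at_50cm(self):
        # r = (1 - exp(-2d))/2 with d = 0.5 Morgans -> 0.316
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [0, 50_000_000],
                           "ref": 0, "alt": 1, "freq": 0.5})
        loci = ps.LocusMap.from_catalogue(SNPCatalogue(df))
        hap = np.zeros((1, 2, 2), dtype=np.uint8)
        hap[0, 1] = 1
        g = ps._make_gametes(hap, np.zeros(10_000, dtype=np.int64), loci,
                             np.random.default_rng(10))
        rec = (g[:, 0] != g[:, 1]).mean()
        expect = 0.5 * (1 - np.exp(-1.0))
        assert abs(rec - expect) < 3 * np.sqrt(expect * (1 - expect) / 10_000)

    def test_independent_assortment_across_chromosomes(self):
        df = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [0, 0],
                           "ref": 0, "alt": 1, "freq": 0.5})
        loci = ps.LocusMap.from_catalogue(SNPCatalogue(df))
        hap = np.zeros((1, 2, 2), dtype=np.uint8)
        hap[0, 1] = 1
        g = ps._make_gametes(hap, np.zeros(8000, dtype=np.int64), loci,
                             np.random.default_rng(11))
        rec = (g[:, 0] != g[:, 1]).mean()
        assert abs(rec - 0.5) < 3 * 0.5 / np.sqrt(8000)


class TestMateDesign:
    @pytest.fixture(scope="class")
    def base(self):
        cat = make_catalogue(200, seed=12)
        return ps.burnin_fisher_wright(cat, 20, 300, seed=13)

    def test_simulation1_counts(self, base):
        off = ps.mate_design(base, ps.SIMULATION_1, seed=14)
        assert off.n == 2000
        fam, counts = np.unique(off.family, return_counts=True)
        assert fam.size == 100 and (counts == 20).all()

    def test_simulation2_counts(self, base):
        off = ps.mate_design(base, ps.SIMULATION_2, seed=15)
        assert off.n == 1000
        fam, counts = np.unique(off.family, return_counts=True)
        assert fam.size == 20 and (counts == 50).all()
        # only 10 sires and 10 dams serve the 20 families
        assert np.unique(off.sire).size == 10
        assert np.unique(off.dam).size == 10

    def test_offspring_are_parental_mosaics(self, base):
        off = ps.mate_design(base, ps.MatingDesign(3, 3, 3, 10), seed=16)
        id_to_row = {int(v): i for i, v in enumerate(base.ids)}
        X = base.haplotypes
        for i in range(off.n):
            for h, parent in ((0, off.sire[i]), (1, off.dam[i])):
                ph = X[id_to_row[int(parent)]]
                gam = off.haplotypes[i, h]
                # every allele must come from one of the parent haplotypes
                assert ((gam == ph[0]) | (gam == ph[1])).all()

    def test_insufficient_parents_rejected(self, base):
        with pytest.raises(ValidationError):
            ps.mate_design(base, ps.MatingDesign(400, 400, 400, 1), seed=17)

    def test_allele_frequency_conserved_in_expectation(self, base):
        # one generation of random mating without selection/mutation
        f0 = base.allele_freqs()
        drifts = []
        for s in range(30):
            off = ps.mate_design(base, ps.SIMULATION_1, seed=100 + s)
            drifts.append(off.allele_freqs() - f0)
        mean_drift = np.abs(np.mean(drifts, axis=0)).mean()
        assert mean_drift < 0.01


class TestTraits:
    def test_assign_qtl_basic(self):
        arch = ps.assign_qtl(10_000, 5000, seed=18)
        assert np.unique(arch.qtl_idx).size == 5000
        assert abs(arch.additive.mean()) < 3 / np.sqrt(5000)
        assert abs(arch.additive.var() - 1) < 0.1
        assert (arch.dominance == 0).all()

    def test_assign_qtl_too_many_rejected(self):
        with pytest.raises(ValidationError):
            ps.assign_qtl(10, 11)

    def test_genetic_values_match_naive_loop(self):
        cat = make_catalogue(80, seed=19)
        pop = ps.burnin_fisher_wright(cat, 5, 50, seed=20)
        arch = ps.assign_qtl(80, 30, dominance_ratio=0.3, seed=21)
        tbv, dom = ps.genetic_values(pop, arch)
        X = pop.genotypes()
        for i in np.random.default_rng(22).choice(50, 10, replace=False):
            t = sum(X[i, j] * a for j, a in zip(arch.qtl_idx, arch.additive))
            d = sum((X[i, j] == 1) * dd
                    for j, dd in zip(arch.qtl_idx, arch.dominance))
            assert np.isclose(tbv[i], t) and np.isclose(dom[i], d)

    def test_all_reference_homozygote_has_zero_tbv(self):
        cat = make_catalogue(20, seed=23)
        loci = ps.LocusMap.from_catalogue(cat)
        hap = np.zeros((3, 2, 20), dtype=np.uint8)
        pop = ps.Population(hap, loci, np.arange(3), np.full(3, -1),
                            np.full(3, -1), np.full(3, -1))
        arch = ps.assign_qtl(20, 5, seed=24)
        tbv, dom = ps.genetic_values(pop, arch)
        assert np.allclose(tbv, 0) and np.allclose(dom, 0)


class TestPhenotypes:
    def test_h2_one_is_noise_free(self):
        tbv = np.random.default_rng(25).normal(0, 2, 500)
        phen = ps.simulate_phenotypes(tbv, 1.0, seed=26)
        assert np.allclose(phen.phenotype, tbv)

    def test_realized_h2_close_to_target_large_n(self):
        rng = np.random.default_rng(27)
        tbv = rng.normal(0, 3, 10_000)
        phen = ps.simulate_phenotypes(tbv, 0.5, seed=28)
        # regression-based estimate: var(tbv)/var(y)
        est = tbv.var() / phen.phenotype.var()
        assert abs(est - 0.5) < 0.03

    def test_seed_reproducibility(self):
        tbv = np.arange(100, dtype=float)
        a = ps.simulate_phenotypes(tbv, 0.3, seed=29)
        b = ps.simulate_phenotypes(tbv, 0.3, seed=29)
        assert np.array_equal(a.phenotype, b.phenotype)

    def test_dominance_share_calibration(self):
        rng = np.random.default_rng(30)
        tbv = rng.normal(0, 2, 20_000)
        dom_raw = rng.normal(0, 1, 20_000)
        phen = ps.simulate_phenotypes(tbv, 0.3, dominance=dom_raw,
                                      dominance_share=0.3, seed=31)
        vp = phen.phenotype.var()
        assert abs(phen.dominance.var() / vp - 0.3) < 0.05
        assert abs(tbv.var() / vp - 0.3) < 0.05

    def test_zero_variance_tbv_rejected(self):
        with pytest.raises(ValidationError):
            ps.simulate_phenotypes(np.ones(10), 0.5, seed=1)

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValidationError):
            ps.simulate_phenotypes(np.arange(10.0), 0.0)
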