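"""Simulator unit and property tests: genome sampling, drift against the
Wright-Fisher closed form, Mendelian transmission, selection response,
admixture, genotyping noise and variant QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapstep import simpop as sp
from hapstep import diversity as dv

from conftest import tiny_genome_config, wf_population


# ---------------------------------------------------------------------------
# genome and architecture
# ---------------------------------------------------------------------------


class TestGenomeSampling:
    def test_counts_and_disjoint_positions(self, tiny_map_and_arch):
        cfg, gmap, _ = tiny_map_and_arch
        assert gmap.n_loci == cfg.n_markers_hd + cfg.n_qtl
        for c in range(len(gmap.chrom_names)):
            pos = gmap.pos_bp[gmap.chrom == c]
            assert len(np.unique(pos)) == len(pos)
            assert np.all(np.diff(gmap.pos_cm[gmap.chrom == c]) > 0)

    def test_polygenic_variance_partition(self, tiny_map_and_arch):
        _, _, arch = tiny_map_and_arch
        # h2=0.30, qtl_h2=0.15, var_pheno=100 -> polygenic remainder 15
        assert arch.var_polygenic == pytest.approx(15.0)
        assert arch.var_residual == pytest.approx(70.0)

    def test_qtl_allele_counts_in_range(self, tiny_map_and_arch):
        cfg, gmap, _ = tiny_map_and_arch
        lo, hi = cfg.qtl_allele_range
        assert np.all((gmap.qtl_n_alleles >= lo) & (gmap.qtl_n_alleles <= hi))

    def test_same_seed_identical(self):
        cfg = tiny_genome_config()
        tc = sp.TraitConfig(h2=0.3, qtl_h2=0.15)
        g1, a1 = sp.sample_genome_and_architecture(cfg, tc, seed=5)
        g2, a2 = sp.sample_genome_and_architecture(cfg, tc, seed=5)
        assert np.array_equal(g1.pos_cm, g2.pos_cm)
        assert np.array_equal(a1.qtl_effects, a2.qtl_effects)

    def test_too_many_loci_rejected(self):
        cfg = sp.GenomeConfig(
            chromosomes=(("c1", 0.001),), n_markers_hd=5000,
            n_markers_medium=10, n_qtl=0,
        )
        with pytest.raises(ValueError, match="distinguishable"):
            sp.sample_genome_and_architecture(
                cfg, sp.TraitConfig(h2=0.3, qtl_h2=0.1), seed=1
            )


# ---------------------------------------------------------------------------
# historical phase: drift, LD, determinism
# ---------------------------------------------------------------------------


class TestHistorical:
    def test_heterozygosity_decay_matches_wright_fisher(self):
        """Mean 2pq after t generations ~ H0 (1 - 1/2N)^t (neutral drift)."""
        N, t, reps = 20, 15, 60
        hets = []
        for r in range(reps):
            pop = wf_population(n=N, n_loci=40, n_gens=t, seed=1000 + 3 * r)
            p = pop.allele_freq()
            hets.append(np.mean(2 * p * (1 - p)))
        expected = 0.5 * (1 - 1 / (2 * N)) ** t
        assert np.mean(hets) == pytest.approx(expected, abs=0.03)

    def test_bottleneck_raises_ld(self):
        """A bottleneck inflates r2 at fixed distance vs a constant census."""
        cfg = tiny_genome_config(n_chrom=1, length=50.0, n_markers=120, n_qtl=0)
        gmap, _ = sp.sample_genome_and_architecture(
            cfg, sp.TraitConfig(h2=0.3, qtl_h2=0.0), seed=7
        )
        r2_const, r2_bott = [], []
        for r in range(6):
            const = sp.simulate_historical(
                cfg, gmap, [sp.HistPhase(30, 200, 200)], seed=50 + r
            )
            bott = sp.simulate_historical(
                cfg, gmap,
                [sp.HistPhase(15, 200, 200), sp.HistPhase(15, 30, 30)],
                seed=50 + r,
            )
            kw = dict(target_c=0.05, window_frac=0.5, maf_min=0.05, seed=1)
            r2_const.append(dv.mean_r2_at_distance(const, gmap.marker_idx, **kw))
            r2_bott.append(dv.mean_r2_at_distance(bott, gmap.marker_idx, **kw))
        assert np.mean(r2_bott) > np.mean(r2_const)

    def test_same_seed_bit_identical(self):
        p1 = wf_population(n=30, n_loci=50, n_gens=5, seed=77)
        p2 = wf_population(n=30, n_loci=50, n_gens=5, seed=77)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)

    def test_extinction_aborts(self):
        cfg = tiny_genome_config(n_chrom=1, n_markers=20, n_qtl=0)
        gmap, _ = sp.sample_genome_and_architecture(
            cfg, sp.TraitConfig(h2=0.3, qtl_h2=0.0), seed=1
        )
        with pytest.raises(sp.SimulationError):
            sp.simulate_historical(cfg, gmap, [sp.HistPhase(5, 50, 0)], seed=2)


class TestMeiosis:
    def test_mendelian_transmission(self, rng):
        """A heterozygous locus transmits each allele ~50% (chi2, n=1e4)."""
        H = np.zeros((1, 2, 3), dtype=np.uint8)
        H[0, 1, :] = 1  # heterozygous at all loci
        rec = np.array([0.5, 0.5])
        gam = sp._gametes(H, np.zeros(10_000, dtype=int), rec, rng)
        count1 = int(gam[:, 1].sum())
        chi2 = (count1 - 5000) ** 2 / 5000 + ((10_000 - count1) - 5000) ** 2 / 5000
        assert chi2 < stats.chi2.ppf(0.99, df=1)

    def test_crossover_rate_matches_map_length(self, rng):
        """Expected switches along a chromosome ~ length/100 under Haldane."""
        L, length_cm = 200, 100.0
        pos = np.linspace(0, length_cm, L)
        d = np.diff(pos) / 100.0
        rec = 0.5 * (1 - np.exp(-2 * d))
        H = np.zeros((1, 2, L), dtype=np.uint8)
        H[0, 1, :] = 1  # strand origin readable from the allele
        gam = sp._gametes(H, np.zeros(4000, dtype=int), rec, rng)
        switches = np.abs(np.diff(gam.astype(int), axis=1)).sum(axis=1)
        # observable switch count ~ Poisson(length/100) thinned by even/odd
        # cancellation between distant loci; with 200 dense loci the loss is
        # negligible at 1 Morgan
        assert np.mean(switches) == pytest.approx(1.0, rel=0.15)


# ---------------------------------------------------------------------------
# breed founding, phenotypes, selection
# ---------------------------------------------------------------------------


class TestFoundBreed:
    def test_full_sample_is_identity(self):
        hist = wf_population(n=30, n_loci=40, n_gens=3, seed=9)
        b = sp.found_breed(hist, 30, seed=1)
        assert np.array_equal(
            np.sort(b.haplotypes, axis=0), np.sort(hist.haplotypes, axis=0)
        )

    def test_seeds_differ(self):
        hist = wf_population(n=60, n_loci=40, n_gens=3, seed=9)
        b1 = sp.found_breed(hist, 20, seed=1)
        b2 = sp.found_breed(hist, 20, seed=2)
        assert not np.array_equal(b1.haplotypes, b2.haplotypes)

    def test_founder_freqs_track_binomial_se(self):
        hist = wf_population(n=200, n_loci=80, n_gens=5, seed=13)
        n_f = 100
        b = sp.found_breed(hist, n_f, seed=3)
        p0 = hist.allele_freq()
        p1 = b.allele_freq()
        se = np.sqrt(np.maximum(p0 * (1 - p0), 1e-9) / (2 * n_f))
        frac_within = np.mean(np.abs(p1 - p0) <= 4 * se + 1e-12)
        assert frac_within > 0.95

    def test_oversampling_rejected(self):
        hist = wf_population(n=20, n_loci=20, n_gens=2, seed=4)
        with pytest.raises(ValueError):
            sp.found_breed(hist, 21, seed=0)


class TestPhenotypes:
    def test_h2_one_means_phenotype_equals_tbv(self):
        hist = wf_population(n=50, n_loci=60, n_gens=3, seed=31)
        cfg = tiny_genome_config(n_chrom=1, n_markers=40, n_qtl=20)
        gmap, arch = sp.sample_genome_and_architecture(
            cfg, sp.TraitConfig(h2=1.0, qtl_h2=0.5), seed=32
        )
        pop = sp.simulate_historical(
            cfg, gmap, [sp.HistPhase(3, 60, 60)], seed=33, arch=arch
        )
        sp.assign_phenotypes(pop, seed=34)
        assert np.allclose(pop.phenotype, pop.tbv + pop.trait.mean)

    def test_founder_sample_heritability(self):
        """var(tbv)/var(phenotype) ~ configured h2 in a large founder cohort."""
        cfg = tiny_genome_config(n_chrom=2, n_markers=200, n_qtl=40)
        gmap, arch = sp.sample_genome_and_architecture(
            cfg, sp.TraitConfig(h2=0.30, qtl_h2=0.15), seed=41
        )
        pop = sp.simulate_historical(
            cfg, gmap, [sp.HistPhase(2, 10_000, 10_000)], seed=42, arch=arch
        )
        sp.assign_phenotypes(pop, seed=43)
        h2_hat = np.var(pop.tbv) / np.var(pop.phenotype)
        # 3 SE of a variance-ratio at n = 10,000 is well under 0.02
        assert h2_hat == pytest.approx(0.30, abs=0.02)


class TestSelection:
    @staticmethod
    def _founders(seed, n=60, h2=0.4):
        cfg = tiny_genome_config(n_chrom=1, n_markers=80, n_qtl=20)
        gmap, arch = sp.sample_genome_and_architecture(
            cfg, sp.TraitConfig(h2=h2, qtl_h2=h2 / 2), seed=seed
        )
        hist = sp.simulate_historical(
            cfg, gmap, [sp.HistPhase(4, n, n)], seed=seed + 1, arch=arch
        )
        pop = sp.found_breed(hist, n, seed=seed + 2)
        return sp.assign_phenotypes(pop, seed=seed + 3)

    @pytest.mark.parametrize("direction,sign", [("up", 1.0), ("down", -1.0)])
    def test_selection_moves_mean_tbv(self, direction, sign):
        """Truncation selection shifts TBV in the chosen direction
        (sign test over 20 independent replicates)."""
        wins = 0
        for r in range(20):
            pop = self._founders(1000 + 10 * r)
            sel = sp.run_recent_selection(
                pop, 3, "phenotypic", direction,
                sp.MatingConfig(dams_per_sire=3), seed=r,
            )
            gen = sel.pedigree["generation"].to_numpy()
            delta = sel.tbv[gen == 3].mean() - sel.tbv[gen == 0].mean()
            wins += sign * delta > 0
        assert wins >= 15  # binomial(20, 0.5) upper 0.1% is 17; 15 is ~2%

    def test_litter_size_distribution(self):
        pop = self._founders(77, n=200)
        sel = sp.run_recent_selection(
            pop, 4, "random", mating_cfg=sp.MatingConfig(), seed=5,
        )
        ped = sel.pedigree
        off = ped[ped["generation"] > 0]
        sizes = off.groupby(["generation", "dam"]).size().to_numpy()
        freqs = np.bincount(sizes, minlength=4)[1:4] / len(sizes)
        assert np.allclose(freqs, [0.30, 0.50, 0.20], atol=0.06)

    def test_pedigree_is_acyclic_and_parents_recorded(self, small_pop):
        ped = small_pop.pedigree
        ids = ped["id"].to_numpy()
        pos = {i: k for k, i in enumerate(ids)}
        for col in ("sire", "dam"):
            parents = ped[col].to_numpy()
            known = parents != 0
            assert all(pos[p] < k for k, p in zip(np.flatnonzero(known), parents[known]))
        nonfounder = ped["generation"] > 0
        assert (ped.loc[nonfounder, ["sire", "dam"]] != 0).all().all()

    def test_same_seed_reproduces_population(self):
        pop1 = self._founders(500)
        pop2 = self._founders(500)
        mc = sp.MatingConfig(dams_per_sire=3)
        s1 = sp.run_recent_selection(pop1, 3, "ebv", "up", mc, seed=9)
        s2 = sp.run_recent_selection(pop2, 3, "ebv", "up", mc, seed=9)
        assert np.array_equal(s1.haplotypes, s2.haplotypes)
        assert np.allclose(s1.phenotype, s2.phenotype)
        pd.testing.assert_frame_equal(s1.pedigree, s2.pedigree)

    def test_infeasible_mating_aborts(self):
        pop = self._founders(600, n=30)
        # census floor far above what 30 founders can produce
        with pytest.raises(sp.SimulationError):
            sp.run_recent_selection(
                pop, 2, "phenotypic", "up",
                sp.MatingConfig(dams_per_sire=3, min_census=5000), seed=1,
            )


class TestComposite:
    def test_single_parent_composite_is_random_mating(self):
        pop = TestSelection._founders(800, n=80)
        comp = sp.make_composite([pop], [1.0], n_random_gens=2, seed=3,
                                 n_founders=60, breed="C1")
        assert comp.pedigree["breed"].iloc[-1] == "C1"
        assert comp.pedigree["generation"].max() == 2

    def test_admixture_proportions_realized(self):
        p1 = TestSelection._founders(810, n=100)
        p2 = p1.copy()          # shares the genome map
        p2.pedigree["breed"] = "other"
        comp = sp.make_composite(
            [p1, p2], [0.625, 0.375], n_random_gens=0, seed=4, n_founders=80
        )
        frac = (comp.pedigree["origin_breed"] == "other").mean()
        assert frac == pytest.approx(0.375, abs=0.01)

    def test_gen0_freqs_are_weighted_parental_freqs(self):
        p1 = TestSelection._founders(820, n=150)
        # a drifted sister population on the same genome
        p2 = sp.run_recent_selection(
            p1.copy(), 3, "random", mating_cfg=sp.MatingConfig(n_dams=40),
            seed=99,
        )
        comp = sp.make_composite(
            [p1, p2], [0.5, 0.5], n_random_gens=0, seed=5, n_founders=140
        )
        last = p2.rows_of_generation(p2.pedigree["generation"].max())
        expect = 0.5 * p1.allele_freq() + 0.5 * p2.allele_freq(rows=last)
        # composite founders are a finite sample; agreement up to sampling
        got = comp.allele_freq()
        assert np.mean(np.abs(got - expect)) < 0.05

    def test_proportions_must_sum_to_one(self):
        p1 = TestSelection._founders(830, n=30)
        with pytest.raises(ValueError):
            sp.make_composite([p1, p1], [0.7, 0.6], 0, seed=1)


# ---------------------------------------------------------------------------
# genotyping and QC
# ---------------------------------------------------------------------------


class TestGenotyping:
    def test_zero_rates_reproduce_truth(self, small_pop):
        loci = small_pop.genome.marker_idx[:50]
        g = sp.apply_genotyping(small_pop, loci, missing_rate=0, error_rate=0, seed=1)
        truth = small_pop.haplotypes[:, :, loci].sum(axis=1)
        assert np.array_equal(g.dosages, truth.astype(np.int8))

    def test_missing_and_error_rates_realized(self, small_pop):
        loci = small_pop.genome.marker_idx
        g = sp.apply_genotyping(small_pop, loci, missing_rate=0.05,
                                error_rate=0.01, seed=2)
        n_calls = g.dosages.size
        se = np.sqrt(0.05 * 0.95 / n_calls)
        assert g.missing_fraction == pytest.approx(0.05, abs=3 * se)
        truth = small_pop.haplotypes[:, :, loci].sum(axis=1)
        obs = g.dosages
        changed = (obs != truth) & (obs != -1)
        err = changed.sum() / (obs != -1).sum()
        assert err == pytest.approx(0.01, abs=0.002)

    def test_error_makes_monomorphic_locus_polymorphic(self):
        pop = wf_population(n=300, n_loci=30, n_gens=1, seed=55)
        pop.haplotypes[:, :, 0] = 1  # force monomorphic
        g = sp.apply_genotyping(pop, np.array([0]), missing_rate=0,
                                error_rate=0.2, seed=3)
        assert len(np.unique(g.dosages)) > 1


class TestVariantQC:
    @staticmethod
    def _matrix(dosages):
        d = np.asarray(dosages, dtype=np.int8)
        m = d.shape[1]
        return sp.GenotypeMatrix(
            dosages=d, loci=np.arange(m), animal_rows=np.arange(d.shape[0]),
            animal_ids=np.arange(d.shape[0]) + 1,
        )

    def test_low_maf_removed(self, rng):
        n = 1000
        rare = np.zeros(n); rare[:5] = 1          # MAF 0.0025
        common = rng.binomial(2, 0.4, n)
        g = self._matrix(np.column_stack([rare, common]))
        out, rep = sp.qc_variants(g)
        assert list(out.loci) == [1]
        assert rep["n_removed_maf"] == 1

    def test_het_excess_removed(self):
        n = 400
        all_het = np.ones(n)                       # p=0.5, het dev = 0.5
        g = self._matrix(np.column_stack([all_het]))
        out, rep = sp.qc_variants(g)
        assert out.dosages.shape[1] == 0
        assert rep["empty"] and rep["n_removed_het_dev"] == 1

    def test_hand_counted_panel(self, rng):
        """10 loci, 3 violating rules -> 7 retained."""
        n = 2000
        cols = [rng.binomial(2, p, n) for p in (0.3, 0.5, 0.2, 0.45, 0.35, 0.25, 0.4)]
        bad_maf = np.zeros(n); bad_maf[:3] = 1
        bad_het = np.ones(n)
        bad_het2 = np.tile([0, 2], n // 2)         # no hets at p=0.5: dev 0.5
        g = self._matrix(np.column_stack(cols + [bad_maf, bad_het, bad_het2]))
        out, rep = sp.qc_variants(g)
        assert rep["n_kept"] == 7
        assert set(out.loci) == set(range(7))
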