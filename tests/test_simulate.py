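"""Generator behaviour: founder LD model, Mendelian gene-drop, trait
calibration and missingness injection."""

import numpy as np
import pytest
from scipy import stats

import shrimpgs as sg
from shrimpgs.simulate import GeneticMap, _gamete, default_line_of_family


class TestGeneticMap:
    def test_uniform_map_invariants(self):
        gmap = GeneticMap.uniform(1000, n_chromosomes=44)
        assert gmap.n_markers == 1000
        assert (gmap.marker_pos >= 0).all()
        for idx, pos, length in gmap.chromosome_blocks():
            assert (pos <= length).all()
            assert (np.diff(pos) >= 0).all()

    def test_position_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            GeneticMap(chromosomes=[("c1", 1.0)], marker_chrom=[0], marker_pos=[1.5])

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            GeneticMap(chromosomes=[("c1", 1.0)], marker_chrom=[0], marker_pos=[-0.1])


class TestFounders:
    def test_allele_frequencies_converge_without_ld(self):
        # no LD, MAF fixed at 0.5, 10,000 founders: frequencies within 0.02
        founders = sg.simulate_founders(
            5000, 5000, n_markers=60, maf_spec=0.5, ld_decay=0.0, seed=1
        )
        freqs = founders.haplotypes.mean(axis=0)
        assert np.abs(freqs - 0.5).max() < 0.02

    def test_colocated_markers_perfectly_correlated_at_high_ld(self):
        gmap = GeneticMap(
            chromosomes=[("c1", 1.0)], marker_chrom=[0, 0], marker_pos=[0.5, 0.5]
        )
        founders = sg.simulate_founders(
            500, 500, n_markers=2, gmap=gmap, maf_spec=0.3, ld_decay=1e9, seed=2
        )
        h = founders.haplotypes
        assert np.array_equal(h[:, 0], h[:, 1])

    def test_seeded_determinism(self):
        a = sg.simulate_founders(13, 13, 1000, seed=42)
        b = sg.simulate_founders(13, 13, 1000, seed=42)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError, match="minor allele frequencies"):
            sg.simulate_founders(5, 5, 10, maf_spec=0.7, seed=0)

    def test_line_divergence_separates_lines(self):
        lines = np.array([0] * 10 + [1] * 10)
        founders = sg.simulate_founders(
            10, 10, 2000, ld_decay=0.0,
            line_of_founder=np.concatenate([lines[:10], lines[10:]]),
            fst=0.2, seed=3,
        )
        geno = founders.to_genotypes()
        grm = sg.grm_vanraden(geno)
        same = grm.values[:5, 5:10].mean()  # within line 0, different founders
        cross = grm.values[:10, 10:].mean()
        assert same > cross  # line sharing raises relatedness


class TestGeneDrop:
    def test_homozygous_parent_transmits_allele_everywhere(self):
        rng = np.random.default_rng(0)
        gmap = GeneticMap.uniform(200, n_chromosomes=4)
        hap = np.ones(200, dtype=np.uint8)
        for _ in range(20):
            g = _gamete(hap, hap, gmap, rng)
            assert (g == 1).all()

    def test_zero_length_chromosome_transmits_intact_haplotype(self):
        gmap = GeneticMap(
            chromosomes=[("c1", 0.0)],
            marker_chrom=np.zeros(50, dtype=int),
            marker_pos=np.zeros(50),
        )
        rng = np.random.default_rng(1)
        hap_a = rng.integers(0, 2, 50).astype(np.uint8)
        hap_b = 1 - hap_a
        for _ in range(20):
            g = _gamete(hap_a, hap_b, gmap, rng)
            assert np.array_equal(g, hap_a) or np.array_equal(g, hap_b)

    def test_offspring_dosages_mendelian_consistent(self):
        founders = sg.simulate_founders(4, 4, 500, seed=5)
        fg = founders.to_genotypes()
        dose = dict(zip(fg.individual_ids, fg.dosages))
        matings = [("S01", "D01"), ("S02", "D02")]
        geno, fams = sg.make_families(founders, matings, 20, n_sampled=40, seed=6)
        for row, (_, sire, dam, _) in zip(
            geno.dosages, fams.table.itertuples(index=False)
        ):
            lo = (dose[sire] == 2).astype(int) + (dose[dam] == 2).astype(int)
            hi = (dose[sire] > 0).astype(int) + (dose[dam] > 0).astype(int)
            assert (row >= lo).all() and (row <= hi).all()

    def test_unknown_parent_rejected(self):
        founders = sg.simulate_founders(2, 2, 50, seed=7)
        with pytest.raises(KeyError, match="unknown parent"):
            sg.make_families(founders, [("S99", "D01")], 5, n_sampled=5, seed=0)

    def test_offspring_per_family_must_be_positive(self):
        founders = sg.simulate_founders(2, 2, 50, seed=7)
        with pytest.raises(ValueError, match="offspring_per_family"):
            sg.make_families(founders, [("S01", "D01")], 0, n_sampled=0, seed=0)

    def test_fullsib_mean_relationship_near_half(self):
        # pedigree expectation: full sibs average G ~ 0.5 (unstructured founders)
        geno, _, fams = sg.simulate_dataset(
            n_markers=5000, n_lines=1, fst=0.0, seed=8
        )
        grm = sg.grm_vanraden(geno)
        fam = np.array([fams.family_of()[i] for i in geno.individual_ids])
        same = np.equal.outer(fam, fam)
        off = ~np.eye(len(fam), dtype=bool)
        within = grm.values[same & off].mean()
        between = grm.values[~same].mean()
        assert abs(within - 0.5) < 0.05
        assert abs(between) < 0.05  # unrelated families ~ 0

    def test_default_line_assignment_sizes(self):
        lines = default_line_of_family(13, 7)
        _, counts = np.unique(lines, return_counts=True)
        assert sorted(counts.tolist(), reverse=True) == [2, 2, 2, 2, 2, 2, 1]


class TestTraits:
    def test_h2_zero_phenotype_independent_of_genotype(self, cohort):
        geno, _, _ = cohort
        arch = sg.TraitArchitecture(
            trait="body_weight", n_qtl=100, target_h2=0.0, target_mean=5.56,
            target_sd=2.16,
        )
        cors = []
        for s in range(15):
            rng = np.random.default_rng(1000 + s)
            full = sg.simulate.draw_architecture(arch, geno.n_markers, rng)
            u = geno.dosages[:, full.qtl_marker_indices] @ full.qtl_effects
            y = sg.simulate_traits(geno, full, seed=s).table["body_weight"]
            cors.append(np.corrcoef(u, y)[0, 1])
        assert abs(np.mean(cors)) < 0.1

    def test_h2_one_phenotype_is_affine_in_genetic_value(self, cohort):
        geno, _, _ = cohort
        arch = sg.TraitArchitecture(
            trait="body_weight", n_qtl=100, target_h2=1.0, target_mean=5.56,
            target_sd=2.16,
        )
        tbl = sg.simulate_traits(geno, arch, seed=3).table
        r = np.corrcoef(tbl["body_weight"], tbl["true_body_weight"])[0, 1]
        assert r > 1 - 1e-12

    def test_phenotypes_positive_and_on_scale(self, cohort):
        _, pheno, _ = cohort
        t = pheno.table
        assert (t["body_weight"] > 0).all() and (t["body_length"] > 0).all()
        assert abs(t["body_weight"].mean() - 5.56) < 0.8
        assert abs(t["body_length"].mean() - 76.99) < 4.0

    def test_shared_qtl_induce_genetic_correlation(self, cohort):
        _, pheno, _ = cohort
        t = pheno.table
        r = np.corrcoef(t["true_body_weight"], t["true_body_length"])[0, 1]
        assert r > 0.3

    def test_too_many_qtl_rejected(self, cohort):
        geno, _, _ = cohort
        arch = sg.TraitArchitecture(
            trait="body_weight", n_qtl=geno.n_markers + 1, target_h2=0.3,
            target_mean=5.0, target_sd=1.0,
        )
        with pytest.raises(ValueError, match="QTL"):
            sg.simulate_traits(geno, arch, seed=0)


class TestMissingness:
    def test_rate_zero_is_identity(self, cohort):
        geno, _, _ = cohort
        out = sg.inject_missingness(geno, 0.0, seed=0)
        assert np.array_equal(out.dosages, geno.dosages)

    def test_rate_one_saturates_marker(self, cohort):
        geno, _, _ = cohort

        def spec(rng, m):
            r = np.zeros(m)
            r[0] = 1.0
            return r

        out = sg.inject_missingness(geno, spec, seed=0)
        assert np.isnan(out.dosages[:, 0]).all()
        assert not np.isnan(out.dosages[:, 1:]).all()

    def test_invalid_rate_rejected(self, cohort):
        geno, _, _ = cohort
        with pytest.raises(ValueError, match="rates"):
            sg.inject_missingness(geno, 1.5, seed=0)

    def test_high_missingness_marker_count_matches_binomial_tail(self):
        # exact binomial oracle: P(Bin(200, 0.03) > 10) markers exceed the
        # 5% missing-rate threshold in expectation
        founders = sg.simulate_founders(50, 50, 4000, ld_decay=0.0, seed=31)
        geno = founders.to_genotypes().subset_individuals(
            founders.individual_ids[:100]
        )
        # build a 200-row matrix by stacking two founder panels
        f2 = sg.simulate_founders(100, 100, 4000, ld_decay=0.0, seed=32)
        geno = f2.to_genotypes()
        assert geno.n_individuals == 200
        out = sg.inject_missingness(geno, 0.03, seed=33)
        n_exceed = (np.isnan(out.dosages).mean(axis=0) > 0.05).sum()
        p_tail = stats.binom.sf(10, 200, 0.03)
        expected = 4000 * p_tail
        sd = np.sqrt(4000 * p_tail * (1 - p_tail))
        assert abs(n_exceed - expected) < 4 * sd + 1

    def test_dataset_seeded_determinism_end_to_end(self):
        a = sg.simulate_dataset(n_markers=300, n_qtl=80, missing_rate_spec=0.02,
                                seed=77)
        b = sg.simulate_dataset(n_markers=300, n_qtl=80, missing_rate_spec=0.02,
                                seed=77)
        assert np.array_equal(a[0].dosages, b[0].dosages, equal_nan=True)
        assert a[1].table.equals(b[1].table)
        assert a[2].table.equals(b[2].table)
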