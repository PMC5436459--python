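"""Genotype/phenotype IO round-trips, allele-frequency accounting, the
marker QC filters and imputation."""

import numpy as np
import pandas as pd
import pytest

import shrimpgs as sg
from shrimpgs import genio, qc
from tests.conftest import toy_genotypes


class TestIO:
    def test_dosage_tsv_round_trip_preserves_missing(self, tmp_path):
        geno = toy_genotypes(
            [[0, 1, 2, np.nan], [2, np.nan, 1, 0], [1, 1, 1, 1],
             [0, 0, 2, 2], [2, 2, 0, 0]]
        )
        path = tmp_path / "g.tsv"
        genio.write_dosage_tsv(geno, path)
        back = genio.read_dosage_tsv(path)
        assert back.individual_ids == geno.individual_ids
        assert back.marker_ids == geno.marker_ids
        assert np.array_equal(back.dosages, geno.dosages, equal_nan=True)

    def test_vcf_round_trip(self, tmp_path):
        geno = toy_genotypes([[0, 1], [2, np.nan], [1, 0]])
        path = tmp_path / "g.vcf"
        genio.write_vcf(geno, path)
        back = genio.read_vcf(path)
        assert back.individual_ids == geno.individual_ids
        assert np.array_equal(back.dosages, geno.dosages, equal_nan=True)

    def test_multiallelic_vcf_rejected_with_site(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\tsnp1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\n"
            "1\t200\tsnp2\tA\tT,G\t.\t.\t.\tGT\t0/0\t1/2\n"
        )
        with pytest.raises(ValueError, match="multi-allelic.*1:200"):
            genio.read_vcf(path)

    def test_fractional_dosages_not_writable_as_vcf(self, tmp_path):
        geno = toy_genotypes([[0.5, 1], [1, 2]])
        with pytest.raises(ValueError, match="integral"):
            genio.write_vcf(geno, tmp_path / "g.vcf")

    def test_phenotype_and_family_round_trip(self, tmp_path, cohort):
        _, pheno, fams = cohort
        genio.write_phenotypes(pheno, tmp_path / "p.tsv")
        genio.write_families(fams, tmp_path / "f.tsv")
        p2 = genio.read_phenotypes(tmp_path / "p.tsv")
        f2 = genio.read_families(tmp_path / "f.tsv")
        assert p2.individual_ids == pheno.individual_ids
        np.testing.assert_allclose(
            p2.table["body_weight"], pheno.table["body_weight"], rtol=1e-5
        )
        assert f2.table["family_index"].tolist() == fams.table["family_index"].tolist()

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            toy_genotypes([[0, 1], [1, 2]], ids=["a", "a"])


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "dosages, p, maf, miss",
        [
            ([[0], [1], [2]], 0.5, 0.5, 0.0),
            ([[2], [2], [2], [2]], 1.0, 0.0, 0.0),
            ([[0], [np.nan], [1], [2]], 0.5, 0.5, 0.25),
        ],
    )
    def test_hand_counted_cases(self, dosages, p, maf, miss):
        freqs = qc.allele_frequencies(toy_genotypes(dosages))
        assert freqs["alt_freq"].iloc[0] == pytest.approx(p)
        assert freqs["maf"].iloc[0] == pytest.approx(maf)
        assert freqs["missing_rate"].iloc[0] == pytest.approx(miss)

    def test_all_missing_marker_flagged_not_fatal(self):
        freqs = qc.allele_frequencies(toy_genotypes([[np.nan], [np.nan]]))
        assert np.isnan(freqs["maf"].iloc[0])
        assert freqs["missing_rate"].iloc[0] == 1.0


class TestQcFilter:
    def test_high_missing_marker_removed(self):
        # 20 individuals x 10 polymorphic markers; marker 5 has 3/20 missing
        d = np.tile(np.tile([0.0, 1.0, 2.0, 1.0], 5)[:, None], (1, 10))
        d[:3, 5] = np.nan
        geno = toy_genotypes(d)
        filtered, report = qc.qc_filter(geno)
        assert "m5" not in filtered.marker_ids
        assert report.n_markers_out == 9
        assert report.n_removed_missing == 1

    def test_boundary_markers_kept(self):
        # 200 individuals: marker 0 at exactly 5% missing, marker 1 at MAF
        # exactly 0.05 -- both strict removal rules leave them in
        n = 200
        d = np.zeros((n, 2))
        d[:95, 0] = np.tile([0, 1, 2, 1, 0], 19)
        d[190:, 0] = np.nan  # 10/200 = 5% missing
        d[:20, 1] = 1.0  # 20 alt alleles / 400 = 0.05 exactly
        geno = toy_genotypes(d)
        freqs = qc.allele_frequencies(geno)
        assert freqs["missing_rate"].iloc[0] == pytest.approx(0.05)
        assert freqs["maf"].iloc[1] == pytest.approx(0.05)
        filtered, _ = qc.qc_filter(geno)
        assert filtered.n_markers == 2

    def test_clean_input_identity(self, cohort):
        geno, _, _ = cohort
        filtered, report = qc.qc_filter(geno)
        # complete simulated matrix: nothing removed by missingness
        assert report.n_removed_missing == 0
        assert report.n_markers_out + report.n_removed_maf == geno.n_markers

    def test_idempotent(self, cohort_missing):
        geno, _, _ = cohort_missing
        once, r1 = qc.qc_filter(geno)
        twice, r2 = qc.qc_filter(once)
        assert once.marker_ids == twice.marker_ids
        assert r2.n_markers_out == r2.n_markers_in

    def test_report_counts_consistent(self, cohort_missing):
        geno, _, _ = cohort_missing
        _, report = qc.qc_filter(geno)
        assert (
            report.n_markers_in
            - report.n_removed_missing
            - report.n_removed_maf
            == report.n_markers_out
        )
        assert report.per_marker["kept"].sum() == report.n_markers_out

    def test_invalid_threshold_rejected(self, cohort):
        geno, _, _ = cohort
        with pytest.raises(ValueError, match="max_missing"):
            qc.qc_filter(geno, max_missing=1.2)


class TestImputation:
    def test_no_missing_is_identity(self, cohort):
        geno, _, _ = cohort
        out = qc.impute_missing(geno)
        assert np.array_equal(out.dosages, geno.dosages)

    def test_mean_dosage_hand_case(self):
        geno = toy_genotypes([[0, 1], [2, 1], [np.nan, 1]])
        out = qc.impute_missing(geno, "mean_dosage")
        assert out.dosages[2, 0] == pytest.approx(1.0)

    def test_family_mean_hand_case(self):
        geno = toy_genotypes(
            [[2], [2], [2], [np.nan], [0], [0]],
            ids=["a1", "a2", "a3", "a4", "b1", "b2"],
        )
        fams = sg.FamilyStructure(
            pd.DataFrame(
                {
                    "individual_id": ["a1", "a2", "a3", "a4", "b1", "b2"],
                    "sire_id": ["s1"] * 4 + ["s2"] * 2,
                    "dam_id": ["d1"] * 4 + ["d2"] * 2,
                    "family_index": [1, 1, 1, 1, 2, 2],
                }
            )
        )
        out = qc.impute_missing(geno, "family_mean", families=fams)
        assert out.dosages[3, 0] == pytest.approx(2.0)

    def test_family_mean_falls_back_to_global_mean(self):
        # only one called member in the family -> global marker mean used
        geno = toy_genotypes(
            [[2], [np.nan], [0], [0], [0], [1]],
            ids=["a1", "a2", "b1", "b2", "b3", "b4"],
        )
        fams = sg.FamilyStructure(
            pd.DataFrame(
                {
                    "individual_id": ["a1", "a2", "b1", "b2", "b3", "b4"],
                    "sire_id": ["s1"] * 2 + ["s2"] * 4,
                    "dam_id": ["d1"] * 2 + ["d2"] * 4,
                    "family_index": [1, 1, 2, 2, 2, 2],
                }
            )
        )
        out = qc.impute_missing(geno, "family_mean", families=fams)
        assert out.dosages[1, 0] == pytest.approx(3 / 5)

    def test_observed_calls_never_altered(self, cohort_missing):
        geno, _, _ = cohort_missing
        filtered, _ = qc.qc_filter(geno)
        out = qc.impute_missing(filtered)
        called = ~np.isnan(filtered.dosages)
        assert np.array_equal(out.dosages[called], filtered.dosages[called])
        assert not np.isnan(out.dosages).any()

    def test_all_missing_marker_is_error(self):
        geno = toy_genotypes([[np.nan, 0], [np.nan, 1]])
        with pytest.raises(ValueError, match="no calls"):
            qc.impute_missing(geno)

    def test_qc_removals_match_binomial_prediction(self, cohort_missing):
        from scipy import stats

        geno, _, _ = cohort_missing
        _, report = qc.qc_filter(geno, min_maf=0.0)
        p_tail = stats.binom.sf(10, 200, 0.03)
        expected = geno.n_markers * p_tail
        sd = np.sqrt(geno.n_markers * p_tail * (1 - p_tail))
        assert abs(report.n_removed_missing - expected) < 4 * sd + 2
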