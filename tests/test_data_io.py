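"""Genotype/phenotype I/O, SNP quality control and phenotype transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lgcblup import (GenotypeMatrix, PhenotypeTable, hwe_chisq, qc_filter,
                     quantile_normalize, read_phenotypes, read_plink,
                     write_phenotypes, write_plink)
from lgcblup.data_io import IntegrityError, PlinkFormatError


def _panel(codes, **kw):
    codes = np.asarray(codes, float)
    n, m = codes.shape
    defaults = dict(
        codes=codes,
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        chrom=np.array(["1"] * m),
        pos_bp=np.arange(1, m + 1) * 100,
        individual_ids=np.array([f"i{i}" for i in range(n)]),
        population=np.array(["A"] * n),
    )
    defaults.update(kw)
    return GenotypeMatrix(**defaults)


class TestPlink:
    def test_reads_reference_bed_written_by_hand(self, tmp_path):
        """A .bed assembled byte-by-byte from the published 2-bit encoding
        (00=hom A1, 10=het, 11=hom A2, 01=missing) decodes to the intended
        A1-dosage matrix."""
        (tmp_path / "ref.fam").write_text(
            "F1 I1 0 0 0 -9\nF1 I2 0 0 0 -9\nF2 I3 0 0 0 -9\n")
        (tmp_path / "ref.bim").write_text(
            "1 s1 0 100 A G\n1 s2 0 200 C T\n")
        # snp1: I1=2 (00), I2=1 (10), I3=0 (11) -> 0b01_11_10_00 = 120
        # snp2: I1=0 (11), I2=missing (01), I3=2 (00) -> 0b01_00_01_11 = 71
        (tmp_path / "ref.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 120, 71]))
        g = read_plink(tmp_path / "ref")
        expected = np.array([[2, 0], [1, np.nan], [0, 2.0]])
        np.testing.assert_array_equal(g.codes, expected)
        assert list(g.population) == ["F1", "F1", "F2"]
        assert list(g.snp_ids) == ["s1", "s2"]

    def test_round_trip_preserves_codes_map_and_ids(self, tmp_path,
                                                    small_dataset):
        g = small_dataset[0]
        write_plink(g, tmp_path / "rt")
        back = read_plink(tmp_path / "rt")
        np.testing.assert_array_equal(back.codes, g.codes)
        np.testing.assert_array_equal(back.individual_ids, g.individual_ids)
        np.testing.assert_array_equal(back.chrom, g.chrom)
        np.testing.assert_array_equal(back.pos_bp, g.pos_bp)

    def test_round_trip_with_missing_genotypes(self, tmp_path):
        codes = np.array([[0, 1, np.nan], [2, np.nan, 1], [1, 1, 2.0]])
        g = _panel(codes)
        write_plink(g, tmp_path / "m")
        np.testing.assert_array_equal(read_plink(tmp_path / "m").codes, codes)

    def test_bad_magic_bytes_is_format_error(self, tmp_path):
        (tmp_path / "x.fam").write_text("F1 I1 0 0 0 -9\n")
        (tmp_path / "x.bim").write_text("1 s1 0 100 A G\n")
        (tmp_path / "x.bed").write_bytes(b"\x00\x00\x00\x00")
        with pytest.raises(PlinkFormatError):
            read_plink(tmp_path / "x")

    def test_truncated_bed_is_integrity_error(self, tmp_path):
        (tmp_path / "t.fam").write_text("F1 I1 0 0 0 -9\n")
        (tmp_path / "t.bim").write_text("1 s1 0 100 A G\n1 s2 0 200 A G\n")
        (tmp_path / "t.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0]))
        with pytest.raises(IntegrityError):
            read_plink(tmp_path / "t")

    def test_empty_fam_is_error(self, tmp_path):
        (tmp_path / "e.fam").write_text("")
        (tmp_path / "e.bim").write_text("1 s1 0 100 A G\n")
        (tmp_path / "e.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]))
        with pytest.raises(Exception):
            read_plink(tmp_path / "e")


class TestHWE:
    @pytest.mark.parametrize("counts, expected_p", [
        ((25, 50, 25), 1.0),            # exact HWE proportions, statistic 0
        ((10, 0, 0), 1.0),              # monomorphic convention
        ((0, 0, 7), 1.0),
    ])
    def test_null_and_degenerate_cases(self, counts, expected_p):
        assert hwe_chisq(*counts) == pytest.approx(expected_p)

    def test_extreme_departure(self):
        # expected counts 25/50/25 -> statistic sum((obs-exp)^2/exp) = 100
        p = hwe_chisq(50, 0, 50)
        assert p == pytest.approx(stats.chi2.sf(100.0, 1))
        assert p < 1e-6

    def test_matches_direct_chisq_formula(self):
        n0, n1, n2 = 30, 40, 30
        n = n0 + n1 + n2
        q = (2 * n2 + n1) / (2 * n)
        exp = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
        stat = (((np.array([n0, n1, n2]) - exp) ** 2) / exp).sum()
        assert stat == pytest.approx(4.0)
        assert hwe_chisq(n0, n1, n2) == pytest.approx(stats.chi2.sf(stat, 1))


class TestQC:
    def test_removes_low_maf_retains_hwe_consistent(self):
        rng = np.random.default_rng(0)
        common = rng.binomial(2, 0.5, size=(100, 1)).astype(float)
        # MAF 0.04: 8 het among 100 diploid individuals
        rare = np.zeros((100, 1))
        rare[:8] = 1.0
        hwe_ok = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2)])
        g = _panel(np.hstack([common, rare, hwe_ok[:, None]]))
        kept, report = qc_filter(g)
        assert list(kept.snp_ids) == ["s0", "s2"]
        assert report.n_maf == 1 and report.n_retained == 2

    def test_hwe_floor_applied_on_pooled_sample(self):
        bad = np.concatenate([np.zeros(50), np.full(50, 2.0)])  # p < 1e-6
        ok = np.concatenate([np.zeros(30), np.ones(40), np.full(30, 2.0)])
        g = _panel(np.column_stack([bad, ok]))
        kept, report = qc_filter(g)
        assert list(kept.snp_ids) == ["s1"]   # chi2=4, p=0.0455 retained
        assert report.n_hwe == 1

    def test_missing_rate_threshold(self):
        rng = np.random.default_rng(1)
        good = rng.binomial(2, 0.4, size=(200, 1)).astype(float)
        holey = good.copy()
        holey[:5, 0] = np.nan                  # 2.5% missing > 1%
        kept, report = qc_filter(_panel(np.hstack([good, holey])))
        assert list(kept.snp_ids) == ["s0"]
        assert report.n_missing_rate == 1

    def test_idempotent(self, small_dataset):
        g = small_dataset[0]
        once, _ = qc_filter(g, min_maf=0.1)
        twice, rep = qc_filter(once, min_maf=0.1)
        assert rep.n_retained == once.n_snps
        np.testing.assert_array_equal(once.codes, twice.codes)

    def test_all_removed_is_error(self):
        rare = np.zeros((50, 1))
        rare[0] = 1.0
        with pytest.raises(ValueError, match="empty panel"):
            qc_filter(_panel(rare))


class TestQuantileNormalize:
    def test_median_maps_to_zero_and_ranks_preserved(self):
        out = quantile_normalize(np.array([3.0, 1.0, 2.0]))
        assert out[2] == pytest.approx(0.0)
        assert list(np.argsort(out)) == [1, 2, 0]

    def test_n5_hits_textbook_quantiles(self):
        out = quantile_normalize(np.array([10.0, 20.0, 30.0, 40.0, 50.0]))
        np.testing.assert_allclose(
            out, stats.norm.ppf([0.1, 0.3, 0.5, 0.7, 0.9]), atol=1e-12)

    def test_large_normal_sample_nearly_unchanged(self):
        x = np.random.default_rng(2).standard_normal(10000)
        out = quantile_normalize(x)
        assert np.corrcoef(x, out)[0, 1] > 0.99

    def test_mean_zero_for_tie_free_input(self):
        x = np.random.default_rng(3).permutation(101).astype(float)
        assert abs(quantile_normalize(x).mean()) < 1e-8

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.full(5, 7.0))


class TestPhenotypeTable:
    def test_tsv_round_trip_with_missing(self, tmp_path):
        frame = pd.DataFrame({
            "iid": ["a", "b", "c"], "pop": ["P1", "P1", "P2"],
            "bw": [1.5, np.nan, -0.3]})
        write_phenotypes(PhenotypeTable(frame), tmp_path / "p.tsv")
        back = read_phenotypes(tmp_path / "p.tsv")
        assert back.traits == ["bw"]
        np.testing.assert_array_equal(
            back.values_for(["c", "a", "b"], "bw"), [-0.3, 1.5, np.nan])
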