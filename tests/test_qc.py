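"""QC filters, MAF computation and genotype file round trips."""

import numpy as np
import pytest

from hmolink import apply_qc, compute_maf, read_genotypes, write_dosage_tsv, write_vcf
from hmolink.io import MultiAllelicError
from hmolink.qc import EmptyResultError

from conftest import toy_matrix

VCF_BODY = """\
##fileformat=VCFv4.2
##contig=<ID=19>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
19\t100\trsX\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.
"""

MULTI_ALLELIC = """\
##fileformat=VCFv4.2
##contig=<ID=19>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
19\t100\trsM\tG\tA,C\t.\tPASS\t.\tGT\t0/1
"""


class TestReadGenotypes:
    def test_vcf_dosage_coding_and_missing(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(VCF_BODY)
        g = read_genotypes(p, "vcf")
        col = g.dosages["rsX"]
        assert list(col[:3]) == [0.0, 1.0, 2.0]
        assert np.isnan(col.iloc[3])

    def test_multiallelic_rejected(self, tmp_path):
        p = tmp_path / "multi.vcf"
        p.write_text(MULTI_ALLELIC)
        with pytest.raises(MultiAllelicError, match="rsM"):
            read_genotypes(p, "vcf")

    def test_major_alt_is_flipped_to_minor(self, tmp_path):
        # ALT at frequency 0.75 -> dosages must count REF (the minor allele)
        body = VCF_BODY.replace("0/0\t0/1\t1/1\t./.", "1/1\t1/1\t0/1\t0/0")
        p = tmp_path / "flip.vcf"
        p.write_text(body)
        g = read_genotypes(p, "vcf")
        assert list(g.dosages["rsX"]) == [0.0, 0.0, 1.0, 2.0]
        assert compute_maf(g, "rsX") <= 0.5

    def test_vcf_round_trip(self, tmp_path, fixture_cohort):
        # the full cohort keeps every ALT at minor frequency, so dosages
        # survive the write -> read minor-allele re-orientation unchanged
        full = fixture_cohort.genotypes
        p = tmp_path / "rt.vcf"
        write_vcf(full, p, seed=1)
        back = read_genotypes(p, "vcf", variants=full.variants)
        assert back.dosages.shape == full.dosages.shape
        assert np.allclose(
            back.dosages[full.rsids].to_numpy(), full.dosages.to_numpy(),
            equal_nan=True,
        )

    def test_dosage_tsv_round_trip(self, tmp_path, fixture_cohort):
        p = tmp_path / "rt.tsv"
        write_dosage_tsv(fixture_cohort.genotypes, p, seed=1)
        back = read_genotypes(p, "dosage-tsv")
        assert np.allclose(
            back.dosages.to_numpy(),
            fixture_cohort.genotypes.dosages.to_numpy(),
            equal_nan=True,
        )


class TestComputeMaf:
    def test_fixture_rs601338(self, fixture_cohort):
        assert compute_maf(fixture_cohort.genotypes, "rs601338") == pytest.approx(
            108 / 304
        )

    def test_all_major_is_zero(self):
        m = toy_matrix({"rs1": [0, 0, 0, 0]})
        assert compute_maf(m, "rs1") == 0.0

    def test_missing_excluded_from_denominator(self):
        # 10 samples, 1 missing, 2 heterozygous among the 9 observed -> 2/18
        m = toy_matrix({"rs1": [1, 1, 0, 0, 0, 0, 0, 0, 0, None]})
        assert compute_maf(m, "rs1") == pytest.approx(2 / 18)

    def test_all_missing_raises(self):
        m = toy_matrix({"rs1": [None, None]})
        with pytest.raises(ValueError, match="missing"):
            compute_maf(m, "rs1")

    def test_matches_allele_counting_oracle(self, rng):
        for _ in range(30):
            n, p = rng.integers(2, 11), rng.integers(1, 11)
            vals = rng.choice([0.0, 1.0, 2.0, np.nan], size=(n, p),
                              p=[0.5, 0.3, 0.15, 0.05])
            if np.isnan(vals).all(axis=0).any():
                continue
            m = toy_matrix({f"rs{j}": vals[:, j] for j in range(p)})
            for j in range(p):
                col = vals[:, j]
                obs = col[~np.isnan(col)]
                if obs.size == 0:
                    continue
                f = obs.sum() / (2 * obs.size)
                assert compute_maf(m, f"rs{j}") == pytest.approx(min(f, 1 - f))


class TestApplyQC:
    def test_clean_matrix_untouched(self):
        m = toy_matrix({f"rs{j}": [0, 1, 2, 1, 0] for j in range(3)})
        out, rep = apply_qc(m)
        assert out.dosages.shape == m.dosages.shape
        assert rep.samples_removed == []
        assert rep.n_variants_out == 3

    def test_sample_missingness_filter(self):
        cols = {f"rs{j}": [1.0] * 20 for j in range(5)}
        # one sample missing 2 of 5 variants (40% > 5%)
        for j in (0, 1):
            cols[f"rs{j}"] = [None] + [1.0] * 19
        m = toy_matrix(cols)
        out, rep = apply_qc(m)
        assert rep.samples_removed == ["T0"]
        assert out.n_samples == 19

    def test_maf_filter(self):
        base = {f"rs{j}": [0, 1] * 50 for j in range(2)}
        base["rs_rare"] = [1.0] + [0.0] * 99  # MAF 0.005 < 0.01
        m = toy_matrix(base)
        out, rep = apply_qc(m)
        assert rep.variants_removed_maf == ["rs_rare"]
        assert "rs_rare" not in out.rsids

    def test_boundary_missingness_retained(self):
        # exactly 5% missing is kept ("more than" is strict)
        cols = {f"rs{j}": [1.0] * 20 for j in range(20)}
        cols["rs0"] = [None] + [1.0] * 19  # sample T0: 1/20 = 5%
        m = toy_matrix(cols)
        out, _ = apply_qc(m)
        assert "T0" in out.sample_ids

    def test_idempotent(self, fixture_cohort):
        once, _ = apply_qc(fixture_cohort.genotypes)
        twice, rep2 = apply_qc(once)
        assert once.dosages.equals(twice.dosages)
        assert not rep2.samples_removed
        assert not rep2.variants_removed_maf

    def test_empty_result_error(self):
        m = toy_matrix({"rs1": [1.0, None], "rs2": [None, 1.0]})
        with pytest.raises(EmptyResultError):
            apply_qc(m)

    def test_report_counts_consistent(self):
        # 40 clean variants keep per-sample missingness at 1/41 (< 5%)
        # while rs_bad is missing in 20% of samples (> 5%)
        cols = {f"rs{j}": [0, 1, 2, 1] * 5 for j in range(40)}
        cols["rs_bad"] = [None] * 4 + [0.0] * 16
        m = toy_matrix(cols)
        out, rep = apply_qc(m)
        assert rep.n_variants_in == 41
        assert rep.samples_removed == []
        assert rep.variants_removed_missingness == ["rs_bad"]
        assert rep.n_variants_out == out.n_variants
        assert rep.n_samples_out == out.n_samples
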