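import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hwe_enumeration_p
from prsphewas.genio import (
    GenioError,
    GenotypeMatrix,
    QCThresholds,
    VariantRecord,
    WeightSet,
    harmonize_weights,
    hwe_exact_test,
    qc_filter,
    read_gene_models,
    read_genotypes,
    read_gmt,
    write_genotypes_tsv,
    write_gmt,
)

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=R2,Number=1,Type=Float,Description="quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="dosage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, lines, samples=("s1",)):
    path.write_text(VCF_HEADER.format(samples="\t".join(samples)) + "".join(l + "\n" for l in lines))
    return path


class TestVariantRecord:
    def test_rejects_identical_alleles(self):
        with pytest.raises(GenioError):
            VariantRecord("v", "1", 10, "A", "A")

    def test_rejects_nonpositive_pos(self):
        with pytest.raises(GenioError):
            VariantRecord("v", "1", 0, "A", "G")

    def test_ambiguous_detection(self):
        assert VariantRecord("v", "1", 1, "A", "T").is_ambiguous
        assert VariantRecord("v", "1", 1, "C", "G").is_ambiguous
        assert not VariantRecord("v", "1", 1, "A", "G").is_ambiguous
        # indels: strand logic disabled
        assert not VariantRecord("v", "1", 1, "AT", "A").is_snp


class TestReadVcf:
    def test_ds_field_copied(self, tmp_path):
        p = write_vcf(tmp_path / "a.vcf", ["1\t100\trs1\tA\tG\t.\t.\tR2=0.9\tGT:DS\t0/1:1.0"])
        g = read_genotypes(p, "vcf")
        assert g.n_samples == 1 and g.n_variants == 1
        assert g.dosages[0, 0] == 1.0
        v = g.variants[0]
        assert (v.chrom, v.pos, v.allele_a1, v.allele_a2) == ("1", 100, "G", "A")
        assert v.info_r2 == pytest.approx(0.9)

    def test_hard_genotypes_when_no_ds(self, tmp_path):
        p = write_vcf(
            tmp_path / "a.vcf",
            ["1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t./."],
            samples=("s1", "s2", "s3", "s4"),
        )
        g = read_genotypes(p, "vcf")
        row = g.dosages[:, 0]
        assert list(row[:3]) == [0.0, 1.0, 2.0]
        assert np.isnan(row[3])

    def test_multiallelic_rejected(self, tmp_path):
        p = write_vcf(tmp_path / "a.vcf", ["1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/1"])
        with pytest.raises(GenioError, match="bi-allelic"):
            read_genotypes(p, "vcf")

    def test_duplicate_id_rejected(self, tmp_path):
        p = write_vcf(
            tmp_path / "a.vcf",
            [
                "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1",
                "1\t200\trs1\tC\tT\t.\t.\t.\tGT\t0/1",
            ],
        )
        with pytest.raises(GenioError, match="duplicate"):
            read_genotypes(p, "vcf")


class TestDosageTsv:
    def test_na_is_missing_not_zero(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("sample_id\tv1\tv2\ns1\tNA\t1.5\n")
        g = read_genotypes(p, "tsv")
        assert np.isnan(g.dosages[0, 0])
        assert g.dosages[0, 1] == 1.5

    def test_round_trip_bit_exact(self, tmp_path, tiny_genotypes):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_genotypes_tsv(tiny_genotypes, p1)
        g2 = read_genotypes(p1, "tsv")
        write_genotypes_tsv(g2, p2)
        assert p1.read_text() == p2.read_text()
        m1, m2 = tiny_genotypes.dosages, g2.dosages
        assert np.array_equal(np.isnan(m1), np.isnan(m2))
        assert np.array_equal(m1[~np.isnan(m1)], m2[~np.isnan(m2)])

    def test_sidecar_metadata(self, tmp_path, tiny_genotypes):
        write_genotypes_tsv(tiny_genotypes, tmp_path / "d.tsv", tmp_path / "v.tsv")
        g = read_genotypes(tmp_path / "d.tsv", "tsv", variants_path=tmp_path / "v.tsv")
        assert [v.pos for v in g.variants] == [100, 200, 300]

    def test_duplicate_header_ids(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("sample_id\tv1\tv1\ns1\t0\t1\n")
        with pytest.raises(GenioError, match="duplicate"):
            read_genotypes(p, "tsv")


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_two_sample_enumeration(self):
        # oracle-computed: tables with 2 minor alleles in 2 diploids are
        # het=0 (prob 1/3) and het=2 (prob 2/3); observed het=0 -> p=1/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1.0 / 3.0)
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)

    def test_negative_counts_error(self):
        with pytest.raises(GenioError):
            hwe_exact_test(-1, 0, 1)
        with pytest.raises(GenioError):
            hwe_exact_test(0, 0, 0)

    @given(
        st.tuples(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)).filter(
            lambda t: sum(t) >= 1
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, counts):
        a, h, b = counts
        assert hwe_exact_test(a, h, b) == pytest.approx(float(hwe_enumeration_p(a, h, b)), abs=1e-12)

    def test_symmetric_in_homozygote_labels(self):
        assert hwe_exact_test(12, 7, 3) == pytest.approx(hwe_exact_test(3, 7, 12))


class TestQcFilter:
    def make(self, dosage_cols, info=None):
        variants = [
            VariantRecord(f"v{j}", "1", 10 * (j + 1), "A", "G", info_r2=None if info is None else info[j])
            for j in range(len(dosage_cols))
        ]
        d = np.column_stack(dosage_cols).astype(float)
        return GenotypeMatrix([f"s{i}" for i in range(d.shape[0])], variants, d)

    def test_low_maf_removed(self, rng):
        n = 400
        common = rng.binomial(2, 0.3, n).astype(float)
        rare = np.zeros(n)
        rare[:4] = 1.0  # MAF 0.005
        g = self.make([common, rare])
        kept, report = qc_filter(g, QCThresholds())
        assert kept.variant_ids() == ["v0"]
        assert report.loc[report["variant_id"] == "v1", "failed_rules"].iloc[0] == "maf"

    def test_clean_variant_retained(self):
        col = np.array([0, 1, 2, 1, 0, 1, 2, 1, 1, 0] * 5, dtype=float)
        g = self.make([col])
        kept, report = qc_filter(g, QCThresholds())
        assert kept.n_variants == 1
        assert report["retained"].all()

    def test_report_partitions_input(self, rng):
        cols = [rng.binomial(2, p, 200).astype(float) for p in (0.004, 0.3, 0.45)]
        g = self.make(cols)
        kept, report = qc_filter(g, QCThresholds())
        assert len(report) == g.n_variants
        assert int(report["retained"].sum()) + int((~report["retained"]).sum()) == g.n_variants
        assert kept.n_variants == int(report["retained"].sum())

    def test_info_r2_rule(self, rng):
        col = rng.binomial(2, 0.3, 200).astype(float)
        g = self.make([col, col.copy()], info=[0.9, 0.2])
        g.variants[1] = VariantRecord("v1", "1", 20, "A", "G", info_r2=0.2)
        kept, report = qc_filter(g, QCThresholds())
        assert kept.variant_ids() == ["v0"]
        assert "info_r2" in report.loc[1, "failed_rules"]

    def test_missingness_rule(self, rng):
        col = rng.binomial(2, 0.3, 100).astype(float)
        holey = col.copy()
        holey[:10] = np.nan  # 10% missing
        g = self.make([col, holey])
        kept, _ = qc_filter(g, QCThresholds())
        assert kept.variant_ids() == ["v0"]

    def test_all_removed_is_error(self):
        g = self.make([np.zeros(50)])
        with pytest.raises(GenioError, match="empty after QC"):
            qc_filter(g, QCThresholds())

    def test_idempotent(self, rng):
        cols = [rng.binomial(2, p, 300).astype(float) for p in rng.uniform(0.005, 0.5, 12)]
        g = self.make(cols)
        kept, _ = qc_filter(g, QCThresholds())
        kept2, report2 = qc_filter(kept, QCThresholds())
        assert kept2.variant_ids() == kept.variant_ids()
        assert report2["retained"].all()


class TestHarmonizeWeights:
    def variants(self):
        return [
            VariantRecord("g1", "1", 100, "A", "G"),
            VariantRecord("g2", "1", 200, "C", "A"),
            VariantRecord("g3", "1", 300, "A", "T"),
        ]

    def ws(self, rows):
        return WeightSet(
            "w",
            pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight"]),
        )

    def test_swap_negates(self):
        w = self.ws([("x1", "1", 100, "G", "A", 0.3)])
        h, log = harmonize_weights(w, self.variants())
        assert h.entries["weight"].iloc[0] == -0.3
        assert h.entries["effect_allele"].iloc[0] == "A"
        assert log["status"].iloc[0] == "swapped"

    def test_strand_flip(self):
        w = self.ws([("x2", "1", 200, "G", "T", 0.7)])
        h, log = harmonize_weights(w, self.variants(), allow_strand_flip=True)
        assert h.entries["weight"].iloc[0] == 0.7
        assert log["status"].iloc[0] == "strand_flipped"

    def test_strand_flip_disabled(self):
        w = self.ws([("x2", "1", 200, "G", "T", 0.7), ("x1", "1", 100, "A", "G", 0.1)])
        h, log = harmonize_weights(w, self.variants(), allow_strand_flip=False)
        assert dict(zip(log["variant_id"], log["status"]))["x2"] == "allele_mismatch"
        assert h.variant_ids() == ["g1"]

    def test_ambiguous_dropped(self):
        w = self.ws([("x3", "1", 300, "A", "T", 0.5), ("x1", "1", 100, "A", "G", 0.1)])
        h, log = harmonize_weights(w, self.variants(), drop_ambiguous=True)
        assert "g3" not in h.variant_ids()
        assert dict(zip(log["variant_id"], log["status"]))["x3"] == "ambiguous"

    def test_ambiguous_kept_when_allowed(self):
        w = self.ws([("x3", "1", 300, "A", "T", 0.5)])
        h, _ = harmonize_weights(w, self.variants(), drop_ambiguous=False)
        assert h.variant_ids() == ["g3"]

    def test_unmatched_logged_and_zero_match_errors(self):
        w = self.ws([("x9", "9", 999, "A", "G", 0.5)])
        with pytest.raises(GenioError, match="zero variants matched"):
            harmonize_weights(w, self.variants())


class TestGeneModelsAndGmt:
    def test_bed_coordinate_conversion(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t99\t200\tgeneX\n")
        genes = read_gene_models(p, "bed")
        assert (genes[0].start, genes[0].end) == (100, 200)

    def test_gff3_read(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n1\tsrc\tgene\t150\t900\t.\t+\t.\tID=geneA\n")
        genes = read_gene_models(p, "gff3")
        assert genes[0].gene_id == "geneA"
        assert (genes[0].chrom, genes[0].start, genes[0].end) == ("1", 150, 900)

    def test_bed_end_before_start_error(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t500\t400\tgeneX\n")
        with pytest.raises(GenioError):
            read_gene_models(p, "bed")

    def test_gmt_dedup_and_empty(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("pwA\tdesc\tg1\tg2\tg1\npwEmpty\tdesc\n")
        db = read_gmt(p)
        assert db["pwA"] == {"g1", "g2"}
        assert db["pwEmpty"] == set()

    def test_gmt_round_trip(self, tmp_path):
        db = {"pw1": {"g1", "g2"}, "pw2": {"g3"}}
        write_gmt(db, tmp_path / "p.gmt")
        assert read_gmt(tmp_path / "p.gmt") == db
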