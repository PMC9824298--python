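"""Data model, CSV/VCF round-trips, and allele-frequency estimation."""

import numpy as np
import pytest

from conftest import matrix_from_calls
from teacore.genotypes import (
    GenotypeError,
    GenotypeMatrix,
    LocusInfo,
    allele_frequencies,
    read_genotype_csv,
    read_vcf,
    write_fingerprint_table,
    write_genotype_csv,
    write_vcf,
)
from teacore.simulate import PanelSimConfig, simulate_panel


class TestLocusInfo:
    def test_invariants_enforced(self):
        with pytest.raises(GenotypeError):
            LocusInfo("L1", pos=0)
        with pytest.raises(GenotypeError):
            LocusInfo("L1", allele_a="A", allele_b="A")
        with pytest.raises(GenotypeError):
            LocusInfo("L1", flank_up="ACGT")  # not 35 nt
        with pytest.raises(GenotypeError):
            LocusInfo("L1", flank_up="X" * 35)  # bad alphabet
        ok = LocusInfo("L1", chrom="chr1", pos=5, allele_a="A", allele_b="T",
                       flank_up="A" * 35, flank_down="N" * 35)
        assert ok.pos == 5

    def test_duplicate_ids_rejected(self):
        with pytest.raises(GenotypeError, match="duplicate locus"):
            GenotypeMatrix(
                ["s1"], [LocusInfo("L1"), LocusInfo("L1")],
                np.zeros((1, 2), dtype=np.int8),
            )
        with pytest.raises(GenotypeError, match="duplicate sample"):
            GenotypeMatrix(
                ["s1", "s1"], [LocusInfo("L1")], np.zeros((2, 1), dtype=np.int8)
            )


class TestCsv:
    def test_direct_echo(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("sample,L1\na,1/1\nb,1/2\n")
        g = read_genotype_csv(f)
        assert g.to_frame().values.tolist() == [["1/1"], ["1/2"]]

    def test_na_is_missing_and_excluded_from_n_typed(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("sample,L1\na,NA\nb,1/2\nc,1/1\n")
        fr = allele_frequencies(read_genotype_csv(f))
        assert fr.n_typed[0] == 2

    def test_reversed_het_normalised(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("sample,L1\na,2/1\n")
        assert read_genotype_csv(f).to_frame().iloc[0, 0] == "1/2"

    def test_duplicate_header_rejected(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("sample,L1,L1\na,1/1,1/1\n")
        with pytest.raises(GenotypeError, match="duplicate"):
            read_genotype_csv(f)

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("sample,L1\na,1/1\nb,1/3\n")
        with pytest.raises(GenotypeError, match="'b'.*'L1'"):
            read_genotype_csv(f)

    def test_round_trip_preserves_all_calls(self, tmp_path):
        cfg = PanelSimConfig(n_samples=12, n_loci=8, missing_rate=0.2, seed=5)
        g, _ = simulate_panel(cfg)
        path = tmp_path / "rt.csv"
        write_genotype_csv(g, path)
        g2 = read_genotype_csv(path)
        assert np.array_equal(g.codes, g2.codes)
        assert g2.samples == g.samples and g2.locus_ids == g.locus_ids


class TestVcf:
    def test_round_trip_preserves_all_calls(self, tmp_path):
        g, _ = simulate_panel(PanelSimConfig(n_samples=10, n_loci=9, missing_rate=0.15, seed=2))
        path = tmp_path / "rt.vcf"
        write_vcf(g, path)
        g2 = read_vcf(path)
        # VCF is coordinate-sorted; align by locus id before comparing
        g2 = g2.subset(loci=g.locus_ids)
        assert np.array_equal(g.codes, g2.codes)
        assert [l.allele_a for l in g2.loci] == [l.allele_a for l in g.loci]

    def _write(self, tmp_path, body):
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        )
        f = tmp_path / "t.vcf"
        f.write_text(header + body)
        return f

    def test_gt_mapping_and_phase_discarded(self, tmp_path):
        f = self._write(
            tmp_path,
            "chr1\t10\tv1\tA\tT\t.\t.\t.\tGT\t0/1\t0|1\n"
            "chr1\t20\tv2\tG\tC\t.\t.\t.\tGT\t1/1\t./.\n",
        )
        g = read_vcf(f)
        assert g.to_frame().loc["s1"].tolist() == ["1/2", "2/2"]
        assert g.to_frame().loc["s2"].tolist() == ["1/2", "NA"]
        assert g.loci[0].pos == 10  # 1-based preserved

    def test_multiallelic_rejected_or_skipped(self, tmp_path):
        f = self._write(
            tmp_path,
            "chr1\t10\tv1\tA\tT,C\t.\t.\t.\tGT\t0/1\t0/0\n"
            "chr1\t20\tv2\tG\tC\t.\t.\t.\tGT\t0/0\t1/1\n",
        )
        g = read_vcf(f, on_invalid="skip")
        assert g.locus_ids == ["v2"]
        with pytest.raises(GenotypeError, match="not a biallelic SNP"):
            read_vcf(f, on_invalid="raise")

    def test_indel_skipped(self, tmp_path):
        f = self._write(
            tmp_path,
            "chr1\t10\tv1\tAT\tA\t.\t.\t.\tGT\t0/1\t0/0\n"
            "chr1\t20\tv2\tG\tC\t.\t.\t.\tGT\t0/0\t1/1\n",
        )
        assert read_vcf(f).locus_ids == ["v2"]

    def test_haploid_gt_is_error(self, tmp_path):
        f = self._write(tmp_path, "chr1\t10\tv1\tA\tT\t.\t.\t.\tGT\t0\t0/0\n")
        with pytest.raises(GenotypeError, match="non-diploid"):
            read_vcf(f)


class TestAlleleFrequencies:
    def test_symmetric_counts(self):
        g = matrix_from_calls({"a": ["1/1"], "b": ["1/2"], "c": ["2/2"]})
        assert allele_frequencies(g).p[0] == pytest.approx(0.5)

    def test_monomorphic(self):
        g = matrix_from_calls({"a": ["1/1"], "b": ["1/1"]})
        fr = allele_frequencies(g)
        assert fr.p[0] == 1.0 and fr.maf[0] == 0.0

    def test_hand_counted_117_sample_panel(self):
        # 24 of 234 allele draws are allele b: 93 homozygous a/a + 24 het
        rows = {f"s{i}": ["1/1"] for i in range(93)}
        rows.update({f"h{i}": ["1/2"] for i in range(24)})
        fr = allele_frequencies(matrix_from_calls(rows))
        assert fr.p[0] == pytest.approx(210 / 234)
        assert fr.maf[0] == pytest.approx(24 / 234, abs=5e-4)

    def test_all_missing_locus_is_error(self):
        g = matrix_from_calls({"a": ["NA", "1/1"], "b": ["NA", "1/2"]})
        with pytest.raises(GenotypeError, match="L1"):
            allele_frequencies(g)

    def test_invariant_under_sample_order(self):
        g, _ = simulate_panel(PanelSimConfig(n_samples=20, n_loci=5, seed=3))
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(g.samples))
        assert np.allclose(
            allele_frequencies(g).p, allele_frequencies(g.subset(samples=perm)).p
        )

    def test_allele_swap_maps_p_to_q(self):
        g, _ = simulate_panel(PanelSimConfig(n_samples=30, n_loci=4, seed=9))
        swapped = GenotypeMatrix(
            g.samples, g.loci, np.where(g.codes >= 0, 2 - g.codes, g.codes)
        )
        f1, f2 = allele_frequencies(g), allele_frequencies(swapped)
        assert np.allclose(f1.p, f2.q)
        assert np.allclose(f1.maf, f2.maf)


class TestFingerprintTable:
    def test_shape_order_and_round_trip(self, tmp_path):
        g, _ = simulate_panel(PanelSimConfig(n_samples=3, n_loci=5, seed=4))
        panel = [g.locus_ids[3], g.locus_ids[1]]
        path = tmp_path / "fp.csv"
        write_fingerprint_table(g, panel, path)
        back = read_genotype_csv(path)
        assert back.locus_ids == panel  # panel ordering preserved
        assert back == g.subset(loci=panel)

    def test_unknown_locus_is_lookup_error(self, tiny_matrix, tmp_path):
        with pytest.raises(GenotypeError, match="unknown locus"):
            write_fingerprint_table(tiny_matrix, ["nope"], tmp_path / "x.csv")
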