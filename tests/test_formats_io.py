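"""Round-trip and validation behaviour of the readers/writers."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from strainprior import formats_io
from strainprior.formats_io import (
    FunctionalAnnotation,
    GeneModel,
    IntervalFeature,
    PanelMatrix,
    VariantRecord,
    normalize_genotype,
)

from conftest import make_indel, make_snv


class TestGenotypeNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [("0/1", "0/1"), ("1/0", "0/1"), ("0|1", "0/1"), ("2/1", "1/2"),
         ("./.", "./."), ("./1", "./."), ("1|1", "1/1")],
    )
    def test_normalization(self, raw, expected):
        assert normalize_genotype(raw) == expected

    def test_haploid_code_rejected(self):
        with pytest.raises(ValueError):
            normalize_genotype("1")


class TestVariantRecord:
    def test_position_must_be_positive(self):
        with pytest.raises(ValueError):
            make_snv(pos=0)

    def test_genotype_indexing_missing_allele_rejected(self):
        with pytest.raises(ValueError, match="missing allele"):
            make_snv(alt="G", case="1/2")

    @pytest.mark.parametrize(
        "ref, alts, expected",
        [("A", ["G"], "SNV"), ("A", ["AT"], "insertion"), ("AT", ["A"], "deletion"),
         ("A", ["G", "C"], "SNV")],
    )
    def test_variant_class(self, ref, alts, expected):
        r = VariantRecord("chr1", 5, ref, alts, {"S": "0/1"})
        assert r.variant_class == expected

    def test_alt_indices_multiallelic(self):
        r = make_snv(alt=["G", "C"], case="1/2")
        assert r.alt_indices_of("GK_SLAC") == (1, 2)
        assert r.is_homozygous_variant("GK_SLAC") is False


class TestVCFRoundTrip:
    def test_round_trip_preserves_model_fields(self, tmp_path):
        records = [
            make_snv(pos=100, case="0/1", control="0/0"),
            make_snv(pos=200, alt=["G", "C"], case="1/2", control="0/1"),
            make_snv(pos=300, case="./.", control="1/1"),
            make_indel(pos=400),
        ]
        path = tmp_path / "x.vcf"
        formats_io.write_vcf(records, path, samples=["GK_SLAC", "WISTAR_SLAC"],
                             contigs={"chr1": 10_000})
        back = formats_io.read_vcf(path)
        assert len(back) == len(records)
        for orig, rt in zip(records, back):
            assert rt.site == orig.site
            assert rt.ref_allele == orig.ref_allele
            assert rt.alt_alleles == orig.alt_alleles
            assert rt.genotypes == orig.genotypes
            assert rt.site_qc == orig.site_qc

    def test_phased_genotypes_normalized_on_read(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "chr1\t10\t.\tA\tG\t.\t.\t.\tGT\t0|1\t./.\n"
        )
        path = tmp_path / "phased.vcf"
        path.write_text(text)
        (record,) = formats_io.read_vcf(path)
        assert record.genotypes == {"A": "0/1", "B": "./."}

    def test_malformed_header_fatal(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(ValueError, match="cannot parse"):
            formats_io.read_vcf(path)


class TestPanel:
    def _write(self, tmp_path, body, groups="strain\tgroup\nS1\tcase_consistent\n"):
        panel = tmp_path / "panel.tsv"
        panel.write_text(body)
        sidecar = tmp_path / "groups.tsv"
        sidecar.write_text(groups)
        return panel, sidecar

    def test_three_strains_two_sites(self, tmp_path):
        panel, sidecar = self._write(
            tmp_path,
            "chromosome\tposition\tS1\tS2\tS3\n"
            "chr1\t10\t0/0\t0/1\t1/1\n"
            "chr1\t20\t1/1\t./.\t0/0\n",
        )
        matrix = formats_io.read_panel(panel, sidecar)
        assert matrix.genotypes.size == 6
        assert matrix.genotype("chr1", 20, "S2") == "./."
        assert matrix.case_consistent_strains == ["S1"]

    def test_duplicate_site_rows_fatal(self, tmp_path):
        panel, sidecar = self._write(
            tmp_path,
            "chromosome\tposition\tS1\n"
            "chr1\t10\t0/0\nchr1\t10\t1/1\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            formats_io.read_panel(panel, sidecar)

    def test_unknown_genotype_code_rejected(self, tmp_path):
        panel, sidecar = self._write(
            tmp_path, "chromosome\tposition\tS1\nchr1\t10\t3/3\n"
        )
        with pytest.raises(ValueError, match="unknown genotype"):
            formats_io.read_panel(panel, sidecar)

    def test_empty_panel_reads_as_empty_matrix(self, tmp_path):
        panel, sidecar = self._write(tmp_path, "chromosome\tposition\tS1\n")
        matrix = formats_io.read_panel(panel, sidecar)
        assert matrix.n_sites == 0


class TestNewick:
    def test_single_leaf(self, tmp_path):
        path = formats_io.write_newick(TreeNode(name="A"), tmp_path / "t.nwk")
        assert path.read_text().strip() == "A;"

    def test_two_leaves_with_heights(self, tmp_path):
        a, b = TreeNode(name="A", length=1.0), TreeNode(name="B", length=1.0)
        tree = TreeNode(children=[a, b])
        path = formats_io.write_newick(tree, tmp_path / "t.nwk")
        back = formats_io.read_newick(path)
        assert sorted(t.name for t in back.tips()) == ["A", "B"]
        assert all(abs(t.length - 1.0) < 1e-9 for t in back.tips())

    def test_duplicate_leaf_labels_fatal(self, tmp_path):
        tree = TreeNode(children=[TreeNode(name="A"), TreeNode(name="A")])
        with pytest.raises(ValueError, match="duplicate"):
            formats_io.write_newick(tree, tmp_path / "t.nwk")

    def test_round_trip_preserves_topology_and_heights(self, tmp_path):
        tree = TreeNode.read(io.StringIO("((A:1.5,B:1.5):0.25,(C:1,D:1):0.75);"))
        path = formats_io.write_newick(tree, tmp_path / "t.nwk")
        back = formats_io.read_newick(path)
        assert back.compare_rfd(tree) == 0.0
        orig = {t.name: tree.find(t.name).accumulate_to_ancestor(tree)
                for t in tree.tips()}
        rt = {t.name: back.find(t.name).accumulate_to_ancestor(back)
              for t in back.tips()}
        assert all(abs(orig[k] - rt[k]) < 1e-9 for k in orig)


class TestTabularRoundTrips:
    def test_genes_bed(self, tmp_path):
        genes = [GeneModel("G1", "chr1", 100, 500, False),
                 GeneModel("Olr1", "chr2", 0, 50, True)]
        path = formats_io.write_genes_bed(genes, tmp_path / "g.bed")
        back = formats_io.read_genes_bed(path)
        assert {g.gene_id: g.is_olfactory_receptor for g in back} == {
            "G1": False, "Olr1": True}

    def test_gene_model_requires_positive_span(self):
        with pytest.raises(ValueError):
            GeneModel("G", "chr1", 10, 10)

    def test_features(self, tmp_path):
        features = [
            IntervalFeature("chr1", 0, 100, "SV-deletion"),
            IntervalFeature("chr1", 50, 80, "CNV-gain", ratio=2.5, p_value=1e-5),
        ]
        path = formats_io.write_features(features, tmp_path / "f.tsv")
        back = formats_io.read_features(path)
        assert back[0].ratio is None and back[0].feature_kind == "SV-deletion"
        assert back[1].p_value == pytest.approx(1e-5)
        assert back[1].ratio == pytest.approx(2.5)

    def test_feature_validation(self):
        with pytest.raises(ValueError):
            IntervalFeature("chr1", 5, 5, "SV-deletion")
        with pytest.raises(ValueError, match="kind"):
            IntervalFeature("chr1", 0, 5, "whatever")
        with pytest.raises(ValueError, match="ratio"):
            IntervalFeature("chr1", 0, 5, "CNV-gain", ratio=0.0)

    def test_annotations(self, tmp_path):
        ann = {("chr1", 10): FunctionalAnnotation(
            "chr1", 10, "G1", "exonic", "nonsynonymous", "deleterious")}
        path = formats_io.write_annotations(ann, tmp_path / "a.tsv")
        back = formats_io.read_annotations(path)
        assert back[("chr1", 10)].exonic_effect == "nonsynonymous"

    def test_annotation_vocabulary_enforced(self):
        with pytest.raises(ValueError):
            FunctionalAnnotation("chr1", 1, "G", "weird")
        with pytest.raises(ValueError):
            FunctionalAnnotation("chr1", 1, "G", "intronic",
                                 exonic_effect="nonsynonymous")

    def test_truth_panel(self, tmp_path):
        variant = {("chr1", 10), ("chr2", 5)}
        invariant = {("chr1", 99)}
        path = formats_io.write_truth_panel(variant, invariant, tmp_path / "t.tsv")
        v, i = formats_io.read_truth_panel(path)
        assert (v, i) == (variant, invariant)
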