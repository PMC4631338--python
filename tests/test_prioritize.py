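"""PAV flagging, panel consistency filter, OR exclusion, interval overlap."""

import numpy as np
import pandas as pd
import pytest

from strainprior import prioritize
from strainprior.formats_io import (
    FunctionalAnnotation,
    GeneModel,
    IntervalFeature,
    PanelMatrix,
)

from conftest import make_snv


def annotation(region, effect="."):
    return FunctionalAnnotation("chr1", 1, "G1", region, exonic_effect=effect)


class TestFlagPAV:
    @pytest.mark.parametrize(
        "region, effect, is_pav, reason",
        [("exonic", "nonsynonymous", True, "nonsynonymous"),
         ("exonic", "stopgain", True, "stopgain"),
         ("exonic", "stoploss", True, "stoploss"),
         ("exonic", "frameshift_insertion", True, "frameshift_insertion"),
         ("exonic", "frameshift_deletion", True, "frameshift_deletion"),
         ("exonic", "synonymous", False, None),
         ("splicing", ".", True, "splicing"),
         ("ncRNA_exonic", ".", True, "ncRNA_exonic"),
         ("UTR", ".", False, None),
         ("intronic", ".", False, None),
         ("upstream", ".", False, None),
         ("downstream", ".", False, None),
         ("intergenic", ".", False, None)],
    )
    def test_vocabulary_fully_partitioned(self, region, effect, is_pav, reason):
        flag = prioritize.flag_pav(annotation(region, effect))
        assert (flag.is_pav, flag.pav_reason) == (is_pav, reason)

    def test_unknown_class_raises_not_silent(self):
        bad = annotation("exonic", "nonsynonymous")
        bad.exonic_effect = "weird"  # bypass constructor validation
        with pytest.raises(ValueError):
            prioritize.flag_pav(bad)


def build_panel(rows, groups):
    """rows: {(chrom,pos): {strain: gt}}"""
    strains = sorted({s for r in rows.values() for s in r})
    index = pd.MultiIndex.from_tuples(sorted(rows),
                                      names=["chromosome", "position"])
    data = {s: [rows[site].get(s, "./.") for site in sorted(rows)]
            for s in strains}
    return PanelMatrix(genotypes=pd.DataFrame(data, index=index), groups=groups)


GROUPS = {"GK_OX": "case_consistent", "WKY_NCrl": "control_background",
          "SHR_NHsd": "control_background"}


class TestPanelFilter:
    def test_consistent_homozygote_retained(self):
        pav = make_snv(pos=100)
        panel = build_panel(
            {("chr1", 100): {"GK_OX": "1/1", "WKY_NCrl": "0/0",
                             "SHR_NHsd": "0/0"}}, GROUPS)
        result = prioritize.panel_filter([pav], panel, "GK_SLAC")
        assert result.survivors == [pav]

    def test_heterozygous_case_consistent_strain_drops(self):
        pav = make_snv(pos=100)
        panel = build_panel(
            {("chr1", 100): {"GK_OX": "0/1", "WKY_NCrl": "0/0",
                             "SHR_NHsd": "0/0"}}, GROUPS)
        result = prioritize.panel_filter([pav], panel, "GK_SLAC")
        assert result.survivors == []
        assert result.n_dropped_case_inconsistent == 1

    def test_background_homozygote_drops(self):
        pav = make_snv(pos=100)
        panel = build_panel(
            {("chr1", 100): {"GK_OX": "1/1", "WKY_NCrl": "1/1",
                             "SHR_NHsd": "0/0"}}, GROUPS)
        result = prioritize.panel_filter([pav], panel, "GK_SLAC")
        assert result.survivors == []
        assert result.n_dropped_background == 1

    def test_missing_genotype_asymmetry(self):
        # missing in background keeps the variant; missing in case drops it
        keep = build_panel(
            {("chr1", 100): {"GK_OX": "1/1", "WKY_NCrl": "./.",
                             "SHR_NHsd": "0/0"}}, GROUPS)
        drop = build_panel(
            {("chr1", 100): {"GK_OX": "./.", "WKY_NCrl": "0/0",
                             "SHR_NHsd": "0/0"}}, GROUPS)
        pav = make_snv(pos=100)
        assert prioritize.panel_filter([pav], keep, "GK_SLAC").survivors == [pav]
        assert prioritize.panel_filter([pav], drop, "GK_SLAC").survivors == []

    def test_heterozygous_focal_pav_side_listed(self):
        pav = make_snv(pos=100, case="0/1")
        panel = build_panel(
            {("chr1", 100): {"GK_OX": "1/1", "WKY_NCrl": "0/0",
                             "SHR_NHsd": "0/0"}}, GROUPS)
        result = prioritize.panel_filter([pav], panel, "GK_SLAC")
        assert result.survivors == [] and result.heterozygous == [pav]

    def test_different_alternate_allele_does_not_match(self):
        # background strain homozygous for a *different* alternate
        pav = make_snv(pos=100, alt=["G", "C"], case="2/2")
        panel = build_panel(
            {("chr1", 100): {"GK_OX": "2/2", "WKY_NCrl": "1/1",
                             "SHR_NHsd": "0/0"}}, GROUPS)
        result = prioritize.panel_filter([pav], panel, "GK_SLAC")
        assert result.survivors == [pav]

    def test_strain_in_groups_absent_from_panel_fatal(self):
        panel = build_panel(
            {("chr1", 100): {"GK_OX": "1/1"}},
            {**GROUPS, "LEW_Crl": "control_background"})
        with pytest.raises(KeyError, match="absent from panel"):
            prioritize.panel_filter([make_snv(pos=100)], panel, "GK_SLAC")

    def test_empty_panel_passes_through_with_warning(self):
        panel = build_panel({}, GROUPS) if False else PanelMatrix(
            genotypes=pd.DataFrame(
                index=pd.MultiIndex.from_tuples([], names=["chromosome",
                                                           "position"])),
            groups=GROUPS)
        pav = make_snv(pos=100)
        with pytest.warns(UserWarning, match="empty"):
            result = prioritize.panel_filter([pav], panel, "GK_SLAC")
        assert result.survivors == [pav] and result.panel_was_empty

    def test_monotone_in_background_strains(self):
        rng = np.random.default_rng(9)
        pavs = [make_snv(pos=p) for p in range(10, 200, 10)]
        codes = ["0/0", "0/1", "1/1", "./."]
        strains = ["GK_OX", "BG1", "BG2", "BG3"]
        rows = {
            p.site: {s: str(rng.choice(codes, p=[0.5, 0.1, 0.3, 0.1]))
                     for s in strains}
            for p in pavs
        }
        base_groups = {"GK_OX": "case_consistent", "BG1": "control_background",
                       "BG2": "control_background"}
        wider_groups = {**base_groups, "BG3": "control_background"}
        base = prioritize.panel_filter(
            pavs, build_panel(rows, base_groups), "GK_SLAC").survivors
        wider = prioritize.panel_filter(
            pavs, build_panel(rows, wider_groups), "GK_SLAC").survivors
        assert {r.site for r in wider} <= {r.site for r in base}
        # adding a case-consistent strain can also only shrink the set
        stricter_groups = {**base_groups, "BG3": "case_consistent"}
        stricter = prioritize.panel_filter(
            pavs, build_panel(rows, stricter_groups), "GK_SLAC").survivors
        assert {r.site for r in stricter} <= {r.site for r in base}


class TestExcludeORGenes:
    def test_published_worked_example(self):
        models = {}
        genes = []
        for i in range(252):
            gene = f"G{i:03d}"
            genes.append(gene)
            models[gene] = GeneModel(gene, "chr1", i * 100, i * 100 + 50,
                                     is_olfactory_receptor=i < 60)
        kept, n_removed = prioritize.exclude_or_genes(genes, models)
        assert (len(kept), n_removed) == (192, 60)

    def test_no_flags_is_identity(self):
        models = {"A": GeneModel("A", "chr1", 0, 10, False)}
        assert prioritize.exclude_or_genes(["A"], models) == (["A"], 0)

    def test_all_flagged_empty(self):
        models = {"A": GeneModel("A", "chr1", 0, 10, True)}
        assert prioritize.exclude_or_genes(["A"], models) == ([], 1)

    def test_unmodelled_gene_kept_with_warning(self):
        with pytest.warns(UserWarning, match="no gene model"):
            kept, n = prioritize.exclude_or_genes(["ghost"], {})
        assert kept == ["ghost"] and n == 0


def brute_force_overlaps(features, genes):
    hits = {}
    for g in genes:
        for f in features:
            if f.chromosome == g.chromosome and f.start < g.end and g.start < f.end:
                hits.setdefault(g.gene_id, set()).add((f.chromosome, f.start, f.end))
    return hits


class TestFeatureGeneOverlap:
    def test_basic_overlap_and_half_open_boundary(self):
        genes = [GeneModel("G1", "chr1", 150, 400), GeneModel("G2", "chr1", 200, 400)]
        feature = IntervalFeature("chr1", 100, 200, "SV-deletion")
        hits = prioritize.overlap_features_with_genes([feature], genes)
        assert "G1" in hits and "G2" not in hits

    def test_random_instance_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(21)
        genes = []
        for i in range(200):
            start = int(rng.integers(0, 100_000))
            genes.append(GeneModel(f"G{i}", f"chr{rng.integers(1, 3)}",
                                   start, start + int(rng.integers(1, 500))))
        features = []
        for _ in range(200):
            start = int(rng.integers(0, 100_000))
            features.append(IntervalFeature(
                f"chr{rng.integers(1, 3)}", start,
                start + int(rng.integers(1, 500)), "SV-deletion"))
        fast = prioritize.overlap_features_with_genes(features, genes)
        fast_sets = {g: {(f.chromosome, f.start, f.end) for f in fs}
                     for g, fs in fast.items()}
        assert fast_sets == brute_force_overlaps(features, genes)
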