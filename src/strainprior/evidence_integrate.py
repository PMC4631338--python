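"""Evidence integration into a tiered candidate table, and the end-to-end
pipeline driver.

A candidate gene is high-confidence when it is itself a prior gene or when
its PPI partners are significantly enriched for prior genes (adjusted
p <= 0.05); differential (co-)expression is corroborating annotation only
and never promotes a gene on its own.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (
    density_profile,
    enrichment_network,
    expression_integration,
    formats_io,
    phylogeny,
    prioritize,
    strain_compare,
    variant_filters,
)

logger = logging.getLogger("strainprior")

TIER_HIGH = "high-confidence"
TIER_CANDIDATE = "candidate"

ENRICHMENT_ALPHA = 0.05


@dataclass
class EvidenceRecord:
    """Accumulated evidence for one candidate gene."""

    gene: str
    variants: list[dict] = field(default_factory=list)
    is_prior_gene: bool = False
    ppi_enriched: bool = False
    enrichment_adjusted_p: float | None = None
    de_tissues: list[str] = field(default_factory=list)
    dc_tissues: list[str] = field(default_factory=list)

    @property
    def expression_support(self) -> bool:
        return bool(self.de_tissues or self.dc_tissues)

    @property
    def tier(self) -> str:
        return TIER_HIGH if (self.is_prior_gene or self.ppi_enriched) \
            else TIER_CANDIDATE

    @property
    def evidence_flags(self) -> dict:
        return {
            "is_prior_gene": self.is_prior_gene,
            "ppi_enriched": self.ppi_enriched,
            "expression_support": self.expression_support,
        }

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "variants": self.variants,
            "is_prior_gene": self.is_prior_gene,
            "ppi_enriched": self.ppi_enriched,
            "enrichment_adjusted_p": self.enrichment_adjusted_p,
            "de_tissues": self.de_tissues,
            "dc_tissues": self.dc_tissues,
            "tier": self.tier,
        }


def integrate(
    candidates: list[str],
    prior_set: set[str],
    enrichment: list,
    expression_flags: dict[str, dict],
    variants_by_gene: dict[str, list[dict]] | None = None,
) -> list[EvidenceRecord]:
    """Merge the evidence streams into one record per candidate gene.

    Evidence keyed to genes outside the candidate list is ignored with a
    warning.  Records are sorted by (tier, adjusted p, gene).
    """
    candidate_set = set(candidates)
    enrichment_by_gene = {}
    for r in enrichment:
        if r.gene not in candidate_set:
            logger.warning("enrichment evidence for non-candidate %s ignored", r.gene)
            continue
        enrichment_by_gene[r.gene] = r
    for gene in expression_flags:
        if gene not in candidate_set:
            logger.warning("expression evidence for non-candidate %s ignored", gene)

    records = []
    for gene in sorted(candidate_set):
        enr = enrichment_by_gene.get(gene)
        flags = expression_flags.get(gene, {})
        records.append(
            EvidenceRecord(
                gene=gene,
                variants=(variants_by_gene or {}).get(gene, []),
                is_prior_gene=gene in prior_set,
                ppi_enriched=bool(
                    enr is not None
                    and enr.adjusted_p is not None
                    and enr.adjusted_p <= ENRICHMENT_ALPHA
                ),
                enrichment_adjusted_p=None if enr is None else enr.adjusted_p,
                de_tissues=list(flags.get("de_tissues", [])),
                dc_tissues=list(flags.get("dc_tissues", [])),
            )
        )
    tier_rank = {TIER_HIGH: 0, TIER_CANDIDATE: 1}
    records.sort(
        key=lambda r: (
            tier_rank[r.tier],
            r.enrichment_adjusted_p if r.enrichment_adjusted_p is not None else 2.0,
            r.gene,
        )
    )
    return records


DEFAULT_PARAMS = {
    "case": "GK_SLAC",
    "control": "WISTAR_SLAC",
    "bin_size": 1_000_000,
    "score_threshold": 0.4,
    "adjust_method": "fdr_bh",
    "dc_permutations": 300,
    "cnv_n_tests": None,  # default: number of CNV features
    "seed": 0,
}


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    print(f"[strainprior] {name}: {t1 - t0:.2f}s", file=sys.stderr)
    return t1


def run_pipeline(config: dict | str | Path) -> dict:
    """Run filter -> compare -> density -> prioritize -> tree -> enrich ->
    express -> integrate on the inputs named in `config`.

    ``config`` is a mapping (or YAML file) with keys ``inputs`` (paths as
    produced by the synthetic generator), ``params`` (see DEFAULT_PARAMS)
    and ``outdir``.  Writes every intermediate plus ``report.json`` under
    outdir and returns the report dict.  The report carries full parameter
    provenance and is byte-identical across reruns with the same config
    and seed.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    inputs = {k: Path(v) for k, v in config["inputs"].items()}
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    case, control = params["case"], params["control"]
    report: dict = {"params": {k: v for k, v in sorted(params.items())},
                    "inputs": {k: Path(v).name for k, v in
                               sorted(config["inputs"].items())}}
    t0 = time.perf_counter()

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- hard filters
    try:
        records = formats_io.read_vcf(inputs["vcf"])
        snvs = [r for r in records if r.is_snv]
        indels = [r for r in records if not r.is_snv]
        passed_snvs, snv_report = variant_filters.filter_snvs(snvs, indels)
        passed_indels, indel_report = variant_filters.filter_indels(indels)
        report["filter"] = {"snvs": snv_report.as_dict(),
                            "indels": indel_report.as_dict()}
        contigs = _contig_lengths(inputs["vcf"])
        formats_io.write_vcf(passed_snvs + passed_indels, outdir / "passed.vcf",
                             samples=[case, control], contigs=contigs)
    except Exception as exc:
        fail("filter", exc)
    t0 = _stage("filter", t0)

    # -- case-specific derivation and QC statistics
    try:
        specific, stats = strain_compare.derive_specific(
            passed_snvs + passed_indels, case, control)
        report["compare"] = stats.as_dict()
        if "truth_panel" in inputs:
            truth_variant, truth_invariant = formats_io.read_truth_panel(
                inputs["truth_panel"])
            called = {r.site for r in passed_snvs if r.is_variant(case)}
            report["validation"] = strain_compare.validate_against_truth(
                called, truth_variant, truth_invariant).as_dict()
    except Exception as exc:
        fail("compare", exc)
    t0 = _stage("compare", t0)

    # -- density profiling
    try:
        coverage = formats_io.read_bedgraph(inputs["coverage"])
        covered = density_profile.covered_bases_per_bin(
            coverage, contigs, params["bin_size"])
        spec_snvs = [r for r in specific if r.is_snv]
        spec_indels = [r for r in specific if not r.is_snv]
        snv_bins = density_profile.profile(spec_snvs, covered, contigs,
                                           params["bin_size"])
        indel_bins = density_profile.profile(spec_indels, covered, contigs,
                                             params["bin_size"])
        r, r2 = density_profile.correlate_densities(snv_bins, indel_bins)
        top, bottom = density_profile.extreme_bins(snv_bins)
        report["density"] = {
            "n_bins": len(snv_bins),
            "snv_indel_density_r": round(r, 6),
            "snv_indel_density_r2": round(r2, 6),
            "top_bins": [[b.chromosome, b.start] for b in top],
            "bottom_bins": [[b.chromosome, b.start] for b in bottom],
        }
        _write_bins(snv_bins, outdir / "snv_density.tsv")
        _write_bins(indel_bins, outdir / "indel_density.tsv")
    except Exception as exc:
        fail("density", exc)
    t0 = _stage("density", t0)

    # -- PAV selection, panel filter, OR exclusion, SV/CNV overlap
    try:
        annotations = formats_io.read_annotations(inputs["annotations"])
        genes = formats_io.read_genes_bed(inputs["genes"])
        gene_models = {g.gene_id: g for g in genes}
        pavs = [r for r in specific
                if r.site in annotations
                and prioritize.flag_pav(annotations[r.site]).is_pav]
        panel = formats_io.read_panel(inputs["panel"], inputs["panel_groups"])
        panel_result = prioritize.panel_filter(pavs, panel, case)
        surviving_genes = sorted({annotations[r.site].gene_id
                                  for r in panel_result.survivors})
        candidates, n_or_removed = prioritize.exclude_or_genes(
            surviving_genes, gene_models)
        features = formats_io.read_features(inputs["features"]) \
            if "features" in inputs else []
        cnvs = [f for f in features if f.feature_kind.startswith("CNV")]
        svs = [f for f in features if f.feature_kind.startswith("SV")]
        n_tests = params["cnv_n_tests"] or max(1, len(cnvs))
        diff_cnvs, cnv_report = variant_filters.filter_differential_cnv(
            cnvs, n_tests=n_tests)
        sv_cnv_hits = prioritize.overlap_features_with_genes(
            svs + diff_cnvs, genes)
        report["prioritize"] = {
            "n_pavs": len(pavs),
            "n_heterozygous_pavs": len(panel_result.heterozygous),
            "n_surviving_pavs": len(panel_result.survivors),
            "n_genes_with_surviving_pavs": len(surviving_genes),
            "n_or_genes_removed": n_or_removed,
            "n_candidate_genes": len(candidates),
            "cnv_filter": cnv_report.as_dict(),
            "n_sv_cnv_genes": len(sv_cnv_hits),
        }
        variants_by_gene: dict[str, list[dict]] = {}
        for r in panel_result.survivors:
            ann = annotations[r.site]
            variants_by_gene.setdefault(ann.gene_id, []).append({
                "position": f"{r.chromosome}:{r.position}",
                "change": f"{r.ref_allele}->{','.join(r.alt_alleles)}",
                "effect": ann.exonic_effect if ann.exonic_effect != "."
                else ann.region_class,
                "sift_call": ann.sift_call,
            })
    except Exception as exc:
        fail("prioritize", exc)
    t0 = _stage("prioritize", t0)

    # -- strain phylogeny
    try:
        labels, dmat = phylogeny.distance_matrix(panel)
        tree = phylogeny.upgma(dmat, labels)
        formats_io.write_newick(tree, outdir / "upgma_tree.nwk")
        report["phylogeny"] = {
            "n_strains": len(labels),
            "is_ultrametric": phylogeny.is_ultrametric(tree),
        }
    except Exception as exc:
        fail("tree", exc)
    t0 = _stage("tree", t0)

    # -- PPI enrichment
    try:
        edges = formats_io.read_ppi_edges(inputs["ppi"])
        prior = set(formats_io.read_gene_list(inputs["prior"]))
        graph = enrichment_network.build_ppi_graph(
            edges, params["score_threshold"])
        enrichment = enrichment_network.enrich_genes(
            graph, candidates, prior, method=params["adjust_method"])
        shared = enrichment_network.shared_partner_network(graph, candidates)
        report["enrichment"] = {
            "n_tested": len(enrichment),
            "n_significant": sum(
                1 for r in enrichment
                if r.adjusted_p is not None and r.adjusted_p <= ENRICHMENT_ALPHA),
            "adjust_method": params["adjust_method"],
            "n_shared_partner_edges": len(shared),
        }
    except Exception as exc:
        fail("enrich", exc)
    t0 = _stage("enrich", t0)

    # -- expression evidence
    try:
        exprs = expression_integration.ExpressionSet.from_files(
            inputs["expression"], inputs["expression_meta"])
        de_results, dc_results = [], []
        for tissue in exprs.tissues:
            for tp in exprs.times:
                de = expression_integration.differential_expression(
                    exprs, tissue, tp, case, control)
                de_results.extend(d for d in de if d.gene in set(candidates))
                dc_results.extend(
                    expression_integration.differential_coexpression(
                        exprs, tissue, tp, candidates, case, control,
                        n_permutations=params["dc_permutations"],
                        seed=params["seed"],
                    )
                )
        expression_flags = expression_integration.combine_timepoints(
            de_results, dc_results)
        report["expression"] = {
            "n_de_genes": sum(1 for f in expression_flags.values()
                              if f["de_tissues"]),
            "n_dc_genes": sum(1 for f in expression_flags.values()
                              if f["dc_tissues"]),
        }
    except Exception as exc:
        fail("express", exc)
    t0 = _stage("express", t0)

    # -- evidence integration
    try:
        evidence = integrate(candidates, prior, enrichment, expression_flags,
                             variants_by_gene)
        report["candidates"] = [r.as_dict() for r in evidence]
        report["summary"] = {
            "n_candidates": len(evidence),
            "n_high_confidence": sum(1 for r in evidence if r.tier == TIER_HIGH),
            "high_confidence_genes": sorted(
                r.gene for r in evidence if r.tier == TIER_HIGH),
        }
    except Exception as exc:
        fail("integrate", exc)
    _stage("integrate", t0)

    formats_io.write_json(report, outdir / "report.json")
    return report


def _contig_lengths(vcf_path: Path) -> dict[str, int]:
    contigs = formats_io.read_vcf_contigs(vcf_path)
    if not contigs:
        raise ValueError(f"no contig headers with lengths in {vcf_path}")
    return contigs


def _write_bins(bins, path: Path) -> None:
    lines = ["chromosome\tstart\tend\tn_variants\tn_covered_bases\tdensity"]
    for b in bins:
        density = "" if b.density is None else f"{b.density:.8g}"
        lines.append(f"{b.chromosome}\t{b.start}\t{b.end}\t{b.n_variants}\t"
                     f"{b.n_covered_bases}\t{density}")
    path.write_text("\n".join(lines) + "\n")
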