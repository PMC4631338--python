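"""Functional-impact selection, strain-panel consistency filter, OR-gene
exclusion, and SV/CNV-to-gene interval mapping.

Protein-affecting variants (PAVs) are those whose annotation can alter a
protein product: nonsynonymous, stopgain, stoploss, splicing, frameshift
indels and exonic ncRNA.  Candidate PAVs must be homozygous-variant in the
focal case strain and every case-consistent panel strain, and not
homozygous-variant (for the same alternate allele) in any control-background
panel strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .formats_io import (
    MISSING_GT,
    FunctionalAnnotation,
    GeneModel,
    IntervalFeature,
    PanelMatrix,
    VariantRecord,
    genotype_alleles,
)

__all__ = [
    "FunctionalAnnotation",
    "PAVFlag",
    "PanelFilterResult",
    "flag_pav",
    "panel_filter",
    "exclude_or_genes",
    "overlap_features_with_genes",
]

#: region classes / exonic effects that make a variant protein-affecting
PAV_REGION_REASONS = {"splicing": "splicing", "ncRNA_exonic": "ncRNA_exonic"}
PAV_EXONIC_EFFECTS = {
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "frameshift_insertion",
    "frameshift_deletion",
}
NON_PAV_REGIONS = {"UTR", "intronic", "upstream", "downstream", "intergenic"}


@dataclass
class PAVFlag:
    is_pav: bool
    pav_reason: str | None = None

    def __post_init__(self) -> None:
        if self.is_pav != (self.pav_reason is not None):
            raise ValueError("is_pav and pav_reason must agree")


def flag_pav(annotation: FunctionalAnnotation) -> PAVFlag:
    """Decide whether an annotated variant is protein-affecting.

    Every class in the annotation vocabulary maps explicitly to PAV or
    non-PAV; anything outside it raises rather than silently passing as
    non-PAV.
    """
    region = annotation.region_class
    if region in PAV_REGION_REASONS:
        return PAVFlag(True, PAV_REGION_REASONS[region])
    if region == "exonic":
        effect = annotation.exonic_effect
        if effect in PAV_EXONIC_EFFECTS:
            return PAVFlag(True, effect)
        if effect in ("synonymous", "."):
            return PAVFlag(False)
        raise ValueError(f"unknown exonic effect {effect!r}")
    if region in NON_PAV_REGIONS:
        return PAVFlag(False)
    raise ValueError(f"unknown region class {region!r}")


@dataclass
class PanelFilterResult:
    """Outcome of the strain-panel consistency filter."""

    survivors: list[VariantRecord]
    heterozygous: list[VariantRecord] = field(default_factory=list)
    n_dropped_case_inconsistent: int = 0
    n_dropped_background: int = 0
    panel_was_empty: bool = False


def _is_hom_for_alt(code: str, alt_index: int) -> bool:
    alleles = genotype_alleles(code)
    return alleles is not None and alleles[0] == alleles[1] == alt_index


def panel_filter(
    pavs: list[VariantRecord], panel: PanelMatrix, case: str
) -> PanelFilterResult:
    """Keep PAVs consistent with the case clade and absent from background.

    A PAV survives iff the focal case strain is homozygous-variant, every
    case-consistent panel strain is homozygous for the same alternate
    allele, and no control-background strain is.  Missing panel genotypes
    count against a case-consistent strain (homozygosity must be observed)
    but in favour of a background strain (absence of evidence cannot
    demonstrate the variant).  Heterozygous focal PAVs go to a side list.
    An empty panel passes homozygous PAVs through with a warning.
    """
    case_strains = panel.case_consistent_strains
    background = panel.background_strains
    missing = [s for s in case_strains + background if s not in panel.strains]
    if panel.n_sites > 0 and missing:
        raise KeyError(f"strains named in groups but absent from panel: {missing}")

    empty = panel.n_sites == 0 or not (case_strains or background)
    if empty:
        warnings.warn(
            "panel is empty; consistency filter passes all homozygous PAVs through",
            stacklevel=2,
        )

    result = PanelFilterResult(survivors=[], panel_was_empty=empty)
    for r in pavs:
        if not r.is_homozygous_variant(case):
            result.heterozygous.append(r)
            continue
        if empty:
            result.survivors.append(r)
            continue
        alt_index = r.alleles_of(case)[0]
        chrom, pos = r.site
        if not all(
            _is_hom_for_alt(panel.genotype(chrom, pos, s), alt_index)
            for s in case_strains
        ):
            result.n_dropped_case_inconsistent += 1
            continue
        if any(
            _is_hom_for_alt(panel.genotype(chrom, pos, s), alt_index)
            for s in background
        ):
            result.n_dropped_background += 1
            continue
        result.survivors.append(r)
    return result


def exclude_or_genes(
    gene_ids: list[str], models: dict[str, GeneModel]
) -> tuple[list[str], int]:
    """Drop olfactory-receptor genes; returns (kept, n_removed).

    A gene without a model cannot be confirmed as OR and is kept with a
    warning.
    """
    kept: list[str] = []
    n_removed = 0
    for gene in gene_ids:
        model = models.get(gene)
        if model is None:
            warnings.warn(f"no gene model for {gene}; kept (OR status unknown)",
                          stacklevel=2)
            kept.append(gene)
        elif model.is_olfactory_receptor:
            n_removed += 1
        else:
            kept.append(gene)
    return kept, n_removed


def overlap_features_with_genes(
    features: list[IntervalFeature], genes: list[GeneModel]
) -> dict[str, list[IntervalFeature]]:
    """Map each gene to the SV/CNV features intersecting it by >= 1 base.

    Both inputs are 0-based half-open, so a feature ending exactly where a
    gene starts does not overlap.  Interval-tree lookup per chromosome.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start, g.end, g.gene_id)
    hits: dict[str, list[IntervalFeature]] = {}
    for f in features:
        tree = trees.get(f.chromosome)
        if tree is None:
            continue
        for iv in tree.overlap(f.start, f.end):
            hits.setdefault(iv.data, []).append(f)
    for gene in hits:
        hits[gene].sort(key=lambda f: (f.chromosome, f.start, f.feature_kind))
    return hits
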