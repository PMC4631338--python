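"""Readers and writers for the formats the pipeline touches.

One internal data model is shared by all stages.  Coordinate conventions:
VCF records keep their native 1-based positions; every interval-like object
(genes, SVs/CNVs, coverage, density bins, assembly gaps) is 0-based
half-open.  Conversion between the two happens here and in the binning
code, nowhere else.

VCF parsing goes through :mod:`cyvcf2`; Newick trees are
:class:`skbio.TreeNode`; tabular dialects are plain TSV (tab separated,
UTF-8, header row) handled with :mod:`pandas`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF
from skbio import TreeNode

MISSING_GT = "./."

#: genotype codes a strain-panel matrix may contain
PANEL_GT_CODES = {"0/0", "0/1", "1/1", "0/2", "1/2", "2/2", MISSING_GT}

#: site-level QC annotations carried by a VariantRecord, mapped to the
#: VCF INFO keys used on disk
SITE_QC_FIELDS = {
    "depth": "DP",
    "allele_number": "AN",
    "quality_by_depth": "QD",
    "zero_mapq_count": "MQ0",
    "base_quality": "BQ",
}
_INFO_TO_QC = {v: k for k, v in SITE_QC_FIELDS.items()}
_INT_QC = {"depth", "allele_number", "zero_mapq_count"}


def normalize_genotype(gt: str) -> str:
    """Normalize a diploid genotype code: phase stripped, alleles sorted.

    ``"0|1" -> "0/1"``, ``"2/1" -> "1/2"``; any missing allele collapses to
    ``"./."`` (a half-called genotype cannot be classified).
    """
    alleles = gt.replace("|", "/").split("/")
    if len(alleles) != 2:
        raise ValueError(f"not a diploid genotype code: {gt!r}")
    if "." in alleles:
        return MISSING_GT
    a, b = sorted(int(x) for x in alleles)
    return f"{a}/{b}"


def genotype_alleles(gt: str) -> tuple[int, int] | None:
    """Allele indices of a normalized genotype, or None if missing."""
    if gt == MISSING_GT:
        return None
    a, b = gt.split("/")
    return int(a), int(b)


@dataclass
class VariantRecord:
    """One variant site with per-strain genotypes and site-level QC.

    ``position`` is 1-based (VCF convention).  Multi-allelic sites are kept
    whole — genotype codes like ``1/2`` refer to two alternate alleles at
    one site and must not be split.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_alleles: list[str]
    genotypes: dict[str, str]
    site_qc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        self.genotypes = {s: normalize_genotype(g) for s, g in self.genotypes.items()}
        n_alleles = 1 + len(self.alt_alleles)
        for strain, gt in self.genotypes.items():
            alleles = genotype_alleles(gt)
            if alleles and max(alleles) >= n_alleles:
                raise ValueError(
                    f"{self.chromosome}:{self.position} genotype {gt} of "
                    f"{strain} indexes a missing allele"
                )

    @property
    def variant_class(self) -> str:
        """'SNV', 'insertion' or 'deletion' (longest-alt rule for mixed sites)."""
        if len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles):
            return "SNV"
        if max(len(a) for a in self.alt_alleles) > len(self.ref_allele):
            return "insertion"
        return "deletion"

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"

    def genotype(self, strain: str) -> str:
        return self.genotypes[strain]

    def alleles_of(self, strain: str) -> tuple[int, int] | None:
        return genotype_alleles(self.genotypes[strain])

    def alt_indices_of(self, strain: str) -> tuple[int, ...]:
        """Distinct alternate-allele indices carried by a strain (sorted)."""
        alleles = self.alleles_of(strain)
        if alleles is None:
            return ()
        return tuple(sorted({a for a in alleles if a >= 1}))

    def is_variant(self, strain: str) -> bool:
        return bool(self.alt_indices_of(strain))

    def is_homozygous(self, strain: str) -> bool:
        alleles = self.alleles_of(strain)
        return alleles is not None and alleles[0] == alleles[1]

    def is_homozygous_variant(self, strain: str) -> bool:
        alleles = self.alleles_of(strain)
        return alleles is not None and alleles[0] == alleles[1] >= 1

    @property
    def site(self) -> tuple[str, int]:
        return (self.chromosome, self.position)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF 4.x file into VariantRecords.

    Genotypes are surfaced for all samples; phasing is discarded
    (``0|1`` becomes ``0/1``); multi-allelic records are preserved whole.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        genotypes = {}
        for sample, g in zip(samples, v.genotypes):
            a, b = g[0], g[1]
            code = MISSING_GT if a < 0 or b < 0 else f"{a}/{b}"
            genotypes[sample] = code
        site_qc = {}
        for info_key, qc_key in _INFO_TO_QC.items():
            value = v.INFO.get(info_key)
            if value is not None:
                site_qc[qc_key] = int(value) if qc_key in _INT_QC else float(value)
        records.append(
            VariantRecord(
                chromosome=v.CHROM,
                position=v.POS,
                ref_allele=v.REF,
                alt_alleles=list(v.ALT),
                genotypes=genotypes,
                site_qc=site_qc,
            )
        )
    vcf.close()
    return records


def read_vcf_contigs(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from a VCF's ##contig header lines."""
    contigs: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("##"):
            break
        if line.startswith("##contig=<"):
            fields = dict(
                kv.split("=", 1)
                for kv in line[len("##contig=<"):].rstrip(">").split(",")
            )
            if "ID" in fields and "length" in fields:
                contigs[fields["ID"]] = int(fields["length"])
    return contigs


_VCF_INFO_HEADERS = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##INFO=<ID=AN,Number=1,Type=Integer,Description="Number of called alleles">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
    '##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Reads with mapping quality zero">',
    '##INFO=<ID=BQ,Number=1,Type=Float,Description="RMS base quality">',
]


def write_vcf(
    records: list[VariantRecord],
    path: str | Path,
    samples: list[str] | None = None,
    contigs: dict[str, int] | None = None,
) -> Path:
    """Write VariantRecords as a minimal VCF 4.2 file (GT format only)."""
    path = Path(path)
    if samples is None:
        samples = list(records[0].genotypes) if records else []
    lines = ["##fileformat=VCFv4.2", "##source=strainprior"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.extend(_VCF_INFO_HEADERS)
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    ordered = sorted(records, key=lambda r: (r.chromosome, r.position))
    for r in ordered:
        info_parts = []
        for qc_key, info_key in SITE_QC_FIELDS.items():
            if qc_key in r.site_qc:
                value = r.site_qc[qc_key]
                text = str(int(value)) if qc_key in _INT_QC else f"{float(value):g}"
                info_parts.append(f"{info_key}={text}")
        info = ";".join(info_parts) or "."
        gts = "\t".join(r.genotypes.get(s, MISSING_GT) for s in samples)
        lines.append(
            f"{r.chromosome}\t{r.position}\t.\t{r.ref_allele}\t"
            f"{','.join(r.alt_alleles)}\t.\t.\t{info}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Strain panel


@dataclass
class PanelMatrix:
    """Strains x sites genotype matrix with strain-group labels.

    ``genotypes`` is indexed by (chromosome, position) with one column per
    strain; ``groups`` maps strain -> 'case_consistent' | 'control_background'
    | 'other'.
    """

    genotypes: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        bad = set(self.genotypes.values.ravel()) - PANEL_GT_CODES
        if bad:
            raise ValueError(f"unknown genotype codes in panel: {sorted(bad)}")

    @property
    def strains(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_sites(self) -> int:
        return len(self.genotypes)

    def strains_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def case_consistent_strains(self) -> list[str]:
        return self.strains_in_group("case_consistent")

    @property
    def background_strains(self) -> list[str]:
        return self.strains_in_group("control_background")

    def genotype(self, chromosome: str, position: int, strain: str) -> str:
        key = (chromosome, position)
        if key not in self.genotypes.index:
            return MISSING_GT
        return self.genotypes.at[key, strain]


def read_panel(path: str | Path, groups_path: str | Path) -> PanelMatrix:
    """Read a panel genotype TSV plus its strain-group sidecar.

    The matrix file has columns ``chromosome``, ``position`` then one column
    per strain; duplicate site rows are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if df.empty and list(df.columns)[:2] != ["chromosome", "position"]:
        df = pd.DataFrame(columns=["chromosome", "position"])
    dup = df.duplicated(subset=["chromosome", "position"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate panel site {first['chromosome']}:{first['position']}"
        )
    matrix = df.set_index(["chromosome", "position"])
    groups_df = pd.read_csv(groups_path, sep="\t")
    groups = dict(zip(groups_df["strain"], groups_df["group"]))
    return PanelMatrix(genotypes=matrix, groups=groups)


def write_panel(panel: PanelMatrix, path: str | Path, groups_path: str | Path) -> None:
    out = panel.genotypes.reset_index()
    out.to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        sorted(panel.groups.items()), columns=["strain", "group"]
    ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models and interval features


@dataclass
class GeneModel:
    """A gene span (0-based half-open) with an olfactory-receptor flag."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    is_olfactory_receptor: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read BED6 gene models; the score column carries the OR flag (0/1)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end, name, score, _strand = line.split("\t")[:6]
        genes.append(
            GeneModel(
                gene_id=name,
                chromosome=chrom,
                start=int(start),
                end=int(end),
                is_olfactory_receptor=bool(int(score)),
            )
        )
    return genes


def write_genes_bed(genes: list[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t"
        f"{int(g.is_olfactory_receptor)}\t+"
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
    ]
    path.write_text("\n".join(lines) + "\n" if lines else "")
    return path


SV_KINDS = {
    "SV-deletion",
    "SV-inversion",
    "SV-tandem-duplication",
    "SV-translocation-breakpoint",
}
CNV_KINDS = {"CNV-gain", "CNV-loss"}


@dataclass
class IntervalFeature:
    """A structural-variant or copy-number interval (0-based half-open).

    ``ratio`` is the case/control mapped-read ratio and ``p_value`` the raw
    segmentation p-value; both are CNV-only and may be None.
    """

    chromosome: str
    start: int
    end: int
    feature_kind: str
    ratio: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("feature start must be < end")
        if self.feature_kind not in SV_KINDS | CNV_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.ratio is not None and not self.ratio > 0:
            raise ValueError("ratio must be > 0 when present")


def read_features(path: str | Path) -> list[IntervalFeature]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    features = []
    for row in df.itertuples(index=False):
        ratio = getattr(row, "ratio", None)
        p = getattr(row, "p_value", None)
        features.append(
            IntervalFeature(
                chromosome=row.chromosome,
                start=int(row.start),
                end=int(row.end),
                feature_kind=row.feature_kind,
                ratio=None if ratio is None or pd.isna(ratio) else float(ratio),
                p_value=None if p is None or pd.isna(p) else float(p),
            )
        )
    return features


def write_features(features: list[IntervalFeature], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "chromosome": f.chromosome,
            "start": f.start,
            "end": f.end,
            "feature_kind": f.feature_kind,
            "ratio": f.ratio,
            "p_value": f.p_value,
        }
        for f in sorted(features, key=lambda f: (f.chromosome, f.start, f.feature_kind))
    ]
    pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "feature_kind", "ratio", "p_value"]
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Functional annotations (ANNOVAR/SIFT-style TSV)

REGION_CLASSES = {
    "exonic",
    "splicing",
    "ncRNA_exonic",
    "UTR",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
}
EXONIC_EFFECTS = {
    "nonsynonymous",
    "synonymous",
    "stopgain",
    "stoploss",
    "frameshift_insertion",
    "frameshift_deletion",
    ".",
}
SIFT_CALLS = {"deleterious", "tolerated", "."}


@dataclass
class FunctionalAnnotation:
    """Region class + exonic effect + SIFT call for one variant site."""

    chromosome: str
    position: int
    gene_id: str
    region_class: str
    exonic_effect: str = "."
    sift_call: str = "."

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if self.exonic_effect not in EXONIC_EFFECTS:
            raise ValueError(f"unknown exonic effect {self.exonic_effect!r}")
        if self.region_class != "exonic" and self.exonic_effect != ".":
            raise ValueError("exonic_effect only applies to exonic variants")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chromosome, self.position)


def read_annotations(path: str | Path) -> dict[tuple[str, int], FunctionalAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, keep_default_na=False)
    annotations = {}
    for row in df.itertuples(index=False):
        ann = FunctionalAnnotation(
            chromosome=row.chromosome,
            position=int(row.position),
            gene_id=row.gene_id,
            region_class=row.region_class,
            exonic_effect=row.exonic_effect,
            sift_call=row.sift_call,
        )
        annotations[ann.site] = ann
    return annotations


def write_annotations(
    annotations: dict[tuple[str, int], FunctionalAnnotation], path: str | Path
) -> Path:
    path = Path(path)
    rows = [
        {
            "chromosome": a.chromosome,
            "position": a.position,
            "gene_id": a.gene_id,
            "region_class": a.region_class,
            "exonic_effect": a.exonic_effect,
            "sift_call": a.sift_call,
        }
        for a in sorted(annotations.values(), key=lambda a: (a.chromosome, a.position))
    ]
    pd.DataFrame(
        rows,
        columns=["chromosome", "position", "gene_id", "region_class",
                 "exonic_effect", "sift_call"],
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# PPI edges, gene lists, coverage, truth panel


def read_ppi_edges(path: str | Path) -> pd.DataFrame:
    """Edge list TSV with columns gene_a, gene_b, score."""
    return pd.read_csv(path, sep="\t")


def write_ppi_edges(edges: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    edges.to_csv(path, sep="\t", index=False)
    return path


def read_gene_list(path: str | Path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(genes) + "\n" if genes else "")
    return path


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Per-interval read depth: columns chromosome, start, end, depth."""
    return pd.read_csv(
        path, sep="\t", names=["chromosome", "start", "end", "depth"],
        dtype={"chromosome": str},
    )


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    track.to_csv(path, sep="\t", index=False, header=False)
    return path


def read_truth_panel(path: str | Path) -> tuple[set, set]:
    """Truth positions TSV (chromosome, position, status) -> (variant, invariant)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    variant = {
        (r.chromosome, int(r.position))
        for r in df.itertuples(index=False) if r.status == "variant"
    }
    invariant = {
        (r.chromosome, int(r.position))
        for r in df.itertuples(index=False) if r.status == "invariant"
    }
    return variant, invariant


def write_truth_panel(variant: set, invariant: set, path: str | Path) -> Path:
    path = Path(path)
    rows = [(c, p, "variant") for c, p in sorted(variant)]
    rows += [(c, p, "invariant") for c, p in sorted(invariant)]
    pd.DataFrame(rows, columns=["chromosome", "position", "status"]).to_csv(
        path, sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# Newick trees and JSON reports


def write_newick(tree: TreeNode, path: str | Path) -> Path:
    """Write a tree as Newick; duplicate leaf labels are fatal."""
    labels = [t.name for t in tree.tips()] or [tree.name]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    path = Path(path)
    tree.write(str(path), format="newick")
    return path


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_json(obj, path: str | Path) -> Path:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
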