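"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a two-strain inbred comparison at desk scale: two
mostly-homozygous focal genomes (case and control) differing at a
controllable set of sites, a multi-strain genotype panel evolved along a
known clock-like tree, gene models with an olfactory-receptor fraction, a
PPI graph with planted prior-gene enrichment, and an expression matrix
with planted fold-changes and planted correlation flips.

Defaults mirror the study conditions the pipeline was built for: genotype
group mixture (3.6% / 92.9% / 3.5% het-case / hom-case / hom-het groups),
target Ti/Tv 2.10, ~96% case homozygosity, an indel:SNV ratio of about
0.135, eleven control-background panel strains plus one case-consistent
strain, and expression in three tissues at five time points.

One global seed drives independent per-component substreams, so
regenerating one component never perturbs another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from . import formats_io
from .formats_io import (
    FunctionalAnnotation,
    GeneModel,
    IntervalFeature,
    PanelMatrix,
    VariantRecord,
)

BASES = ("A", "C", "G", "T")
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

CASE = "GK_SLAC"
CONTROL = "WISTAR_SLAC"
CASE_CONSISTENT_STRAINS = ("GK_OX",)
BACKGROUND_STRAINS = (
    "SHR_NHsd", "SHRSP_Gla", "SHR_OlaIpcv", "WKY_NCrl", "WKY_Gla", "WKY_NHsd",
    "LEW_Crl", "LEW_NcrlBR", "WAG_Rij", "MHS_Gib", "MNS_Gib",
)
OTHER_STRAINS = ("BBDP_Wor", "BN", "F344")

#: substream indices for the per-component RNGs
_STREAMS = (
    "focal", "panel", "genes", "annotations", "ppi",
    "expression", "coverage", "truth_panel", "features", "planting",
)


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    ``group_mixture`` gives the proportions of the five genotype groups
    among case-specific variants; ``het_fraction``, when set, rescales the
    heterozygous groups (1 and 5) to that total with the homozygous groups
    filling the remainder proportionally.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_variants: int = 24_000
    indel_fraction: float = 0.12
    target_titv: float = 2.10
    het_fraction: float | None = None
    group_mixture: tuple[float, ...] = (0.036, 0.929, 0.035, 0.0, 0.0)
    specific_fraction: float = 0.45
    qc_fail_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "depth": 0.02, "allele_number": 0.01, "base_quality": 0.02,
            "quality_by_depth": 0.02, "zero_mapq": 0.01,
        }
    )
    n_snv_clusters: int = 5
    n_panel_strains: int = 17
    n_panel_sites: int = 3_000
    panel_candidate_fraction: float = 0.5
    n_genes: int = 240
    or_fraction: float = 0.24
    n_pav_snvs: int = 60
    n_het_pav_snvs: int = 8
    or_pav_fraction: float = 0.25
    ppi_n_edges: int = 2_000
    ppi_universe_size: int = 800
    prior_gene_count: int = 60
    n_planted_enriched: int = 3
    planted_partner_count: int = 15
    planted_prior_prob: float = 0.6
    planted_enriched_genes: tuple[str, ...] | None = None
    n_prior_candidate_genes: int = 3
    tissues: tuple[str, ...] = ("liver", "muscle", "adipose")
    time_points: tuple[int, ...] = (1, 2, 3, 4, 5)
    expr_samples_per_condition: int = 5
    expr_log2_mean: float = 8.0
    expr_log2_sigma: float = 0.25
    n_de_planted: int = 3
    de_fold_change: float = 4.0
    n_dc_planted: int = 2
    dc_rho_case: float = 0.9
    dc_rho_control: float = -0.9
    planted_de_genes: dict[str, dict] | None = None
    planted_dc_genes: dict[str, dict] | None = None
    n_svs: int = 30
    n_cnvs: int = 60
    cnv_differential_fraction: float = 0.3
    n_truth_variant: int = 500
    n_truth_invariant: int = 300
    truth_sensitivity: float = 0.95
    truth_specificity: float = 0.995
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_mixture) - 1.0) > 1e-9:
            raise ValueError("group_mixture must sum to 1")
        if len(self.group_mixture) != 5:
            raise ValueError("group_mixture needs five entries")
        if self.target_titv <= 0:
            raise ValueError("target_titv must be positive")
        for name in ("n_variants", "n_panel_strains", "n_genes", "ppi_n_edges",
                     "prior_gene_count", "expr_samples_per_condition"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def effective_mixture(self) -> tuple[float, ...]:
        """group_mixture with the heterozygous share rescaled to het_fraction."""
        mix = tuple(float(m) for m in self.group_mixture)
        if self.het_fraction is None:
            return mix
        het = mix[0] + mix[4]
        hom = mix[1] + mix[2] + mix[3]
        target_het = float(self.het_fraction)
        het_scale = target_het / het if het > 0 else 0.0
        hom_scale = (1.0 - target_het) / hom if hom > 0 else 0.0
        scaled = (mix[0] * het_scale, mix[1] * hom_scale, mix[2] * hom_scale,
                  mix[3] * hom_scale, mix[4] * het_scale)
        if het == 0 and target_het > 0:
            scaled = (target_het, *(m * hom_scale for m in mix[1:4]), 0.0)
        return scaled

    def rng(self, component: str) -> np.random.Generator:
        """Independent substream for one component, derived from the seed."""
        index = _STREAMS.index(component)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(index,))
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        kwargs = dict(data)
        for key in ("group_mixture", "tissues", "time_points",
                    "planted_enriched_genes"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """What the generator planted, keyed the same way the outputs are."""

    true_group_per_variant: dict[str, str] = field(default_factory=dict)
    qc_fail_sites: list[str] = field(default_factory=list)
    cluster_sites: list[str] = field(default_factory=list)
    pav_sites: list[str] = field(default_factory=list)
    surviving_pav_sites: list[str] = field(default_factory=list)
    candidate_genes: list[str] = field(default_factory=list)
    true_tree_newick: str = ""
    true_enriched_genes: list[str] = field(default_factory=list)
    prior_candidate_genes: list[str] = field(default_factory=list)
    true_de_genes: dict[str, dict] = field(default_factory=dict)
    true_dc_genes: dict[str, dict] = field(default_factory=dict)
    differential_cnv_count: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _site_key(chromosome: str, position: int) -> str:
    return f"{chromosome}:{position}"


def _sample_positions(
    rng: np.random.Generator, length: int, k: int, exclude: set[int] | None = None
) -> np.ndarray:
    """k distinct 1-based positions on a chromosome, outside `exclude`."""
    exclude = exclude or set()
    chosen: set[int] = set()
    while len(chosen) < k:
        draw = rng.integers(1, length + 1, size=int((k - len(chosen)) * 1.3) + 8)
        for p in draw:
            p = int(p)
            if p not in exclude and p not in chosen:
                chosen.add(p)
                if len(chosen) == k:
                    break
    return np.array(sorted(chosen))


def _draw_snv_alleles(rng: np.random.Generator, p_transition: float,
                      n_alts: int = 1) -> tuple[str, list[str]]:
    ref = BASES[rng.integers(4)]
    alts: list[str] = []
    pool = [b for b in BASES if b != ref]
    while len(alts) < n_alts:
        if rng.random() < p_transition:
            alt = TRANSITION_PARTNER[ref]
        else:
            alt = [b for b in pool if b != TRANSITION_PARTNER[ref]][rng.integers(2)]
        if alt not in alts:
            alts.append(alt)
    return ref, alts


_GROUP_GENOTYPES = {
    "Group1": ("0/1", "0/0"),
    "Group2": ("1/1", "0/0"),
    "Group3": ("1/1", "0/1"),
    "Group4": ("1/2", "0/0"),
    "Group5": ("1/2", "0/1"),
}


def generate_focal_records(
    cfg: SimConfig,
) -> tuple[list[VariantRecord], list[VariantRecord], GroundTruth]:
    """Two-sample focal callset: (snv_records, indel_records, truth).

    Group proportions follow cfg's (effective) mixture within binomial
    error; substitution types realize the target Ti/Tv; a configurable
    fraction of records violates each QC filter rule; positions are unique
    per chromosome.
    """
    rng = cfg.rng("focal")
    truth = GroundTruth()
    p_ti = cfg.target_titv / (1.0 + cfg.target_titv)
    mixture = np.array(cfg.effective_mixture)
    p_het_shared = mixture[0] + mixture[4]

    n_indels = int(round(cfg.n_variants * cfg.indel_fraction))
    n_snvs = cfg.n_variants - n_indels

    chroms = sorted(cfg.chromosome_lengths)
    lengths = np.array([cfg.chromosome_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    # allocate variant counts per chromosome proportionally to length
    snv_alloc = rng.multinomial(n_snvs, weights)
    indel_alloc = rng.multinomial(n_indels, weights)

    snv_records: list[VariantRecord] = []
    indel_records: list[VariantRecord] = []

    for chrom, n_snv_c, n_indel_c in zip(chroms, snv_alloc, indel_alloc):
        length = cfg.chromosome_lengths[chrom]
        used: set[int] = set()
        positions = _sample_positions(rng, length, n_snv_c + n_indel_c)
        used.update(int(p) for p in positions)
        rng.shuffle(positions)  # SNV/indel split must not depend on coordinate
        snv_pos = positions[:n_snv_c]
        indel_pos = positions[n_snv_c:]

        for pos in snv_pos:
            pos = int(pos)
            specific = rng.random() < cfg.specific_fraction
            if specific:
                group = str(rng.choice(list(_GROUP_GENOTYPES), p=mixture))
                case_gt, control_gt = _GROUP_GENOTYPES[group]
            else:
                group = "NotSpecific"
                shared = "0/1" if rng.random() < p_het_shared else "1/1"
                case_gt = control_gt = shared
            n_alts = 2 if "2" in case_gt else 1
            ref, alts = _draw_snv_alleles(rng, p_ti, n_alts)
            record = VariantRecord(
                chromosome=chrom, position=pos, ref_allele=ref, alt_alleles=alts,
                genotypes={CASE: case_gt, CONTROL: control_gt},
                site_qc=_passing_snv_qc(rng),
            )
            snv_records.append(record)
            truth.true_group_per_variant[_site_key(chrom, pos)] = group

        for pos in indel_pos:
            pos = int(pos)
            specific = rng.random() < cfg.specific_fraction
            if specific:
                group = str(rng.choice(list(_GROUP_GENOTYPES), p=mixture))
                case_gt, control_gt = _GROUP_GENOTYPES[group]
            else:
                group = "NotSpecific"
                case_gt = control_gt = "0/1" if rng.random() < p_het_shared else "1/1"
            n_alts = 2 if "2" in case_gt else 1
            base = BASES[rng.integers(4)]
            extra = BASES[rng.integers(4)]
            if rng.random() < 0.5:  # insertion
                ref = base
                alts = [base + extra]
                if n_alts == 2:
                    alts.append(base + extra + BASES[rng.integers(4)])
            else:  # deletion
                ref = base + extra
                alts = [base]
                if n_alts == 2:
                    alts.append(base + BASES[rng.integers(4)])
            record = VariantRecord(
                chromosome=chrom, position=pos, ref_allele=ref, alt_alleles=alts,
                genotypes={CASE: case_gt, CONTROL: control_gt},
                site_qc={
                    "depth": int(rng.poisson(14)),  # ~3% fall below the DP>=8 cut
                    "allele_number": 4,
                },
            )
            indel_records.append(record)
            truth.true_group_per_variant[_site_key(chrom, pos)] = group

        # planted SNV clusters: triples of extra shared SNVs inside a 10-bp window
        n_clusters_c = cfg.n_snv_clusters // len(chroms) + (
            1 if chroms.index(chrom) < cfg.n_snv_clusters % len(chroms) else 0
        )
        for _ in range(n_clusters_c):
            anchor = int(rng.integers(10, length - 10))
            member_pos = [anchor, anchor + 3, anchor + 6]
            if any(p in used for p in member_pos):
                continue
            for p in member_pos:
                used.add(p)
                ref, alts = _draw_snv_alleles(rng, p_ti)
                snv_records.append(
                    VariantRecord(
                        chromosome=chrom, position=p, ref_allele=ref,
                        alt_alleles=alts,
                        genotypes={CASE: "1/1", CONTROL: "1/1"},
                        site_qc=_passing_snv_qc(rng),
                    )
                )
                truth.true_group_per_variant[_site_key(chrom, p)] = "NotSpecific"
                truth.cluster_sites.append(_site_key(chrom, p))

    _plant_qc_failures(cfg, rng, snv_records, truth)
    snv_records.sort(key=lambda r: (r.chromosome, r.position))
    indel_records.sort(key=lambda r: (r.chromosome, r.position))
    return snv_records, indel_records, truth


def _passing_snv_qc(rng: np.random.Generator) -> dict:
    return {
        "depth": int(10 + rng.poisson(5)),
        "allele_number": 4,
        "base_quality": float(np.round(30 + rng.uniform(0, 10), 2)),
        "quality_by_depth": float(np.round(5 + rng.uniform(0, 25), 2)),
        "zero_mapq_count": int(rng.integers(0, 5)),
    }


def _plant_qc_failures(cfg, rng, records, truth) -> None:
    """Overwrite QC fields on disjoint record subsets to violate each rule."""
    order = rng.permutation(len(records))
    cursor = 0
    for rule, frac in sorted(cfg.qc_fail_fractions.items()):
        n_fail = int(round(frac * len(records)))
        chosen = order[cursor : cursor + n_fail]
        cursor += n_fail
        for i in chosen:
            r = records[int(i)]
            if rule == "depth":
                r.site_qc["depth"] = int(rng.integers(0, 10))
            elif rule == "allele_number":
                r.site_qc["allele_number"] = 2
            elif rule == "base_quality":
                r.site_qc["base_quality"] = float(np.round(rng.uniform(10, 30), 2))
            elif rule == "quality_by_depth":
                r.site_qc["quality_by_depth"] = float(np.round(rng.uniform(0, 5), 2))
            elif rule == "zero_mapq":
                r.site_qc["zero_mapq_count"] = int(rng.integers(5, 20))
            else:
                raise ValueError(f"unknown QC rule {rule!r}")
            truth.qc_fail_sites.append(_site_key(r.chromosome, r.position))


# ---------------------------------------------------------------------------
# Strain panel


def _join_clades(children: list[tuple[TreeNode, float]], height: float) -> tuple[TreeNode, float]:
    """Merge clades (node, height) at `height`; branch lengths fill the gap."""
    for node, child_height in children:
        node.length = height - child_height
    return TreeNode(children=[c[0] for c in children]), height


def default_panel_tree(cfg: SimConfig) -> TreeNode:
    """Clock-like panel tree: a tight case clade, a control-background
    clade, and progressively deeper outgroups.  Branch lengths are per-site
    flip probabilities."""
    leaves = {name: (TreeNode(name=name), 0.0)
              for name in (CASE, *CASE_CONSISTENT_STRAINS, CONTROL,
                           *BACKGROUND_STRAINS, *OTHER_STRAINS)}
    extra = max(0, cfg.n_panel_strains - len(leaves))
    for i in range(extra):
        name = f"OUT{i + 1:02d}"
        leaves[name] = (TreeNode(name=name), 0.0)

    # merge heights spaced so the topology is resolvable from the default
    # number of panel sites (steps well above binomial distance noise)
    gk = _join_clades([leaves[CASE], leaves["GK_OX"]], 0.005)
    # balanced background clade: shallow pairs, no deep ladder, so every
    # split stays resolvable before identity-by-state saturates
    w1 = _join_clades(
        [_join_clades([leaves[CONTROL], leaves["WKY_NCrl"]], 0.010),
         _join_clades([leaves["WKY_Gla"], leaves["WKY_NHsd"]], 0.020)], 0.045)
    w2 = _join_clades(
        [_join_clades([leaves["SHR_NHsd"], leaves["SHRSP_Gla"]], 0.012),
         _join_clades([leaves["SHR_OlaIpcv"], leaves["LEW_Crl"]], 0.022)], 0.05)
    w3 = _join_clades(
        [_join_clades([leaves["LEW_NcrlBR"], leaves["WAG_Rij"]], 0.014),
         _join_clades([leaves["MHS_Gib"], leaves["MNS_Gib"]], 0.024)], 0.055)
    wistar = _join_clades([_join_clades([w1, w2], 0.075), w3], 0.095)
    ingroup = _join_clades([gk, wistar], 0.12)
    tree = _join_clades([ingroup, leaves["BBDP_Wor"]], 0.14)
    tree = _join_clades([tree, leaves["BN"]], 0.16)
    tree = _join_clades([tree, leaves["F344"]], 0.18)
    height = 0.18
    for i in range(extra):
        height += 0.015
        tree = _join_clades([tree, leaves[f"OUT{i + 1:02d}"]], height)
    root = tree[0]
    root.length = None
    return root


def strain_groups(panel_strains: list[str]) -> dict[str, str]:
    groups = {}
    for s in panel_strains:
        if s in CASE_CONSISTENT_STRAINS:
            groups[s] = "case_consistent"
        elif s in BACKGROUND_STRAINS:
            groups[s] = "control_background"
        else:
            groups[s] = "other"
    return groups


def generate_panel(
    cfg: SimConfig, tree: TreeNode | None = None
) -> tuple[PanelMatrix, TreeNode]:
    """Evolve homozygous panel genotypes along a tree by Bernoulli flips.

    Each branch flips each site's binary state (hom-ref vs hom-var) with
    probability equal to its length; leaves become '0/0'/'1/1' columns.  A
    zero-length tree yields identical strains.
    """
    rng = cfg.rng("panel")
    if tree is None:
        tree = default_panel_tree(cfg)
    n_sites = cfg.n_panel_sites
    chroms = sorted(cfg.chromosome_lengths)
    lengths = np.array([cfg.chromosome_lengths[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(n_sites, lengths / lengths.sum())
    sites: list[tuple[str, int]] = []
    for chrom, k in zip(chroms, alloc):
        for p in _sample_positions(rng, cfg.chromosome_lengths[chrom], int(k)):
            sites.append((chrom, int(p)))

    states: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, state: np.ndarray) -> None:
        for child in node.children:
            p_flip = min(max(child.length or 0.0, 0.0), 0.5)
            flips = rng.random(n_sites) < p_flip
            child_state = state ^ flips
            if child.is_tip():
                states[child.name] = child_state
            else:
                descend(child, child_state)

    root_state = np.zeros(n_sites, dtype=bool)
    if tree.is_tip():
        states[tree.name] = root_state
    else:
        descend(tree, root_state)

    strains = sorted(states)
    data = {s: np.where(states[s], "1/1", "0/0") for s in strains}
    index = pd.MultiIndex.from_tuples(sites, names=["chromosome", "position"])
    matrix = pd.DataFrame(data, index=index)
    return PanelMatrix(genotypes=matrix, groups=strain_groups(strains)), tree


def inject_focal_sites(
    panel: PanelMatrix,
    pav_records: list[VariantRecord],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[PanelMatrix, set[tuple[str, int]]]:
    """Add the focal PAV sites to the panel with planted filter outcomes.

    A fraction ``panel_candidate_fraction`` of homozygous PAV sites is made
    consistent (case clade homozygous-variant, background homozygous-
    reference) and should survive the consistency filter; the rest are
    sabotaged either in the case clade or by a background strain carrying
    the variant.  Returns the extended panel and the set of sites planted
    to survive.
    """
    matrix = panel.genotypes[~panel.genotypes.index.isin(
        [r.site for r in pav_records])]
    strains = panel.strains
    rows: dict[tuple[str, int], dict[str, str]] = {}
    surviving: set[tuple[str, int]] = set()
    case_strains = [s for s in strains if s in CASE_CONSISTENT_STRAINS]
    backgrounds = [s for s in strains if s in BACKGROUND_STRAINS]
    others = [s for s in strains if s not in CASE_CONSISTENT_STRAINS
              and s not in BACKGROUND_STRAINS]
    for r in pav_records:
        row = {}
        case_gt = r.genotypes[CASE]
        for s in others:
            if s == CASE:
                row[s] = case_gt
            elif s == CONTROL and CONTROL in r.genotypes:
                row[s] = r.genotypes[CONTROL]
            else:
                row[s] = "1/1" if rng.random() < 0.2 else "0/0"
        if not r.is_homozygous_variant(CASE):
            for s in case_strains + backgrounds:
                row[s] = "0/1" if rng.random() < 0.5 else "0/0"
            rows[r.site] = row
            continue
        alt = r.alleles_of(CASE)[0]
        hom = f"{alt}/{alt}"
        if rng.random() < cfg.panel_candidate_fraction:
            for s in case_strains:
                row[s] = hom
            for s in backgrounds:
                row[s] = "0/0"
            surviving.add(r.site)
        else:
            if rng.random() < 0.5 and case_strains:
                # break case-clade consistency
                for s in case_strains:
                    row[s] = str(rng.choice(["0/0", "0/1", "./."]))
                for s in backgrounds:
                    row[s] = "0/0"
            else:
                for s in case_strains:
                    row[s] = hom
                leak = rng.integers(len(backgrounds))
                for i, s in enumerate(backgrounds):
                    row[s] = hom if i == leak else "0/0"
        rows[r.site] = row

    added = pd.DataFrame.from_dict(rows, orient="index", columns=strains)
    added.index = pd.MultiIndex.from_tuples(added.index,
                                            names=["chromosome", "position"])
    combined = pd.concat([matrix, added]).sort_index()
    return PanelMatrix(genotypes=combined, groups=dict(panel.groups)), surviving


# ---------------------------------------------------------------------------
# Gene models, annotations, SV/CNV, coverage


def generate_gene_models(cfg: SimConfig) -> list[GeneModel]:
    """Non-overlapping gene spans; a configurable fraction flagged OR."""
    rng = cfg.rng("genes")
    chroms = sorted(cfg.chromosome_lengths)
    lengths = np.array([cfg.chromosome_lengths[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(cfg.n_genes, lengths / lengths.sum())
    n_or = int(round(cfg.or_fraction * cfg.n_genes))
    or_flags = np.zeros(cfg.n_genes, dtype=bool)
    or_flags[rng.choice(cfg.n_genes, size=n_or, replace=False)] = True
    genes: list[GeneModel] = []
    gene_index = 0
    or_index = 0
    for chrom, k in zip(chroms, alloc):
        k = int(k)
        if k == 0:
            continue
        slot = cfg.chromosome_lengths[chrom] // k
        for j in range(k):
            max_len = max(2_000, min(50_000, slot - 2))
            gene_len = int(rng.integers(2_000, max_len + 1))
            start = j * slot + int(rng.integers(0, max(1, slot - gene_len)))
            if or_flags[gene_index]:
                or_index += 1
                gene_id = f"Olr{or_index:03d}"
            else:
                gene_id = f"Gene{gene_index + 1:04d}"
            genes.append(
                GeneModel(gene_id=gene_id, chromosome=chrom, start=start,
                          end=start + gene_len,
                          is_olfactory_receptor=bool(or_flags[gene_index]))
            )
            gene_index += 1
    return genes


_BACKGROUND_REGION_PROBS = {
    "UTR": 0.004, "intronic": 0.23, "upstream": 0.01, "downstream": 0.01,
    "intergenic": 0.736, "exonic": 0.01,
}
_BACKGROUND_EXONIC_EFFECTS = ("synonymous",)


def generate_annotations(
    cfg: SimConfig,
    snv_records: list[VariantRecord],
    indel_records: list[VariantRecord],
    genes: list[GeneModel],
    truth: GroundTruth,
) -> dict[tuple[str, int], FunctionalAnnotation]:
    """ANNOVAR-style annotations with planted protein-affecting variants.

    ``cfg.n_pav_snvs`` homozygous case-specific SNV sites (clean of QC
    failures) become nonsynonymous/stopgain/splicing/ncRNA PAVs assigned
    to genes, ``or_pav_fraction`` of them to OR genes;
    ``cfg.n_het_pav_snvs`` heterozygous specific sites become PAVs too
    (the paper-style het side list).  Everything else gets background
    classes.  Indel PAVs become frameshifts.
    """
    rng = cfg.rng("annotations")
    bad_sites = set(truth.qc_fail_sites) | set(truth.cluster_sites)
    or_genes = [g.gene_id for g in genes if g.is_olfactory_receptor]
    non_or = [g.gene_id for g in genes if not g.is_olfactory_receptor]

    hom_pool = [
        r for r in snv_records
        if truth.true_group_per_variant[_site_key(*r.site)] in ("Group2", "Group3",
                                                                "Group4")
        and r.is_homozygous_variant(CASE)
        and _site_key(*r.site) not in bad_sites
    ]
    het_pool = [
        r for r in snv_records
        if truth.true_group_per_variant[_site_key(*r.site)] in ("Group1", "Group5")
        and _site_key(*r.site) not in bad_sites
    ]
    n_pav = min(cfg.n_pav_snvs, len(hom_pool))
    n_het_pav = min(cfg.n_het_pav_snvs, len(het_pool))
    pav_records = [hom_pool[i] for i in
                   sorted(rng.choice(len(hom_pool), size=n_pav, replace=False))]
    het_pav_records = [het_pool[i] for i in
                       sorted(rng.choice(len(het_pool), size=n_het_pav,
                                         replace=False))]

    annotations: dict[tuple[str, int], FunctionalAnnotation] = {}
    pav_effects = ("nonsynonymous", "stopgain", "splicing", "ncRNA_exonic")
    pav_probs = (0.85, 0.05, 0.05, 0.05)
    n_or_pav = int(round(cfg.or_pav_fraction * n_pav))
    for i, r in enumerate(pav_records + het_pav_records):
        gene_id = (str(rng.choice(or_genes)) if i < n_or_pav
                   else str(rng.choice(non_or)))
        effect = str(rng.choice(pav_effects, p=pav_probs))
        if effect in ("splicing", "ncRNA_exonic"):
            region, exonic_effect = effect, "."
        else:
            region, exonic_effect = "exonic", effect
        sift = str(rng.choice(["tolerated", "deleterious"], p=[0.8, 0.2])) \
            if exonic_effect == "nonsynonymous" else "."
        annotations[r.site] = FunctionalAnnotation(
            chromosome=r.chromosome, position=r.position, gene_id=gene_id,
            region_class=region, exonic_effect=exonic_effect, sift_call=sift,
        )
        truth.pav_sites.append(_site_key(*r.site))

    region_names = list(_BACKGROUND_REGION_PROBS)
    region_p = np.array(list(_BACKGROUND_REGION_PROBS.values()))
    all_genes = [g.gene_id for g in genes]
    for r in snv_records + indel_records:
        if r.site in annotations:
            continue
        region = str(rng.choice(region_names, p=region_p))
        if region == "exonic":
            effect = "synonymous"
        else:
            effect = "."
        gene_id = "." if region == "intergenic" else str(rng.choice(all_genes))
        annotations[r.site] = FunctionalAnnotation(
            chromosome=r.chromosome, position=r.position, gene_id=gene_id,
            region_class=region, exonic_effect=effect, sift_call=".",
        )
    return annotations


def generate_features(cfg: SimConfig, genes: list[GeneModel]) -> tuple[
        list[IntervalFeature], GroundTruth]:
    """SV and CNV intervals; a fraction of CNVs planted as differential."""
    rng = cfg.rng("features")
    chroms = sorted(cfg.chromosome_lengths)
    features: list[IntervalFeature] = []
    sv_kinds = ("SV-deletion", "SV-inversion", "SV-tandem-duplication",
                "SV-translocation-breakpoint")
    truth = GroundTruth()
    for _ in range(cfg.n_svs):
        chrom = str(rng.choice(chroms))
        length = int(rng.integers(1_000, 100_000))
        start = int(rng.integers(0, cfg.chromosome_lengths[chrom] - length))
        features.append(IntervalFeature(
            chromosome=chrom, start=start, end=start + length,
            feature_kind=str(rng.choice(sv_kinds, p=(0.6, 0.1, 0.25, 0.05))),
        ))
    n_diff = int(round(cfg.cnv_differential_fraction * cfg.n_cnvs))
    for i in range(cfg.n_cnvs):
        chrom = str(rng.choice(chroms))
        length = int(rng.integers(5_000, 200_000))
        start = int(rng.integers(0, cfg.chromosome_lengths[chrom] - length))
        differential = i < n_diff
        if differential:
            ratio = float(rng.uniform(2.2, 5.0)) if rng.random() < 0.5 \
                else float(rng.uniform(0.1, 0.45))
            p_value = float(10 ** rng.uniform(-8, -5))
            truth.differential_cnv_count += 1
        else:
            ratio = float(np.exp(rng.normal(0.0, 0.2)))
            p_value = float(rng.uniform(0.05, 1.0))
        kind = "CNV-gain" if ratio > 1 else "CNV-loss"
        features.append(IntervalFeature(
            chromosome=chrom, start=start, end=start + length,
            feature_kind=kind, ratio=ratio, p_value=p_value,
        ))
    return features, truth


def generate_coverage(cfg: SimConfig) -> pd.DataFrame:
    """Per-interval read-depth track (BEDGRAPH frame), ~3% low-coverage."""
    rng = cfg.rng("coverage")
    chunk = 50_000
    rows = []
    for chrom in sorted(cfg.chromosome_lengths):
        length = cfg.chromosome_lengths[chrom]
        for start in range(0, length, chunk):
            end = min(start + chunk, length)
            depth = int(rng.integers(0, 3)) if rng.random() < 0.03 \
                else int(rng.poisson(13))
            rows.append((chrom, start, end, depth))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "depth"])


# ---------------------------------------------------------------------------
# PPI + prior genes, expression, truth panel


def generate_ppi_and_prior(
    cfg: SimConfig,
    genes: list[str],
    planted_enriched: list[str] | None = None,
    prior_overlap: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str], GroundTruth]:
    """PPI edge list with planted prior-gene enrichment around designated
    genes, plus the prior gene list.

    Background edges are uniform over the universe; each planted gene gets
    ``planted_partner_count`` partners of which a ``planted_prior_prob``
    fraction are prior genes (well above the background prior fraction).
    ``prior_overlap`` genes are appended to the prior list itself.
    """
    rng = cfg.rng("ppi")
    universe = list(dict.fromkeys(
        list(genes) + [f"Univ{i:04d}" for i in range(cfg.ppi_universe_size)]
    ))
    prior_pool = [g for g in universe if g not in set(genes)]
    prior = sorted(
        str(prior_pool[i]) for i in
        rng.choice(len(prior_pool), size=cfg.prior_gene_count, replace=False)
    )
    if prior_overlap:
        prior = sorted(set(prior) | set(prior_overlap))
    prior_set = set(prior)
    non_prior = [g for g in universe if g not in prior_set]

    truth = GroundTruth()
    edges: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str) -> None:
        if a != b:
            edges.add((min(a, b), max(a, b)))

    planted = list(planted_enriched or [])
    truth.true_enriched_genes = sorted(planted)
    n_prior_partners = int(round(cfg.planted_prior_prob
                                 * cfg.planted_partner_count))
    for gene in planted:
        # exact partner composition: enrichment strength is by construction
        chosen_prior = rng.choice(len(prior), size=min(n_prior_partners,
                                                       len(prior)),
                                  replace=False)
        pool = [g for g in non_prior if g != gene]
        chosen_other = rng.choice(
            len(pool),
            size=cfg.planted_partner_count - len(chosen_prior),
            replace=False)
        for i in chosen_prior:
            add_edge(gene, str(prior[int(i)]))
        for i in chosen_other:
            add_edge(gene, str(pool[int(i)]))
    while len(edges) < cfg.ppi_n_edges + cfg.planted_partner_count * len(planted):
        a = str(universe[rng.integers(len(universe))])
        b = str(universe[rng.integers(len(universe))])
        if a in planted or b in planted:
            continue
        add_edge(a, b)

    rows = [(a, b, float(np.round(rng.uniform(0.401, 0.999), 3)))
            for a, b in sorted(edges)]
    edge_df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    return edge_df, prior, truth


def generate_expression(
    cfg: SimConfig, gene_ids: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Log-normal expression with planted DE fold-changes and planted
    correlation flips, for both strains across tissues and time points."""
    rng = cfg.rng("expression")
    truth = GroundTruth()
    de = dict(cfg.planted_de_genes or {})
    dc = dict(cfg.planted_dc_genes or {})
    truth.true_de_genes = {g: dict(v) for g, v in de.items()}
    truth.true_dc_genes = {g: dict(v) for g, v in dc.items()}

    samples, meta_rows = [], []
    for strain in (CASE, CONTROL):
        for tissue in cfg.tissues:
            for time in cfg.time_points:
                for i in range(cfg.expr_samples_per_condition):
                    name = f"{strain}_{tissue}_t{time}_r{i + 1}"
                    samples.append(name)
                    meta_rows.append((name, strain, tissue, time))
    meta = pd.DataFrame(meta_rows, columns=["sample", "strain", "tissue",
                                            "time"]).set_index("sample")

    base = rng.normal(cfg.expr_log2_mean, 1.0, size=len(gene_ids))
    log2 = np.empty((len(gene_ids), len(samples)))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    n = cfg.expr_samples_per_condition
    col = 0
    for strain in (CASE, CONTROL):
        for tissue in cfg.tissues:
            for time in cfg.time_points:
                block = base[:, None] + rng.normal(
                    0.0, cfg.expr_log2_sigma, size=(len(gene_ids), n))
                for g, spec in de.items():
                    if spec["tissue"] == tissue and strain == CASE:
                        block[gene_index[g]] += np.log2(spec["fold_change"])
                for g, spec in dc.items():
                    if spec["tissue"] != tissue:
                        continue
                    rho = spec["rho_case"] if strain == CASE else spec["rho_control"]
                    gi, pi = gene_index[g], gene_index[spec["partner"]]
                    z = rng.normal(size=(2, n))
                    shared = z[0]
                    other = rho * shared + np.sqrt(1 - rho ** 2) * z[1]
                    block[gi] = base[gi] + cfg.expr_log2_sigma * shared
                    block[pi] = base[pi] + cfg.expr_log2_sigma * other
                log2[:, col : col + n] = block
                col += n
    values = pd.DataFrame(2.0 ** log2, index=gene_ids, columns=samples)
    values.index.name = "gene"
    return values, meta, truth


def generate_truth_panel(
    cfg: SimConfig, called_sites: set[tuple[str, int]]
) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """Known polymorphic / non-polymorphic positions for validation.

    Truth-variant positions are drawn so that a ``truth_sensitivity``
    fraction is actually called; truth-invariant positions so that a
    ``truth_specificity`` fraction is call-free.
    """
    rng = cfg.rng("truth_panel")
    called = sorted(called_sites)
    chroms = sorted(cfg.chromosome_lengths)
    used = {p for _, p in called_sites}

    n_called_truth = min(int(round(cfg.truth_sensitivity * cfg.n_truth_variant)),
                         len(called))
    picks = rng.choice(len(called), size=n_called_truth, replace=False)
    truth_variant = {called[int(i)] for i in picks}
    while len(truth_variant) < cfg.n_truth_variant:
        chrom = str(rng.choice(chroms))
        pos = int(rng.integers(1, cfg.chromosome_lengths[chrom] + 1))
        if (chrom, pos) not in called_sites:
            truth_variant.add((chrom, pos))

    n_false_positive = int(round((1 - cfg.truth_specificity)
                                 * cfg.n_truth_invariant))
    remaining = [s for s in called if s not in truth_variant]
    truth_invariant: set[tuple[str, int]] = set()
    if remaining and n_false_positive:
        picks = rng.choice(len(remaining),
                           size=min(n_false_positive, len(remaining)),
                           replace=False)
        truth_invariant = {remaining[int(i)] for i in picks}
    while len(truth_invariant) < cfg.n_truth_invariant:
        chrom = str(rng.choice(chroms))
        pos = int(rng.integers(1, cfg.chromosome_lengths[chrom] + 1))
        if (chrom, pos) not in called_sites and (chrom, pos) not in truth_variant:
            truth_invariant.add((chrom, pos))
    return truth_variant, truth_invariant


# ---------------------------------------------------------------------------
# Whole-study generation


def simulate_all(cfg: SimConfig, outdir: str | Path) -> tuple[dict, GroundTruth]:
    """Generate every pipeline input under `outdir`; returns (paths, truth).

    Output is byte-identical for identical configs (fixed orderings, seeded
    substreams).
    """
    from . import prioritize, variant_filters

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    planting_rng = cfg.rng("planting")

    snv_records, indel_records, truth = generate_focal_records(cfg)
    genes = generate_gene_models(cfg)
    annotations = generate_annotations(cfg, snv_records, indel_records, genes, truth)

    # PAV records that pass the hard filters, for panel planting
    passed_snvs, _ = variant_filters.filter_snvs(snv_records, indel_records)
    pav_records = [
        r for r in passed_snvs
        if r.site in annotations and prioritize.flag_pav(annotations[r.site]).is_pav
    ]

    panel, tree = generate_panel(cfg)
    panel, surviving = inject_focal_sites(panel, pav_records, cfg, planting_rng)
    truth.surviving_pav_sites = sorted(_site_key(*s) for s in surviving)
    truth.true_tree_newick = str(tree)

    gene_models = {g.gene_id: g for g in genes}
    candidate_genes = sorted({
        annotations[s].gene_id for s in surviving
        if not gene_models[annotations[s].gene_id].is_olfactory_receptor
    })
    truth.candidate_genes = candidate_genes

    # plant downstream evidence on the recoverable candidate genes
    pool = list(candidate_genes)
    planting_rng.shuffle(pool)
    if cfg.planted_enriched_genes is not None:
        enriched = list(cfg.planted_enriched_genes)
    else:
        enriched = sorted(pool[: cfg.n_planted_enriched])
    prior_overlap = sorted(
        pool[cfg.n_planted_enriched : cfg.n_planted_enriched
             + cfg.n_prior_candidate_genes]
    )
    truth.prior_candidate_genes = prior_overlap

    edge_df, prior, ppi_truth = generate_ppi_and_prior(
        cfg, [g.gene_id for g in genes], planted_enriched=enriched,
        prior_overlap=prior_overlap,
    )
    truth.true_enriched_genes = ppi_truth.true_enriched_genes

    de_cfg = cfg.planted_de_genes
    dc_cfg = cfg.planted_dc_genes
    remaining = [g for g in pool if g not in set(enriched) | set(prior_overlap)]
    if de_cfg is None:
        de_cfg = {
            g: {"tissue": cfg.tissues[i % len(cfg.tissues)],
                "fold_change": cfg.de_fold_change}
            for i, g in enumerate(sorted(remaining[: cfg.n_de_planted]))
        }
    if dc_cfg is None:
        dc_pool = sorted(remaining[cfg.n_de_planted : cfg.n_de_planted
                                   + cfg.n_dc_planted])
        partner_candidates = [g.gene_id for g in genes
                              if not g.is_olfactory_receptor
                              and g.gene_id not in set(dc_pool)]
        partners = sorted(partner_candidates)[-len(dc_pool):] if dc_pool else []
        dc_cfg = {
            g: {"partner": partners[i], "tissue": cfg.tissues[i % len(cfg.tissues)],
                "rho_case": cfg.dc_rho_case, "rho_control": cfg.dc_rho_control}
            for i, g in enumerate(dc_pool)
        }
    expr_cfg = dataclasses.replace(cfg, planted_de_genes=de_cfg,
                                   planted_dc_genes=dc_cfg)
    values, meta, expr_truth = generate_expression(
        expr_cfg, [g.gene_id for g in genes])
    truth.true_de_genes = expr_truth.true_de_genes
    truth.true_dc_genes = expr_truth.true_dc_genes

    features, feature_truth = generate_features(cfg, genes)
    truth.differential_cnv_count = feature_truth.differential_cnv_count
    coverage = generate_coverage(cfg)

    called = {r.site for r in passed_snvs if r.is_variant(CASE)}
    truth_variant, truth_invariant = generate_truth_panel(cfg, called)

    paths = {
        "vcf": outdir / "focal.vcf",
        "panel": outdir / "panel.tsv",
        "panel_groups": outdir / "panel_groups.tsv",
        "genes": outdir / "genes.bed",
        "annotations": outdir / "annotations.tsv",
        "ppi": outdir / "ppi_edges.tsv",
        "prior": outdir / "prior_genes.txt",
        "expression": outdir / "expression.tsv",
        "expression_meta": outdir / "expression_meta.tsv",
        "coverage": outdir / "coverage.bedgraph",
        "features": outdir / "features.tsv",
        "truth_panel": outdir / "truth_panel.tsv",
        "tree": outdir / "true_tree.nwk",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "sim_config.yaml",
    }
    formats_io.write_vcf(snv_records + indel_records, paths["vcf"],
                         samples=[CASE, CONTROL],
                         contigs=cfg.chromosome_lengths)
    formats_io.write_panel(panel, paths["panel"], paths["panel_groups"])
    formats_io.write_genes_bed(genes, paths["genes"])
    formats_io.write_annotations(annotations, paths["annotations"])
    formats_io.write_ppi_edges(edge_df, paths["ppi"])
    formats_io.write_gene_list(prior, paths["prior"])
    values.round(4).to_csv(paths["expression"], sep="\t")
    meta.to_csv(paths["expression_meta"], sep="\t")
    formats_io.write_bedgraph(coverage, paths["coverage"])
    formats_io.write_features(features, paths["features"])
    formats_io.write_truth_panel(truth_variant, truth_invariant,
                                 paths["truth_panel"])
    formats_io.write_newick(tree, paths["tree"])
    formats_io.write_json(truth.to_dict(), paths["ground_truth"])
    cfg.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}, truth
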