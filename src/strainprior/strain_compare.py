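"""Case-specific variant derivation, genotype-group classification and QC.

A case/control genotype pair falls into one of five groups (diploid codes,
alleles unordered):

====== ============= ================
group  case          control
====== ============= ================
Group1 0/1           0/0
Group2 1/1           0/0
Group3 1/1           0/1
Group4 1/2           0/0
Group5 1/2           0/1
====== ============= ================

Any other pair — including sites where either genotype is missing — is
``NotSpecific``.  Groups 4 and 5 require a multi-allelic site kept whole.

Percentages are reported to two decimals, rounding half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .formats_io import MISSING_GT, VariantRecord, genotype_alleles, normalize_genotype

GROUP_LABELS = ("Group1", "Group2", "Group3", "Group4", "Group5")
NOT_SPECIFIC = "NotSpecific"

_GROUP_PATTERNS = {
    ("0/1", "0/0"): "Group1",
    ("1/1", "0/0"): "Group2",
    ("1/1", "0/1"): "Group3",
    ("1/2", "0/0"): "Group4",
    ("1/2", "0/1"): "Group5",
}

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def percentage(numerator: int, denominator: int, ndigits: int = 2) -> float | None:
    """numerator/denominator as a percentage, rounded half away from zero."""
    if denominator == 0:
        return None
    pct = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def titv_ratio(n_transitions: int, n_transversions: int, ndigits: int = 2) -> float:
    """Transition/transversion ratio rounded to `ndigits` decimals."""
    ratio = Decimal(n_transitions) / Decimal(n_transversions)
    return float(ratio.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' (A<->G, C<->T) or 'transversion' for a single-base change."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return "transition" if (ref, alt) in TRANSITIONS else "transversion"


@dataclass
class GenotypeGroup:
    """Classification of one (case, control) genotype pair."""

    label: str
    case_genotype: str
    control_genotype: str

    @property
    def is_specific(self) -> bool:
        return self.label != NOT_SPECIFIC


def classify_group(case_gt: str, control_gt: str) -> GenotypeGroup:
    """Classify a (case, control) genotype pair into the five groups.

    Genotype codes are normalized first ("1|0" -> "0/1"); missing alleles
    on either side yield NotSpecific; allele indices above 2 are an error
    (the scheme covers at most two alternate alleles at one site).
    """
    case = normalize_genotype(case_gt)
    control = normalize_genotype(control_gt)
    for gt in (case, control):
        alleles = genotype_alleles(gt)
        if alleles and max(alleles) > 2:
            raise ValueError(f"allele index above 2 in genotype {gt}")
    label = _GROUP_PATTERNS.get((case, control), NOT_SPECIFIC)
    return GenotypeGroup(label=label, case_genotype=case, control_genotype=control)


@dataclass
class CompareStats:
    """Per-callset summary of a case/control comparison.

    ``n_transitions``/``n_transversions`` and the homozygosity figures are
    computed over the case strain's variant sites in the full input callset
    (per-strain QC statistics); the group counts are over the derived
    case-specific subset only.
    """

    case: str
    control: str
    n_specific_snvs: int = 0
    n_specific_indels: int = 0
    snv_group_counts: dict[str, int] = field(default_factory=dict)
    indel_group_counts: dict[str, int] = field(default_factory=dict)
    n_case_variant_snvs: int = 0
    n_homozygous: int = 0
    homozygosity_pct: float | None = None
    n_transitions: int = 0
    n_transversions: int = 0
    titv: float | None = None

    def group_percentages(self, table: str = "snv") -> dict[str, float | None]:
        counts = self.snv_group_counts if table == "snv" else self.indel_group_counts
        total = sum(counts.values())
        return {g: percentage(counts.get(g, 0), total) for g in GROUP_LABELS}

    def as_dict(self) -> dict:
        return {
            "case": self.case,
            "control": self.control,
            "n_specific_snvs": self.n_specific_snvs,
            "n_specific_indels": self.n_specific_indels,
            "snv_group_counts": dict(sorted(self.snv_group_counts.items())),
            "indel_group_counts": dict(sorted(self.indel_group_counts.items())),
            "n_case_variant_snvs": self.n_case_variant_snvs,
            "n_homozygous": self.n_homozygous,
            "homozygosity_pct": self.homozygosity_pct,
            "n_transitions": self.n_transitions,
            "n_transversions": self.n_transversions,
            "titv": self.titv,
        }


def count_titv(records: list[VariantRecord], strain: str) -> tuple[int, int]:
    """Transitions/transversions over the alternate alleles a strain carries.

    Counted per allele for multi-allelic sites: each distinct alternate
    allele index in the strain's genotype contributes one substitution.
    Non-SNV records are ignored.
    """
    ti = tv = 0
    for r in records:
        if not r.is_snv:
            continue
        for a in r.alt_indices_of(strain):
            kind = classify_substitution(r.ref_allele, r.alt_alleles[a - 1])
            if kind == "transition":
                ti += 1
            else:
                tv += 1
    return ti, tv


def homozygosity(records: list[VariantRecord], strain: str) -> tuple[int, float | None]:
    """Homozygous count and percentage among the strain's variant sites.

    A site counts as a variant site for the strain when its genotype carries
    at least one alternate allele; it is homozygous when both alleles are
    the same alternate (a/a, a >= 1).  With zero variant sites the
    percentage is undefined (None), not zero.
    """
    n_variant = n_hom = 0
    for r in records:
        if r.is_variant(strain):
            n_variant += 1
            if r.is_homozygous_variant(strain):
                n_hom += 1
    return n_hom, percentage(n_hom, n_variant)


def derive_specific(
    records: list[VariantRecord], case: str, control: str
) -> tuple[list[VariantRecord], CompareStats]:
    """Select case-specific records (groups 1-5) and compute CompareStats."""
    specific: list[VariantRecord] = []
    stats = CompareStats(case=case, control=control)
    snv_records_for_titv: list[VariantRecord] = []
    for r in records:
        group = classify_group(r.genotypes.get(case, MISSING_GT),
                               r.genotypes.get(control, MISSING_GT))
        if group.is_specific:
            specific.append(r)
            counts = stats.snv_group_counts if r.is_snv else stats.indel_group_counts
            counts[group.label] = counts.get(group.label, 0) + 1
        if r.is_snv and r.is_variant(case):
            snv_records_for_titv.append(r)
    stats.n_specific_snvs = sum(stats.snv_group_counts.values())
    stats.n_specific_indels = sum(stats.indel_group_counts.values())
    stats.n_homozygous, stats.homozygosity_pct = homozygosity(
        snv_records_for_titv, case
    )
    stats.n_case_variant_snvs = len(snv_records_for_titv)
    stats.n_transitions, stats.n_transversions = count_titv(snv_records_for_titv, case)
    if stats.n_transversions:
        stats.titv = titv_ratio(stats.n_transitions, stats.n_transversions)
    return specific, stats


@dataclass
class ValidationResult:
    """Sensitivity/specificity of a callset against a truth panel."""

    n_truth_variant_sites: int
    n_called_at_truth_variant_sites: int
    sensitivity_pct: float | None
    n_truth_invariant_sites: int
    n_confirmed_invariant: int
    specificity_pct: float | None

    def as_dict(self) -> dict:
        return {
            "n_truth_variant_sites": self.n_truth_variant_sites,
            "n_called_at_truth_variant_sites": self.n_called_at_truth_variant_sites,
            "sensitivity_pct": self.sensitivity_pct,
            "n_truth_invariant_sites": self.n_truth_invariant_sites,
            "n_confirmed_invariant": self.n_confirmed_invariant,
            "specificity_pct": self.specificity_pct,
        }


def validate_against_truth(
    called_sites: set[tuple[str, int]],
    truth_variant: set[tuple[str, int]],
    truth_invariant: set[tuple[str, int]],
) -> ValidationResult:
    """Sensitivity = called fraction of truth-variant positions; specificity
    = call-free fraction of truth-invariant positions.  Both x100, 2 d.p.;
    an empty truth set makes the corresponding statistic undefined (None).
    """
    overlap = truth_variant & truth_invariant
    if overlap:
        raise ValueError(f"positions in both truth sets, e.g. {sorted(overlap)[0]}")
    n_called = len(called_sites & truth_variant)
    n_confirmed = len(truth_invariant - called_sites)
    return ValidationResult(
        n_truth_variant_sites=len(truth_variant),
        n_called_at_truth_variant_sites=n_called,
        sensitivity_pct=percentage(n_called, len(truth_variant)),
        n_truth_invariant_sites=len(truth_invariant),
        n_confirmed_invariant=n_confirmed,
        specificity_pct=percentage(n_confirmed, len(truth_invariant)),
    )
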