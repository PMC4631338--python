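"""Post-calling hard filters for SNVs, small indels and differential CNVs.

All rules are conjunctive, so the surviving set does not depend on the
order in which rules are evaluated; only the per-rule attribution in the
report does (a removed record is charged to the first rule it fails).

SNV defaults: per-sample total depth >= 10, called-allele number = 4 (both
diploid samples fully called), base quality >= 30, quality-by-depth >= 5,
at most 4 reads with mapping quality zero, not on an indel footprint
(reference span +/- 1 base) and not in an SNV cluster (>= 3 candidate SNVs
inside any 10-bp window; every member of such a window is removed).
Indel defaults: depth >= 8 and allele number = 4.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .formats_io import IntervalFeature, VariantRecord

SNV_THRESHOLDS = {
    "min_depth": 10,
    "allele_number": 4,
    "min_base_quality": 30,
    "min_quality_by_depth": 5,
    "max_zero_mapq": 4,
    "cluster_window": 10,
    "cluster_count": 3,
    "indel_pad": 1,
}

INDEL_THRESHOLDS = {"min_depth": 8, "allele_number": 4}

SNV_RULE_ORDER = (
    "missing_qc",
    "depth",
    "allele_number",
    "base_quality",
    "quality_by_depth",
    "zero_mapq",
    "indel_region",
    "snv_cluster",
)

_QC_KEYS = ("depth", "allele_number", "base_quality", "quality_by_depth",
            "zero_mapq_count")


@dataclass
class FilterReport:
    """Accounting for one filter pass; removals attributed first-failing-rule."""

    n_input: int
    n_passed: int
    counts_per_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_input != self.n_passed + sum(self.counts_per_rule.values()):
            raise ValueError("filter report does not reconcile")

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_passed": self.n_passed,
            "counts_per_rule": dict(sorted(self.counts_per_rule.items())),
        }


def snv_cluster_sites(
    records: list[VariantRecord], window: int = 10, min_count: int = 3
) -> set[tuple[str, int]]:
    """Sites belonging to any ``window``-base window holding >= min_count SNVs.

    Equivalent to sliding a window of `window` consecutive bases over each
    chromosome and flagging every SNV inside any window that contains at
    least `min_count` of them: with sorted positions, any run of min_count
    consecutive candidates spanning <= window-1 bases marks all its members.
    """
    by_chrom: dict[str, list[int]] = {}
    for r in records:
        by_chrom.setdefault(r.chromosome, []).append(r.position)
    clustered: set[tuple[str, int]] = set()
    for chrom, positions in by_chrom.items():
        positions = sorted(set(positions))
        for i in range(len(positions) - min_count + 1):
            if positions[i + min_count - 1] - positions[i] <= window - 1:
                for p in positions[i : i + min_count]:
                    clustered.add((chrom, p))
    return clustered


def indel_footprints(
    indels: list[VariantRecord], pad: int = 1
) -> dict[str, tuple[list[int], list[int]]]:
    """Merged padded reference footprints of indels, per chromosome.

    Footprint of an indel at 1-based position p with reference allele of
    length L is [p - pad, p + L - 1 + pad], inclusive.  Returned as parallel
    sorted start/end lists for bisection.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    for r in indels:
        start = r.position - pad
        end = r.position + len(r.ref_allele) - 1 + pad
        raw.setdefault(r.chromosome, []).append((start, end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, intervals in raw.items():
        intervals.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in intervals:
            if ends and s <= ends[-1] + 1:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (starts, ends)
    return merged


def _in_footprint(
    footprints: dict[str, tuple[list[int], list[int]]], chrom: str, pos: int
) -> bool:
    if chrom not in footprints:
        return False
    starts, ends = footprints[chrom]
    i = bisect_right(starts, pos) - 1
    return i >= 0 and pos <= ends[i]


def _first_failing_rule(record, checks: dict, order) -> str | None:
    for rule in order:
        if not checks[rule](record):
            return rule
    return None


def filter_snvs(
    records: list[VariantRecord],
    indels: list[VariantRecord] = (),
    thresholds: dict | None = None,
    rule_order: tuple[str, ...] = SNV_RULE_ORDER,
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the SNV hard filters; returns survivors and a FilterReport.

    ``indels`` are the raw indel calls whose padded reference footprints
    disqualify overlapping SNVs.  A record with any QC field missing fails
    with rule 'missing_qc' rather than silently passing.
    """
    t = {**SNV_THRESHOLDS, **(thresholds or {})}
    clustered = snv_cluster_sites(records, t["cluster_window"], t["cluster_count"])
    footprints = indel_footprints(list(indels), t["indel_pad"])

    checks = {
        "missing_qc": lambda r: all(k in r.site_qc for k in _QC_KEYS),
        "depth": lambda r: r.site_qc.get("depth", 0) >= t["min_depth"],
        "allele_number": lambda r: r.site_qc.get("allele_number") == t["allele_number"],
        "base_quality": lambda r: r.site_qc.get("base_quality", 0) >= t["min_base_quality"],
        "quality_by_depth": lambda r: r.site_qc.get("quality_by_depth", 0)
        >= t["min_quality_by_depth"],
        "zero_mapq": lambda r: r.site_qc.get("zero_mapq_count", 0) <= t["max_zero_mapq"],
        "indel_region": lambda r: not _in_footprint(footprints, r.chromosome, r.position),
        "snv_cluster": lambda r: r.site not in clustered,
    }
    if set(rule_order) != set(SNV_RULE_ORDER):
        raise ValueError("rule_order must be a permutation of the SNV rules")

    passed: list[VariantRecord] = []
    counts: dict[str, int] = {}
    for r in records:
        rule = _first_failing_rule(r, checks, rule_order)
        if rule is None:
            passed.append(r)
        else:
            counts[rule] = counts.get(rule, 0) + 1
    return passed, FilterReport(len(records), len(passed), counts)


def filter_indels(
    records: list[VariantRecord], thresholds: dict | None = None
) -> tuple[list[VariantRecord], FilterReport]:
    """Indel hard filter: depth >= 8 (inclusive) and allele number = 4."""
    t = {**INDEL_THRESHOLDS, **(thresholds or {})}
    checks = {
        "missing_qc": lambda r: all(k in r.site_qc for k in ("depth", "allele_number")),
        "depth": lambda r: r.site_qc.get("depth", 0) >= t["min_depth"],
        "allele_number": lambda r: r.site_qc.get("allele_number") == t["allele_number"],
    }
    order = ("missing_qc", "depth", "allele_number")
    passed: list[VariantRecord] = []
    counts: dict[str, int] = {}
    for r in records:
        rule = _first_failing_rule(r, checks, order)
        if rule is None:
            passed.append(r)
        else:
            counts[rule] = counts.get(rule, 0) + 1
    return passed, FilterReport(len(records), len(passed), counts)


def filter_differential_cnv(
    features: list[IntervalFeature],
    n_tests: int,
    ratio_threshold: float = 2.0,
    alpha: float = 0.01,
) -> tuple[list[IntervalFeature], FilterReport]:
    """Differential-CNV post-filter.

    A region passes iff its case/control mapped-read ratio exceeds the
    threshold in either direction (ratio > 2 or ratio < 1/2) and its
    Bonferroni-adjusted p-value (raw p x n_tests) is below alpha.
    """
    passed: list[IntervalFeature] = []
    counts: dict[str, int] = {}

    def fail(rule: str) -> None:
        counts[rule] = counts.get(rule, 0) + 1

    for f in features:
        if f.ratio is None:
            fail("missing_ratio")
        elif not (f.ratio > ratio_threshold or f.ratio < 1.0 / ratio_threshold):
            fail("ratio")
        elif f.p_value is None:
            fail("missing_p")
        elif not f.p_value * n_tests < alpha:
            fail("adjusted_p")
        else:
            passed.append(f)
    return passed, FilterReport(len(features), len(passed), counts)
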