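"""Variant density in fixed-width genomic bins, normalized by coverage.

Density in a bin is the number of variants divided by the number of bases
in the bin covered by at least three reads; bins with zero covered bases
have undefined density (None) but are retained.  The bin grid is anchored
at coordinate 0 on each chromosome; the last partial bin keeps its true
width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .formats_io import VariantRecord

DEFAULT_BIN_SIZE = 1_000_000
MIN_COVER_DEPTH = 3


@dataclass
class DensityBin:
    """One genomic window (0-based half-open) with its variant density."""

    chromosome: str
    start: int
    end: int
    n_variants: int
    n_covered_bases: int
    density: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.n_covered_bases <= self.end - self.start:
            raise ValueError("covered bases outside bin width")


def covered_bases_per_bin(
    coverage: pd.DataFrame,
    chromosome_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    min_depth: int = MIN_COVER_DEPTH,
) -> dict[tuple[str, int], int]:
    """Aggregate a per-interval depth track to covered-base counts per bin.

    ``coverage`` is a BEDGRAPH-style frame (chromosome, start, end, depth,
    0-based half-open); bases with depth >= min_depth count as covered.
    """
    counts: dict[tuple[str, int], int] = {}
    for row in coverage.itertuples(index=False):
        if row.depth < min_depth:
            continue
        length = chromosome_lengths.get(row.chromosome)
        if length is None:
            raise ValueError(f"coverage on unknown chromosome {row.chromosome}")
        start, end = max(0, int(row.start)), min(int(row.end), length)
        pos = start
        while pos < end:
            bin_start = (pos // bin_size) * bin_size
            chunk_end = min(end, bin_start + bin_size)
            key = (row.chromosome, bin_start)
            counts[key] = counts.get(key, 0) + (chunk_end - pos)
            pos = chunk_end
    return counts


def profile(
    variants: list[VariantRecord],
    covered: dict[tuple[str, int], int],
    chromosome_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> list[DensityBin]:
    """Tile every chromosome with bins and count variants per bin.

    Variant positions (1-based) are converted to 0-based before binning; a
    variant beyond its chromosome's stated length is a coordinate mismatch
    and fatal.
    """
    counts: dict[tuple[str, int], int] = {}
    for v in variants:
        length = chromosome_lengths.get(v.chromosome)
        if length is None:
            raise ValueError(f"variant on unknown chromosome {v.chromosome}")
        pos0 = v.position - 1
        if pos0 >= length:
            raise ValueError(
                f"variant {v.chromosome}:{v.position} beyond chromosome length {length}"
            )
        key = (v.chromosome, (pos0 // bin_size) * bin_size)
        counts[key] = counts.get(key, 0) + 1

    bins: list[DensityBin] = []
    for chrom in sorted(chromosome_lengths):
        length = chromosome_lengths[chrom]
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            n_var = counts.get((chrom, start), 0)
            n_cov = covered.get((chrom, start), 0)
            density = n_var / n_cov if n_cov > 0 else None
            bins.append(DensityBin(chrom, start, end, n_var, n_cov, density))
    return bins


def correlate_densities(
    snv_bins: list[DensityBin], indel_bins: list[DensityBin]
) -> tuple[float, float]:
    """Pearson correlation of two aligned density profiles -> (r, r^2).

    Bins with undefined density in either profile are excluded pairwise;
    fewer than three complete pairs is an error.
    """
    if len(snv_bins) != len(indel_bins):
        raise ValueError("density profiles are not aligned")
    pairs = [
        (a.density, b.density)
        for a, b in zip(snv_bins, indel_bins)
        if a.density is not None and b.density is not None
    ]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} complete bin pairs; need >= 3")
    x, y = zip(*pairs)
    r = stats.pearsonr(x, y).statistic
    return float(r), float(r * r)


def _overlaps_gap(b: DensityBin, gap_mask: dict[str, list[tuple[int, int]]]) -> bool:
    for s, e in gap_mask.get(b.chromosome, ()):
        if b.start < e and s < b.end:
            return True
    return False


def extreme_bins(
    bins: list[DensityBin],
    fraction: float = 0.05,
    gap_mask: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[list[DensityBin], list[DensityBin]]:
    """Top- and bottom-``fraction`` density bins.

    k = ceil(fraction * n) over the bins with defined density; low-density
    bins overlapping an assembly-gap interval are removed before taking the
    bottom list.  Ties break on (chromosome, start) so output is stable.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    gap_mask = gap_mask or {}
    eligible = [b for b in bins if b.density is not None]
    if not eligible:
        return [], []
    k = math.ceil(fraction * len(eligible))
    top = sorted(eligible, key=lambda b: (-b.density, b.chromosome, b.start))[:k]
    bottom_pool = [b for b in eligible if not _overlaps_gap(b, gap_mask)]
    bottom = sorted(bottom_pool, key=lambda b: (b.density, b.chromosome, b.start))[:k]
    return top, bottom


def variant_deserts(bins: list[DensityBin], floor: float = 0.0) -> list[DensityBin]:
    """Bins with density at or below `floor` — descriptive output only."""
    return [b for b in bins if b.density is not None and b.density <= floor]
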