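"""Net nucleotide substitution distances and UPGMA strain trees.

The pairwise distance is Nei's dA: between-strain divergence minus mean
within-strain diversity,

    dA = mean(pi_XY) - (mean(pi_X) + mean(pi_Y)) / 2

where, per site, pi_XY is the probability that an allele drawn from one
strain differs from an allele drawn from the other, and pi_X is the
within-strain heterozygosity.  Sites missing in either strain are excluded
(pairwise deletion); the result is floored at 0.

UPGMA merges the closest pair of clusters, with size-weighted
arithmetic-mean distance updates and node heights at half the merge
distance; ties break on the lexicographically smallest member label so the
tree is deterministic.
"""

from __future__ import annotations

import math

import numpy as np
from skbio import TreeNode

from .formats_io import MISSING_GT, PanelMatrix, genotype_alleles


def _pi_between(a: tuple[int, int], b: tuple[int, int]) -> float:
    return sum(x != y for x in a for y in b) / 4.0


def _pi_within(a: tuple[int, int]) -> float:
    return 0.0 if a[0] == a[1] else 0.5


def net_distance(panel: PanelMatrix, strain_a: str, strain_b: str) -> float:
    """Nei's dA between two strains over their shared genotyped sites."""
    col_a = panel.genotypes[strain_a]
    col_b = panel.genotypes[strain_b]
    pi_xy = pi_x = pi_y = 0.0
    n = 0
    for ga, gb in zip(col_a, col_b):
        if ga == MISSING_GT or gb == MISSING_GT:
            continue
        a = genotype_alleles(ga)
        b = genotype_alleles(gb)
        pi_xy += _pi_between(a, b)
        pi_x += _pi_within(a)
        pi_y += _pi_within(b)
        n += 1
    if n == 0:
        raise ValueError(f"no shared genotyped sites for {strain_a} and {strain_b}")
    return max(0.0, pi_xy / n - (pi_x / n + pi_y / n) / 2.0)


def distance_matrix(panel: PanelMatrix) -> tuple[list[str], np.ndarray]:
    """All-pairs net-distance matrix (symmetric, zero diagonal)."""
    labels = panel.strains
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = net_distance(panel, labels[i], labels[j])
    return labels, d


def upgma(matrix: np.ndarray, labels: list[str]) -> TreeNode:
    """Build an ultrametric UPGMA tree from a distance matrix.

    Cluster distances are size-weighted arithmetic means; each internal
    node sits at half the distance at which its children merged.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != matrix.shape[1] or matrix.shape[0] != len(labels):
        raise ValueError("matrix and labels do not agree")
    if len(labels) < 2:
        raise ValueError("need at least two strains")
    if not np.isfinite(matrix).all():
        raise ValueError("non-finite distance entries")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")

    clusters: dict[int, dict] = {
        i: {"node": TreeNode(name=label), "size": 1, "height": 0.0,
            "min_label": label}
        for i, label in enumerate(labels)
    }
    dist: dict[frozenset, float] = {
        frozenset((i, j)): float(matrix[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    while len(clusters) > 1:
        # deterministic argmin: smallest distance, then smallest member labels
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted(clusters[i]["min_label"] for i in kv[0])),
            ),
        )
        (pair, d) = best
        i, j = sorted(pair)
        ci, cj = clusters.pop(i), clusters.pop(j)
        height = d / 2.0
        ci["node"].length = height - ci["height"]
        cj["node"].length = height - cj["height"]
        children = sorted([ci, cj], key=lambda c: c["min_label"])
        new = {
            "node": TreeNode(children=[c["node"] for c in children]),
            "size": ci["size"] + cj["size"],
            "height": height,
            "min_label": min(ci["min_label"], cj["min_label"]),
        }
        for k in list(clusters):
            d_ik = dist.pop(frozenset((i, k)))
            d_jk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (
                ci["size"] * d_ik + cj["size"] * d_jk
            ) / new["size"]
        del dist[pair]
        clusters[next_id] = new
        next_id += 1
    root = next(iter(clusters.values()))["node"]
    root.length = None
    return root


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    """All leaves equidistant from the root within `tol`."""
    depths = [
        sum(a.length or 0.0 for a in tip.ancestors() if a.length is not None)
        + (tip.length or 0.0)
        for tip in tree.tips()
    ]
    return math.isclose(min(depths), max(depths), abs_tol=tol)


def robinson_foulds(a: TreeNode, b: TreeNode) -> float:
    """Unrooted Robinson–Foulds distance between two trees."""
    return float(a.compare_rfd(b))
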