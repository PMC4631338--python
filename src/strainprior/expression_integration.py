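"""Differential expression and differential co-expression between strains.

Expression is compared per (tissue, time point) cell.  DE uses a Welch
two-sample t-test with a direction-symmetric fold-change rule
(p <= 0.01 and max(FC, 1/FC) > 2).  Differential co-expression uses a
Fisher-z differential-correlation score ("dcz"): for each gene, the mean
over partner genes of |z_case - z_control| where z = arctanh(r), with a
permutation null over condition labels and Bonferroni correction across
the gene set (adjusted p <= 0.05).  Per-time-point calls are combined by
union: a gene is differential in a tissue if it is called at any time
point, and differential overall if called in any tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DC_STATISTIC_NAME = "dcz"


@dataclass
class ExpressionSet:
    """Genes x samples intensity matrix with per-sample metadata.

    ``values`` holds positive intensities (linear scale unless
    ``log_scale``); ``meta`` is indexed by sample with columns strain,
    tissue, time.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if set(self.values.columns) != set(self.meta.index):
            raise ValueError("expression samples and metadata do not match")
        for col in ("strain", "tissue", "time"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks column {col!r}")
            if self.meta[col].isna().any():
                raise ValueError(f"metadata column {col!r} has missing labels")

    @classmethod
    def from_files(cls, matrix_path, meta_path, log_scale: bool = False):
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values=values, meta=meta, log_scale=log_scale)

    @property
    def tissues(self) -> list:
        return sorted(self.meta["tissue"].unique())

    @property
    def times(self) -> list:
        return sorted(self.meta["time"].unique())

    def condition_samples(self, tissue, time, strain) -> list[str]:
        mask = (
            (self.meta["tissue"] == tissue)
            & (self.meta["time"] == time)
            & (self.meta["strain"] == strain)
        )
        return list(self.meta.index[mask])


@dataclass
class DEResult:
    gene: str
    tissue: str
    time: object
    p_value: float
    fold_change: float
    is_de: bool


@dataclass
class DCResult:
    gene: str
    tissue: str
    time: object
    dc_statistic: float
    p_value: float
    adjusted_p: float
    is_dc: bool


def differential_expression(
    exprs: ExpressionSet,
    tissue,
    time,
    case: str,
    control: str,
    p_threshold: float = 0.01,
    fc_threshold: float = 2.0,
) -> list[DEResult]:
    """Welch t-test + fold-change call for every gene in one cell.

    Fold change is the ratio of linear-scale condition means (case over
    control); for log-scale matrices FC = 2^(mean difference).  Degenerate
    zero-variance cells: equal means give p = 1, unequal means give p = 0
    and the call falls to the fold-change rule alone.
    """
    case_samples = exprs.condition_samples(tissue, time, case)
    control_samples = exprs.condition_samples(tissue, time, control)
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError(
            f"cell ({tissue}, {time}) needs >= 2 samples per condition"
        )
    x = exprs.values[case_samples].to_numpy(dtype=float)
    y = exprs.values[control_samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(x, y, axis=1, equal_var=False).pvalue
    mean_x, mean_y = x.mean(axis=1), y.mean(axis=1)
    degenerate = np.isnan(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes with zero variance in both groups "
            f"in cell ({tissue}, {time})",
            stacklevel=2,
        )
        p = np.where(degenerate & np.isclose(mean_x, mean_y), 1.0, p)
        p = np.where(np.isnan(p), 0.0, p)
    if exprs.log_scale:
        fc = 2.0 ** (mean_x - mean_y)
    else:
        fc = mean_x / mean_y
    results = []
    for gene, p_g, fc_g in zip(exprs.values.index, p, fc):
        symmetric_fc = max(fc_g, 1.0 / fc_g) if fc_g > 0 else np.inf
        results.append(
            DEResult(
                gene=gene,
                tissue=tissue,
                time=time,
                p_value=float(p_g),
                fold_change=float(fc_g),
                is_de=bool(p_g <= p_threshold and symmetric_fc > fc_threshold),
            )
        )
    return results


def _fisher_z_matrix(data: np.ndarray) -> np.ndarray:
    """Fisher-z transformed correlation matrix of rows of `data`."""
    r = np.corrcoef(data)
    r = np.clip(r, -0.999999, 0.999999)
    return np.arctanh(r)


def _dc_statistics(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Per-gene mean |z_case - z_control| over all partner genes."""
    dz = np.abs(_fisher_z_matrix(case) - _fisher_z_matrix(control))
    np.fill_diagonal(dz, 0.0)
    return dz.sum(axis=1) / (dz.shape[0] - 1)


def differential_coexpression(
    exprs: ExpressionSet,
    tissue,
    time,
    gene_set: list[str],
    case: str,
    control: str,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[DCResult]:
    """Fisher-z differential co-expression with a permutation null.

    The p-value for each gene is the label-permutation tail probability of
    its dcz statistic, (1 + #{perm >= observed}) / (1 + B); Bonferroni
    correction is over the full gene set.  Genes constant within either
    condition are skipped with a warning; a gene set of size < 2 has no
    partners and yields an empty result.
    """
    if len(gene_set) < 2:
        return []
    case_samples = exprs.condition_samples(tissue, time, case)
    control_samples = exprs.condition_samples(tissue, time, control)
    if len(case_samples) < 4 or len(control_samples) < 4:
        raise ValueError(
            f"cell ({tissue}, {time}) needs >= 4 samples per condition for DC"
        )
    genes = [g for g in gene_set if g in exprs.values.index]
    data_case = exprs.values.loc[genes, case_samples].to_numpy(dtype=float)
    data_control = exprs.values.loc[genes, control_samples].to_numpy(dtype=float)

    constant = (np.std(data_case, axis=1) == 0) | (np.std(data_control, axis=1) == 0)
    if constant.any():
        skipped = [g for g, c in zip(genes, constant) if c]
        warnings.warn(f"constant genes skipped in DC: {skipped}", stacklevel=2)
        keep = ~constant
        genes = [g for g, k in zip(genes, keep) if k]
        data_case = data_case[keep]
        data_control = data_control[keep]
    if len(genes) < 2:
        return []

    observed = _dc_statistics(data_case, data_control)

    rng = np.random.default_rng(seed)
    combined = np.hstack([data_case, data_control])
    n_case = data_case.shape[1]
    n_total = combined.shape[1]
    exceed = np.zeros(len(genes))
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        perm_stats = _dc_statistics(
            combined[:, perm[:n_case]], combined[:, perm[n_case:]]
        )
        exceed += perm_stats >= observed
    p = (1.0 + exceed) / (1.0 + n_permutations)
    m = len(gene_set)  # Bonferroni over the requested set, skipped genes included
    adjusted = np.minimum(1.0, p * m)
    return [
        DCResult(
            gene=g,
            tissue=tissue,
            time=time,
            dc_statistic=float(s),
            p_value=float(p_g),
            adjusted_p=float(ap),
            is_dc=bool(ap <= alpha),
        )
        for g, s, p_g, ap in zip(genes, observed, p, adjusted)
    ]


def combine_timepoints(
    de_results: list[DEResult], dc_results: list[DCResult]
) -> dict[str, dict]:
    """Union per-cell calls into per-gene flags.

    A gene is DE (DC) in a tissue iff flagged at any time point there, and
    differential overall iff flagged in at least one tissue.
    """
    flags: dict[str, dict] = {}

    def entry(gene: str) -> dict:
        return flags.setdefault(
            gene, {"de_tissues": set(), "dc_tissues": set(), "is_differential": False}
        )

    for r in de_results:
        if r.is_de:
            entry(r.gene)["de_tissues"].add(r.tissue)
    for r in dc_results:
        if r.is_dc:
            entry(r.gene)["dc_tissues"].add(r.tissue)
    for gene, f in flags.items():
        f["de_tissues"] = sorted(f["de_tissues"])
        f["dc_tissues"] = sorted(f["dc_tissues"])
        f["is_differential"] = bool(f["de_tissues"] or f["dc_tissues"])
    return flags
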