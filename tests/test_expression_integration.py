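"""DE and DC calls, degenerate handling, and per-time-point combination."""

import numpy as np
import pandas as pd
import pytest

from strainprior import expression_integration as ei


def build_exprs(values: np.ndarray, genes, case_n, control_n, tissue="liver",
                time=1, log_scale=False):
    samples = [f"GK_{i}" for i in range(case_n)] + \
              [f"WI_{i}" for i in range(control_n)]
    meta = pd.DataFrame(
        {"strain": ["GK"] * case_n + ["WISTAR"] * control_n,
         "tissue": tissue, "time": time},
        index=pd.Index(samples, name="sample"),
    )
    return ei.ExpressionSet(
        values=pd.DataFrame(values, index=genes, columns=samples),
        meta=meta, log_scale=log_scale,
    )


class TestExpressionSet:
    def test_metadata_must_cover_samples(self):
        values = pd.DataFrame(np.ones((1, 2)), index=["g"], columns=["a", "b"])
        meta = pd.DataFrame({"strain": ["GK"], "tissue": ["liver"],
                             "time": [1]}, index=["a"])
        with pytest.raises(ValueError, match="do not match"):
            ei.ExpressionSet(values=values, meta=meta)


class TestDifferentialExpression:
    def test_planted_fourfold_gene_flagged(self):
        rng = np.random.default_rng(0)
        base = 100.0
        case = base * 4 * (1 + 0.1 * rng.standard_normal(5))
        control = base * (1 + 0.1 * rng.standard_normal(5))
        values = np.vstack([np.concatenate([case, control]),
                            base * (1 + 0.1 * rng.standard_normal(10))])
        exprs = build_exprs(values, ["planted", "null"], 5, 5)
        results = {r.gene: r for r in ei.differential_expression(
            exprs, "liver", 1, "GK", "WISTAR")}
        assert results["planted"].is_de
        assert not results["null"].is_de

    def test_identical_groups_not_de(self):
        identical = build_exprs(np.ones((1, 8)), ["g"], 4, 4)
        with pytest.warns(UserWarning, match="zero variance"):
            (r,) = ei.differential_expression(identical, "liver", 1, "GK",
                                              "WISTAR")
        assert not r.is_de and r.p_value == 1.0

    def test_zero_variance_unequal_means_falls_to_fc_rule(self):
        values = np.array([[8.0] * 4 + [2.0] * 4, [3.0] * 4 + [2.0] * 4])
        exprs = build_exprs(values, ["big", "small"], 4, 4)
        results = {r.gene: r for r in ei.differential_expression(
            exprs, "liver", 1, "GK", "WISTAR")}
        assert results["big"].is_de and results["big"].p_value == 0.0
        assert not results["small"].is_de  # FC 1.5 below threshold

    def test_fold_change_rule_symmetric_under_label_swap(self):
        rng = np.random.default_rng(3)
        values = np.exp(rng.normal(4, 0.5, size=(20, 10)))
        exprs = build_exprs(values, [f"g{i}" for i in range(20)], 5, 5)
        forward = ei.differential_expression(exprs, "liver", 1, "GK", "WISTAR")
        backward = ei.differential_expression(exprs, "liver", 1, "WISTAR", "GK")
        for f, b in zip(forward, backward):
            assert f.fold_change == pytest.approx(1.0 / b.fold_change)
            assert f.is_de == b.is_de

    def test_log_scale_fold_change(self):
        values = np.array([[10.0] * 3 + [8.0] * 3])  # log2 diff 2 -> FC 4
        values = values + np.array([[0, 0.01, -0.01, 0, 0.01, -0.01]])
        exprs = build_exprs(values, ["g"], 3, 3, log_scale=True)
        (r,) = ei.differential_expression(exprs, "liver", 1, "GK", "WISTAR")
        assert r.fold_change == pytest.approx(4.0, rel=0.05)

    def test_too_few_samples_error(self):
        exprs = build_exprs(np.ones((1, 3)), ["g"], 1, 2)
        with pytest.raises(ValueError, match=">= 2 samples"):
            ei.differential_expression(exprs, "liver", 1, "GK", "WISTAR")

    def test_null_type_one_rate(self):
        rng = np.random.default_rng(12)
        n_genes = 2000
        values = np.exp(rng.normal(4, 0.3, size=(n_genes, 10)))
        exprs = build_exprs(values, [f"g{i}" for i in range(n_genes)], 5, 5)
        results = ei.differential_expression(exprs, "liver", 1, "GK", "WISTAR")
        n_small_p = sum(r.p_value <= 0.01 for r in results)
        sigma = np.sqrt(n_genes * 0.01 * 0.99)
        assert abs(n_small_p - n_genes * 0.01) <= 3 * sigma
        # the joint DE rule adds a 4-sigma fold-change requirement: ~none pass
        assert sum(r.is_de for r in results) <= 3


def planted_dc_exprs(rho_case, rho_control, n, seed=0, extra_genes=4):
    rng = np.random.default_rng(seed)
    def block(rho, n):
        z = rng.standard_normal((2, n))
        partner = rho * z[0] + np.sqrt(1 - rho ** 2) * z[1]
        rows = [z[0], partner]
        rows += [rng.standard_normal(n) for _ in range(extra_genes)]
        return 2.0 ** (8 + 0.3 * np.vstack(rows))
    values = np.hstack([block(rho_case, n), block(rho_control, n)])
    genes = ["dcgene", "partner"] + [f"bg{i}" for i in range(extra_genes)]
    return build_exprs(values, genes, n, n)


class TestDifferentialCoexpression:
    def test_planted_rho_flip_flagged(self):
        # the mean-over-partners statistic dilutes with gene-set size, so
        # the power condition uses a focused set around the planted pair
        exprs = planted_dc_exprs(0.9, -0.9, n=20, seed=1, extra_genes=2)
        results = {r.gene: r for r in ei.differential_coexpression(
            exprs, "liver", 1, list(exprs.values.index), "GK", "WISTAR",
            n_permutations=499, seed=2)}
        assert results["dcgene"].is_dc
        assert results["partner"].is_dc

    def test_null_background_not_flagged(self):
        exprs = planted_dc_exprs(0.5, 0.5, n=20, seed=3)
        results = ei.differential_coexpression(
            exprs, "liver", 1, list(exprs.values.index), "GK", "WISTAR",
            n_permutations=199, seed=4)
        assert not any(r.is_dc for r in results)

    def test_gene_set_of_one_empty(self):
        exprs = planted_dc_exprs(0.5, 0.5, n=8, seed=5)
        assert ei.differential_coexpression(
            exprs, "liver", 1, ["dcgene"], "GK", "WISTAR") == []

    def test_constant_gene_skipped_with_warning(self):
        exprs = planted_dc_exprs(0.5, 0.5, n=8, seed=6)
        exprs.values.loc["bg0"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            results = ei.differential_coexpression(
                exprs, "liver", 1, list(exprs.values.index), "GK", "WISTAR",
                n_permutations=99, seed=7)
        assert "bg0" not in {r.gene for r in results}

    def test_permutation_p_reproducible_under_seed(self):
        exprs = planted_dc_exprs(0.8, -0.2, n=10, seed=8)
        kwargs = dict(n_permutations=199, seed=11)
        a = ei.differential_coexpression(
            exprs, "liver", 1, list(exprs.values.index), "GK", "WISTAR",
            **kwargs)
        b = ei.differential_coexpression(
            exprs, "liver", 1, list(exprs.values.index), "GK", "WISTAR",
            **kwargs)
        assert [r.p_value for r in a] == [r.p_value for r in b]

    def test_too_few_samples_error(self):
        exprs = planted_dc_exprs(0.5, 0.5, n=3, seed=9)
        with pytest.raises(ValueError, match=">= 4 samples"):
            ei.differential_coexpression(
                exprs, "liver", 1, list(exprs.values.index), "GK", "WISTAR")


class TestCombineTimepoints:
    def _de(self, gene, tissue, time, is_de):
        return ei.DEResult(gene, tissue, time, 0.001, 5.0, is_de)

    def _dc(self, gene, tissue, time, is_dc):
        return ei.DCResult(gene, tissue, time, 1.0, 0.001, 0.01, is_dc)

    def test_single_timepoint_suffices(self):
        flags = ei.combine_timepoints(
            [self._de("g", "liver", 3, True),
             self._de("g", "liver", 1, False)], [])
        assert flags["g"]["de_tissues"] == ["liver"]
        assert flags["g"]["is_differential"]

    def test_never_flagged_absent(self):
        flags = ei.combine_timepoints([self._de("g", "liver", 1, False)], [])
        assert "g" not in flags

    def test_tissue_recorded_per_evidence_kind(self):
        flags = ei.combine_timepoints(
            [self._de("g", "liver", 1, True)],
            [self._dc("g", "muscle", 2, True)])
        assert flags["g"]["de_tissues"] == ["liver"]
        assert flags["g"]["dc_tissues"] == ["muscle"]
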