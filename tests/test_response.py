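"""Welch tests, BH adjustment, the two-way factorial model and the
per-time-point response clustering rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from omicnets import SimConfig, gen_expression
from omicnets.response import (welch_test, bh_adjust, fit_factorial,
                               cluster_responses, ResponseClusterer,
                               select_response_genes)
from omicnets.synthdata import ExpressionMatrix


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means_is_degenerate(self):
        t, p = welch_test([0, 0], [5, 5])
        assert p == 0.0 and np.isinf(t)

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1, 2])

    def test_matches_scipy_on_random_data(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 2, size=5)
        t, p = welch_test(a, b)
        ts, ps = stats.ttest_ind(a, b, equal_var=False)
        assert np.isclose(t, ts) and np.isclose(p, ps)

    def test_null_rejection_rate_calibrated(self, rng):
        a = rng.normal(size=(10000, 5))
        b = rng.normal(size=(10000, 5))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        assert 0.04 < (p < 0.05).mean() < 0.06


class TestBH:
    def test_hand_applied_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        assert bh_adjust([1.0]) == [1.0]

    def test_nan_propagates_and_is_excluded_from_m(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m = 2: q = [0.02, 0.04]
        assert np.allclose(q[[0, 2]], [0.02, 0.04])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_equivariance_and_dominance(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        perm = np.random.RandomState(0).permutation(len(ps))
        assert np.allclose(bh_adjust(np.asarray(ps)[perm]), q[perm])


class TestFactorial:
    def test_constant_gene_reports_p_one(self, small_expr):
        expr, _ = small_expr
        values = expr.values.copy()
        values.iloc[0] = 3.14
        res = fit_factorial(ExpressionMatrix(values, expr.metadata))
        row = res.iloc[0]
        assert row["treatment_p"] == 1.0 and row["interaction_p"] == 1.0

    def test_missing_cell_fails_with_listing(self, small_expr):
        expr, _ = small_expr
        keep = ~((expr.metadata["condition"] == "IL1B")
                 & (expr.metadata["timepoint"] == "P45"))
        sub = ExpressionMatrix(expr.values.loc[:, keep.values],
                               expr.metadata.loc[keep])
        with pytest.raises(ValueError, match="P45"):
            fit_factorial(sub)

    def test_matches_statsmodels_type_two_anova(self, small_expr):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        expr, _ = small_expr
        res = fit_factorial(expr)
        meta = expr.metadata
        for gi in (0, 7, 33):
            df = pd.DataFrame({"y": expr.values.iloc[gi].values,
                               "cond": meta["condition"].values,
                               "tp": meta["timepoint"].values})
            a = anova_lm(smf.ols("y ~ C(cond) * C(tp)", df).fit(), typ=2)
            row = res.iloc[gi]
            assert np.isclose(a.loc["C(cond)", "PR(>F)"],
                              row["treatment_p"], rtol=1e-8)
            assert np.isclose(a.loc["C(tp)", "PR(>F)"],
                              row["time_p"], rtol=1e-8)
            assert np.isclose(a.loc["C(cond):C(tp)", "PR(>F)"],
                              row["interaction_p"], rtol=1e-8)

    def test_planted_interaction_detected(self):
        hits = 0
        for seed in range(40):
            cfg = SimConfig(seed=seed, n_genes=60, cluster_effect=1.5,
                            n_samples_per_cell=8)
            expr, truth = gen_expression(cfg)
            res = fit_factorial(expr)
            up = [g for g, l in truth.cluster_membership.items()
                  if l == "up_P1"]
            hits += (res.loc[up, "interaction_q"] < 0.05).mean()
        assert hits / 40 > 0.9

    def test_permuted_labels_give_uniform_p(self, small_expr, rng):
        expr, _ = small_expr
        ps = []
        for _ in range(200):
            perm = rng.permutation(len(expr.samples))
            meta = expr.metadata.iloc[perm].set_axis(expr.metadata.index)
            res = fit_factorial(ExpressionMatrix(expr.values.iloc[:1], meta))
            ps.append(res["interaction_p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClusters:
    def test_constant_difference_gives_all_none(self, small_expr):
        expr, _ = small_expr
        values = expr.values.copy() * 0.0
        il1b = (expr.metadata["condition"] == "IL1B").values
        values.loc[:, il1b] = 1.0   # identical difference for every gene
        out = cluster_responses(ExpressionMatrix(values, expr.metadata))
        assert (out["z"] == 0).all()
        assert (out["label"] == "none").all()

    def test_condition_swap_flips_labels_exactly(self, small_expr):
        expr, _ = small_expr
        out = cluster_responses(expr)
        meta2 = expr.metadata.copy()
        meta2["condition"] = meta2["condition"].map(
            {"IL1B": "PBS", "PBS": "IL1B"})
        out2 = cluster_responses(ExpressionMatrix(expr.values, meta2))
        swap = {"up": "down", "down": "up", "none": "none"}
        assert (out2["label"].values == out["label"].map(swap).values).all()

    def test_planted_up_cluster_recovered(self, small_expr):
        expr, truth = small_expr
        out = cluster_responses(expr)
        p1 = out[out["timepoint"] == "P1"].set_index("gene")
        up = [g for g, l in truth.cluster_membership.items() if l == "up_P1"]
        nulls = [g for g, l in truth.cluster_membership.items()
                 if l == "null"]
        assert (p1.loc[up, "label"] == "up").mean() >= 0.8
        assert (p1.loc[nulls, "label"] != "none").mean() <= 0.1

    def test_single_gene_fails(self, small_expr):
        expr, _ = small_expr
        with pytest.raises(ValueError):
            cluster_responses(ExpressionMatrix(expr.values.iloc[:1],
                                               expr.metadata))

    def test_estimator_interface(self, small_expr):
        expr, _ = small_expr
        est = ResponseClusterer(fdr=0.2)
        assert est.get_params()["fdr"] == 0.2
        est.fit(expr)
        assert set(est.clusters_["label"]) <= {"up", "down", "none"}
        assert len(est.labels_at("P1")) == expr.values.shape[0]
        genes = select_response_genes(est.contrasts_, "interaction")
        assert len(genes) <= 500
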