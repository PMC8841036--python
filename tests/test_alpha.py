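import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microdepth import (CountTable, SoilVariables, ValidationError,
                        alpha_diversity, diversity_frame, fertility_index,
                        rf_importance, tukey_posthoc, two_way_anova)

from conftest import balanced_metadata


def _one_sample(counts):
    return CountTable(["s1"], [f"a{i}" for i in range(len(counts))],
                      np.array([counts]))


class TestAlphaDiversity:
    def test_uniform_community_evenness_one(self):
        rec = alpha_diversity(_one_sample([10, 10, 10, 10]))[0]
        assert rec.richness == 4
        assert rec.evenness == pytest.approx(1.0)

    def test_single_species_evenness_undefined(self):
        rec = alpha_diversity(_one_sample([100, 0, 0]))[0]
        assert rec.richness == 1
        assert not rec.evenness_defined
        assert math.isnan(rec.evenness)

    def test_closed_form_shannon_pielou(self):
        # H = -(0.97 ln 0.97 + 3 * 0.01 ln 0.01), J = H / ln 4
        rec = alpha_diversity(_one_sample([97, 1, 1, 1]))[0]
        assert rec.shannon == pytest.approx(0.16771, abs=1e-5)
        assert rec.evenness == pytest.approx(0.12098, abs=1e-5)

    def test_merging_equal_asvs_analytic_change(self):
        """Merging two equal-count ASVs drops S by 1 and changes H by the
        analytic merge term 2p ln 2 (each had probability p)."""
        before = alpha_diversity(_one_sample([40, 30, 15, 15]))[0]
        after = alpha_diversity(_one_sample([40, 30, 30]))[0]
        assert after.richness == before.richness - 1
        p = 15 / 100
        assert before.shannon - after.shannon == pytest.approx(2 * p * math.log(2))


def _anova_oracle(y, a_labels, b_labels):
    """Brute-force balanced two-way SS decomposition from cell means."""
    y = np.asarray(y, dtype=float)
    a_levels = sorted(set(a_labels))
    b_levels = sorted(set(b_labels))
    grand = y.mean()
    ss_a = sum((y[a_labels == a]).size * (y[a_labels == a].mean() - grand) ** 2
               for a in a_levels)
    ss_b = sum((y[b_labels == b]).size * (y[b_labels == b].mean() - grand) ** 2
               for b in b_levels)
    ss_cells = 0.0
    ss_resid = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = y[(a_labels == a) & (b_labels == b)]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
            ss_resid += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    return ss_a, ss_b, ss_ab, ss_resid


class TestTwoWayAnova:
    def test_matches_cell_mean_oracle(self):
        meta = balanced_metadata(n_plots=6, n_times=4)  # 3 x 4 x 6 design
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(size=len(meta.sample_ids)),
                      index=meta.sample_ids)
        res = two_way_anova(y, meta)
        a = meta.table["layer"].astype(str).to_numpy()
        b = meta.table["time"].astype(str).to_numpy()
        ss_a, ss_b, ss_ab, ss_resid = _anova_oracle(y.to_numpy(), a, b)
        terms = {t.term: t for t in res.terms}
        assert terms["layer"].ss == pytest.approx(ss_a, abs=1e-10)
        assert terms["time"].ss == pytest.approx(ss_b, abs=1e-10)
        assert terms["layer:time"].ss == pytest.approx(ss_ab, abs=1e-10)
        assert res.residual_ss == pytest.approx(ss_resid, abs=1e-10)
        f_a = (ss_a / terms["layer"].df) / (ss_resid / res.residual_df)
        assert terms["layer"].f == pytest.approx(f_a, rel=1e-10)

    def test_pure_factor_a_effect(self):
        meta = balanced_metadata(2, 2)
        layer = meta.table["layer"].astype(str)
        y = pd.Series(layer.map({"S": 1.0, "M": 2.0, "D": 3.0}).to_numpy(),
                      index=meta.sample_ids)
        # jitter one replicate (plot 2) per cell: residual variance without
        # touching time or interaction cell-mean contrasts
        y += 0.01 * (meta.table["plot"] == 2).to_numpy()
        res = two_way_anova(y, meta)
        terms = {t.term: t for t in res.terms}
        assert terms["time"].ss == pytest.approx(0.0, abs=1e-12)
        assert terms["layer:time"].ss == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_rejected(self):
        meta = balanced_metadata(2, 2)
        y = pd.Series(np.ones(len(meta.sample_ids)), index=meta.sample_ids)
        with pytest.raises(ValidationError):
            two_way_anova(y, meta)

    def test_unbalanced_rejected(self):
        meta = balanced_metadata(2, 2)
        y = pd.Series(np.arange(len(meta.sample_ids), dtype=float),
                      index=meta.sample_ids)
        with pytest.raises(ValidationError, match="unbalanced"):
            two_way_anova(y.iloc[:-1], meta)

    def test_ss_decomposition_sums_to_total(self):
        meta = balanced_metadata(3, 2)
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(size=len(meta.sample_ids)),
                      index=meta.sample_ids)
        res = two_way_anova(y, meta)
        total = ((y - y.mean()) ** 2).sum()
        parts = sum(t.ss for t in res.terms) + res.residual_ss
        assert parts == pytest.approx(total, abs=1e-9)
        assert sum(t.df for t in res.terms) + res.residual_df == len(y) - 1


class TestTukey:
    def test_two_groups_equals_pooled_t_test(self):
        meta = balanced_metadata(3, 2)
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=len(meta.sample_ids)),
                      index=meta.sample_ids)
        res = tukey_posthoc(y, meta, "time")
        labels = meta.table["time"].astype(str)
        g1 = y[(labels == "T1").to_numpy()]
        g2 = y[(labels == "T2").to_numpy()]
        t_p = stats.ttest_ind(g1, g2).pvalue
        assert res["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-9)

    def test_identical_means_p_near_one(self):
        meta = balanced_metadata(3, 2)
        # response depends on plot only: every layer sees the same values
        y = pd.Series(meta.table["plot"].astype(float).to_numpy(),
                      index=meta.sample_ids)
        res = tukey_posthoc(y, meta, "layer")
        assert (res["p_adj"] > 0.99).all()

    def test_shifted_group_detected(self):
        meta = balanced_metadata(4, 2)
        rng = np.random.default_rng(4)
        layer = meta.table["layer"].astype(str)
        y = pd.Series(rng.normal(size=len(meta.sample_ids)),
                      index=meta.sample_ids)
        y[(layer == "D").to_numpy()] += 5.0  # 5 sd shift
        res = tukey_posthoc(y, meta, "layer").set_index(["level_a", "level_b"])
        assert res.loc[("D", "S"), "p_adj"] < 0.001
        assert res.loc[("D", "M"), "p_adj"] < 0.001
        assert res.loc[("M", "S"), "p_adj"] > 0.05

    def test_single_level_rejected(self, toy_metadata):
        y = pd.Series([1.0, 2.0, 3.0], index=toy_metadata.sample_ids)
        with pytest.raises(ValidationError):
            tukey_posthoc(y, toy_metadata, "time")


def _soil(df):
    return SoilVariables(pd.DataFrame(df))


class TestFertilityIndex:
    def test_by_hand_four_samples(self):
        vals = {"TC": [1.0, 2.0, 3.0, 4.0], "TN": [2.0, 2.0, 4.0, 4.0],
                "DOC": [10.0, 20.0, 30.0, 40.0], "DON": [1.0, 1.0, 1.0, 5.0],
                "NH4": [1.0, 3.0, 5.0, 7.0], "NO3": [4.0, 3.0, 2.0, 1.0]}
        soil = _soil(vals)
        idx = fertility_index(soil)
        expect = np.zeros(4)
        for v in vals.values():
            v = np.asarray(v, dtype=float)
            expect += (v - v.mean()) / v.std(ddof=1)
        np.testing.assert_allclose(idx.to_numpy(), expect, atol=1e-12)
        assert idx.mean() == pytest.approx(0.0, abs=1e-12)

    def test_sample_at_cohort_mean_scores_zero(self):
        vals = {v: [1.0, 2.0, 3.0] for v in
                ("TC", "TN", "DOC", "DON", "NH4", "NO3")}
        idx = fertility_index(_soil(vals))
        assert idx.iloc[1] == pytest.approx(0.0, abs=1e-12)
        assert idx.iloc[0] == pytest.approx(-idx.iloc[2], abs=1e-12)

    def test_affine_rescaling_invariant(self):
        rng = np.random.default_rng(5)
        vals = {v: rng.uniform(1, 10, size=6) for v in
                ("TC", "TN", "DOC", "DON", "NH4", "NO3")}
        idx1 = fertility_index(_soil(vals))
        vals2 = dict(vals)
        vals2["DOC"] = vals["DOC"] * 1000.0 + 37.0  # unit change
        idx2 = fertility_index(_soil(vals2))
        np.testing.assert_allclose(idx1.to_numpy(), idx2.to_numpy(), atol=1e-9)

    def test_zero_variance_variable_named(self):
        vals = {v: [1.0, 2.0] for v in ("TC", "TN", "DOC", "DON", "NH4", "NO3")}
        vals["NH4"] = [3.0, 3.0]
        with pytest.raises(ValidationError, match="NH4"):
            fertility_index(_soil(vals))


class TestRFImportance:
    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["x1", "x2"])
        y = X["x1"].copy()
        recs = {r.predictor: r
                for r in rf_importance(X, y, n_trees=100,
                                       n_response_permutations=19, seed=0)}
        assert recs["x1"].importance > recs["x2"].importance
        assert recs["x1"].p_value <= 0.05

    def test_deterministic_and_column_order_invariant(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        y = pd.Series(rng.normal(size=30), index=X.index)
        r1 = rf_importance(X, y, 30, 9, seed=3)
        r2 = rf_importance(X, y, 30, 9, seed=3)
        r3 = rf_importance(X[["c", "a", "b"]], y, 30, 9, seed=3)
        as_dict = lambda rs: {r.predictor: (r.importance, r.p_value) for r in rs}
        assert as_dict(r1) == as_dict(r2) == as_dict(r3)

    def test_preconditions(self):
        X = pd.DataFrame(np.ones((5, 2)), columns=["a", "b"])
        y = pd.Series(np.arange(5.0), index=X.index)
        with pytest.raises(ValidationError):
            rf_importance(X, y)  # too few samples
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 2)),
                         columns=["a", "b"])
        with pytest.raises(ValidationError):
            rf_importance(X, pd.Series(np.ones(12), index=X.index))
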