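"""Group statistics: regressions, mixed ANOVA, Bonferroni post-hocs."""

import numpy as np
import pandas as pd
import pytest

from munet import bonferroni_posthoc, mixed_anova, regress_r2
from munet.errors import InvalidDesignError, UndefinedR2Error
from munet.stats import regression_table


def make_table(rng, n_groups=2, per_group=4, group_shift=0.0,
               condition_shift=0.0):
    rows = []
    sid = 0
    for gi in range(n_groups):
        for _ in range(per_group):
            sid += 1
            base = rng.normal() + gi * group_shift
            for ci, cond in enumerate(("rest", "prehension")):
                rows.append({"subject_id": f"s{sid}", "group": f"G{gi + 1}",
                             "age": float(gi), "impf": 8.0 + gi,
                             "condition": cond,
                             "y": base + ci * condition_shift + rng.normal()})
    return pd.DataFrame(rows)


def split_plot_oracle(tbl, dv="y"):
    """Hand sums-of-squares decomposition of a balanced group x condition
    design with condition repeated within subject."""
    wide = tbl.pivot_table(index=["subject_id", "group"], columns="condition",
                           values=dv).reset_index()
    y = wide[["rest", "prehension"]].to_numpy()
    groups = wide["group"].to_numpy()
    labels = sorted(set(groups))
    grand = y.mean()
    n_cond = 2
    subj_mean = y.mean(axis=1)
    group_mean = {g: y[groups == g].mean() for g in labels}
    n_per = {g: (groups == g).sum() for g in labels}

    ss_group = n_cond * sum(n_per[g] * (group_mean[g] - grand) ** 2
                            for g in labels)
    ss_subj = n_cond * sum((subj_mean[i] - group_mean[groups[i]]) ** 2
                           for i in range(len(y)))
    cond_mean = y.mean(axis=0)
    n_subj = len(y)
    ss_cond = n_subj * ((cond_mean - grand) ** 2).sum()
    ss_inter = 0.0
    for g in labels:
        cell = y[groups == g].mean(axis=0)
        ss_inter += n_per[g] * ((cell - group_mean[g] - cond_mean + grand) ** 2
                                ).sum()
    ss_resid = 0.0
    for i in range(n_subj):
        g = groups[i]
        cell = y[groups == g].mean(axis=0)
        ss_resid += ((y[i] - cell - subj_mean[i] + group_mean[g]) ** 2).sum()

    df_group, df_subj = len(labels) - 1, n_subj - len(labels)
    df_cond = n_cond - 1
    f_group = (ss_group / df_group) / (ss_subj / df_subj)
    f_cond = (ss_cond / df_cond) / (ss_resid / df_subj)
    f_inter = (ss_inter / (df_group * df_cond)) / (ss_resid / df_subj)
    ss_total = ((y - grand) ** 2).sum()
    return {"F": (f_group, f_cond, f_inter),
            "eta": (ss_group / (ss_group + ss_subj),
                    ss_cond / (ss_cond + ss_resid),
                    ss_inter / (ss_inter + ss_resid)),
            "ss_total": ss_total,
            "ss_parts": ss_group + ss_subj + ss_cond + ss_inter + ss_resid}


class TestRegressR2:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        assert regress_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_predictor_small_r2(self):
        rng = np.random.default_rng(0)
        r2s = [regress_r2(rng.normal(size=30), rng.normal(size=30))
               for _ in range(100)]
        assert np.mean(r2s) < 0.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedR2Error):
            regress_r2(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            regress_r2(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestMixedAnova:
    def test_matches_hand_decomposition(self):
        rng = np.random.default_rng(5)
        tbl = make_table(rng, n_groups=3, per_group=5, group_shift=0.8,
                         condition_shift=0.4)
        oracle = split_plot_oracle(tbl)
        res = {r.effect: r for r in mixed_anova(tbl, "y")}
        for i, effect in enumerate(["group", "condition",
                                    "group x condition"]):
            assert res[effect].F == pytest.approx(oracle["F"][i], rel=1e-9)
            assert res[effect].eta_p2 == pytest.approx(oracle["eta"][i],
                                                       rel=1e-9)
        # the split-plot decomposition is exhaustive
        assert oracle["ss_parts"] == pytest.approx(oracle["ss_total"],
                                                   abs=1e-9)

    def test_effect_size_bounds_and_dfs(self):
        rng = np.random.default_rng(2)
        tbl = make_table(rng, n_groups=5, per_group=3)
        for r in mixed_anova(tbl, "y"):
            assert 0.0 <= r.eta_p2 <= 1.0
            assert r.F >= 0.0
            assert r.df_num > 0 and r.df_den > 0

    def test_group_shift_raises_f(self):
        # a shift of two subject-level SDs must raise the group F on nearly
        # every paired seed (a small shift can cancel a random base offset)
        hits, f_null, f_shift = 0, [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            null = make_table(rng, n_groups=2, per_group=6)
            rng = np.random.default_rng(seed)
            shifted = make_table(rng, n_groups=2, per_group=6,
                                 group_shift=2.5)
            f0 = {r.effect: r.F for r in mixed_anova(null, "y")}["group"]
            f1 = {r.effect: r.F for r in mixed_anova(shifted, "y")}["group"]
            hits += f1 > f0
            f_null.append(f0)
            f_shift.append(f1)
        assert hits >= 18
        assert np.mean(f_shift) > 2 * np.mean(f_null)

    def test_missing_condition_rejected(self):
        rng = np.random.default_rng(0)
        tbl = make_table(rng).iloc[:-1]
        with pytest.raises(InvalidDesignError):
            mixed_anova(tbl, "y")


class TestBonferroni:
    def test_adjustment_and_cap(self):
        rng = np.random.default_rng(3)
        tbl = make_table(rng, n_groups=5, per_group=4, group_shift=1.5)
        out = bonferroni_posthoc(tbl, "y")
        assert len(out) == 10
        np.testing.assert_allclose(out["p_bonf"],
                                   np.minimum(1.0, out["p_unc"] * 10))
        order = out.sort_values("p_unc")
        assert order["p_bonf"].is_monotonic_increasing

    def test_null_false_positive_rate(self):
        any_sig = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tbl = make_table(rng, n_groups=5, per_group=3)
            out = bonferroni_posthoc(tbl, "y")
            any_sig += (out["p_bonf"] < 0.05).any()
        assert any_sig <= 10

    def test_small_group_rejected(self):
        rng = np.random.default_rng(0)
        tbl = make_table(rng, n_groups=2, per_group=2)
        tbl = tbl[~((tbl["group"] == "G2") & (tbl["subject_id"] == "s4"))]
        with pytest.raises(InvalidDesignError):
            bonferroni_posthoc(tbl, "y")


class TestRegressionTable:
    def test_measure_vs_predictor_grid(self):
        rng = np.random.default_rng(1)
        tbl = make_table(rng, n_groups=3, per_group=4, group_shift=2.0)
        out = regression_table(tbl, predictors=("age", "impf"),
                               measures=["y"])
        assert set(out["predictor"]) == {"age", "impf"}
        assert ((out["r2"] >= 0) & (out["r2"] <= 1)).all()
        # group_shift=2 on a group-coded age predictor: strong dependence
        assert out.loc[out["predictor"] == "age", "r2"].iloc[0] > 0.3
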