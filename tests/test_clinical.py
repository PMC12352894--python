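"""Response rules, rank-based group tests, screens, models, trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cytostrat.clinical import (
    classify_renal_response,
    compare_groups,
    elastic_net_attribution,
    mixed_longitudinal,
    multivariable,
    spearman_screen,
)


class TestRenalResponse:
    @pytest.mark.parametrize("b_upcr,w_upcr,w_cr,b_cr,w_pred,expected", [
        (2.0, 0.4, 1.0, 1.0, 5.0, "complete"),
        (2.0, 0.9, 1.0, 1.0, 12.0, "partial"),   # >55% reduction, pred 12
        (0.8, 0.1, 1.0, 1.0, 0.0, "not_evaluable"),
        (2.0, 0.4, 1.0, 1.0, 10.0, "partial"),   # prednisone 10 not < 10
        (2.0, 0.4, 1.0, 1.0, 15.0, "partial"),   # prednisone == 15 allowed
        (2.0, 0.4, 1.0, 1.0, 15.1, "none"),
        (2.0, 0.5, 1.0, 1.0, 5.0, "partial"),    # upcr 0.5 not < 0.5 but == 50% cut
        (2.0, 1.01, 1.0, 1.0, 5.0, "none"),      # reduction just under 50%
        (2.0, 0.4, 1.6, 1.0, 5.0, "none"),       # creatinine 160% of baseline
        (2.0, 0.4, 1.2, 1.0, 5.0, "complete"),   # abnormal? no: <=1.3 normal
        (2.0, 0.4, 1.45, 1.2, 5.0, "complete"),  # 121% of baseline, abnormal ok
        (2.0, 0.4, 1.5, 1.2, 5.0, "partial"),    # exactly 125%: fails strict <,
                                                 # passes <= for partial
        (1.0, 0.45, 1.0, 1.0, 5.0, "complete"),  # boundary baseline UPCR == 1
    ])
    def test_rule_branches(self, b_upcr, w_upcr, w_cr, b_cr, w_pred, expected):
        call = classify_renal_response(b_upcr, w_upcr, w_cr, b_cr, w_pred)
        assert call.call == expected, call.trace

    def test_missing_fields_not_evaluable_with_reason(self):
        call = classify_renal_response(2.0, np.nan, 1.0, 1.0, 5.0)
        assert call.call == "not_evaluable"
        assert "missing" in call.trace[0]

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            classify_renal_response(2.0, -0.1, 1.0, 1.0, 5.0)

    def test_trace_reconstructs_decision(self):
        call = classify_renal_response(2.0, 0.4, 1.45, 1.2, 5.0)
        assert any("125%" in t for t in call.trace)
        assert any(t.startswith("complete") for t in call.trace)


class TestCompareGroups:
    def test_matches_hand_ranked_oracle(self):
        """KW on {1,2,3},{4,5,6},{7,8,9}: ranks are 1..9 with no ties, so
        H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2 can be computed by hand."""
        v = pd.Series([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        g = pd.Series(list("aaabbbccc"))
        res = compare_groups(v, g)
        mean_ranks = [2.0, 5.0, 8.0]
        H = 12 / (9 * 10) * sum(3 * (m - 5.0) ** 2 for m in mean_ranks)
        assert res.kw_statistic == pytest.approx(H)
        assert res.kw_statistic == pytest.approx(stats.kruskal(
            [1, 2, 3], [4, 5, 6], [7, 8, 9]).statistic)

    def test_identical_groups_pairwise_p_near_one(self, rng):
        v = pd.Series(np.tile(rng.normal(size=10), 2))
        g = pd.Series(["a"] * 10 + ["b"] * 10)
        res = compare_groups(v, g)
        assert res.pairwise.iloc[0]["p"] > 0.9

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 1000
        for _ in range(reps):
            v = pd.Series(rng.normal(size=30))
            g = pd.Series(np.repeat(list("abc"), 10))
            hits += compare_groups(v, g).kw_p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_all_tied_path(self):
        v = pd.Series([1.0] * 12)
        g = pd.Series(np.repeat(list("abc"), 4))
        res = compare_groups(v, g)
        assert res.kw_p == 1.0


class TestSpearmanScreen:
    def test_monotone_invariance_and_antimonotone(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(scale=0.5, size=50)
        f = pd.DataFrame({"x": x, "ex": np.exp(x)})
        t = pd.DataFrame({"y": y, "neg": -np.arange(50, dtype=float)})
        f["mono"] = np.arange(50, dtype=float)
        tab = spearman_screen(f, t).set_index(["feature", "target"])
        assert tab.loc[("x", "y"), "rho"] == pytest.approx(
            tab.loc[("ex", "y"), "rho"])
        assert tab.loc[("mono", "neg"), "rho"] == pytest.approx(-1.0)

    def test_bh_step_up_oracle(self):
        """BH at q=0.05 on {0.001,0.01,0.02,0.8}: the step-up rule passes the
        first three."""
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.001, 0.01, 0.02, 0.8])
        # independent step-up oracle
        order = np.argsort(p)
        passed = np.zeros(4, dtype=bool)
        kmax = 0
        for rank, i in enumerate(order, start=1):
            if p[i] <= 0.05 * rank / 4:
                kmax = rank
        passed[order[:kmax]] = True
        assert passed.tolist() == [True, True, True, False]
        assert (multipletests(p, alpha=0.05, method="fdr_bh")[0] ==
                passed).all()


class TestMultivariable:
    def test_identity_linear_fit(self, rng):
        y = pd.Series(rng.normal(size=50))
        res = multivariable(y, y, family="linear")
        assert res.coefficient == pytest.approx(1.0)
        # degenerate perfect fit: CI collapses onto the estimate
        assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)

    def test_null_coverage(self):
        rng = np.random.default_rng(4)
        cover_lin = cover_log = 0
        reps = 200
        for _ in range(reps):
            x = pd.Series(rng.normal(size=80))
            y = pd.Series(rng.normal(size=80))
            r = multivariable(y, x, family="linear")
            cover_lin += r.ci_low <= 0.0 <= r.ci_high
            yb = pd.Series(rng.binomial(1, 0.4, size=80).astype(float))
            rl = multivariable(yb, x, family="logistic")
            cover_log += rl.ci_low <= 1.0 <= rl.ci_high
        assert cover_lin / reps >= 0.90
        assert cover_log / reps >= 0.90

    def test_rank_deficient_rejected(self, rng):
        x = pd.Series(rng.normal(size=30))
        cov = pd.DataFrame({"dup": x})
        with pytest.raises(ValueError, match="rank"):
            multivariable(pd.Series(rng.normal(size=30)), x, cov)


class TestElasticNet:
    def test_planted_predictor_dominates(self, rng):
        n, p = 150, 21
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"x{i}" for i in range(p)])
        y = pd.Series(X["x0"] * 1.0 + rng.normal(size=n))
        tab = elastic_net_attribution(X, y, repeats=3, folds=5, seed=0)
        assert tab.index[0] == "x0"
        assert tab.loc["x0", "sign"] > 0

    def test_null_shrinkage(self, rng):
        n, p = 100, 15
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"x{i}" for i in range(p)])
        y = pd.Series(rng.normal(size=n))
        tab = elastic_net_attribution(X, y, repeats=3, folds=5, seed=1)
        assert tab["coefficient"].abs().median() < 0.05
        assert tab["selection_frequency"].median() <= 0.4

    def test_seed_determinism_and_size_guard(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"x{i}" for i in range(5)])
        y = pd.Series(rng.normal(size=60))
        t1 = elastic_net_attribution(X, y, repeats=2, folds=5, seed=9)
        t2 = elastic_net_attribution(X, y, repeats=2, folds=5, seed=9)
        assert np.allclose(t1["coefficient"], t2["coefficient"])
        with pytest.raises(ValueError, match="folds"):
            elastic_net_attribution(X.head(5), y.head(5), folds=10)


class TestMixedLongitudinal:
    def _long_data(self, slope_resp=-0.5, sigma_patient=1.0, n_pat=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_pat):
            resp = i < n_pat // 2
            b = rng.normal(0, sigma_patient)
            for t in range(3):
                mu = 5 + b + (slope_resp * t if resp else 0.0)
                rows.append(dict(pid=f"p{i}", t=t,
                                 g="resp" if resp else "nonresp",
                                 y=mu + rng.normal(0, 0.5)))
        return pd.DataFrame(rows)

    def test_interaction_recovered(self):
        hits = sign_ok = 0
        reps = 25
        for i in range(reps):
            df = self._long_data(seed=i)
            res = mixed_longitudinal(df["y"], df["t"], df["g"], df["pid"])
            est = res.fixed_effects.loc["t:g", "estimate"]
            p = res.fixed_effects.loc["t:g", "p"]
            # group indicator codes the last level alphabetically ("resp")
            sign_ok += est < 0
            hits += p < 0.05
        assert sign_ok >= 0.9 * reps
        assert hits >= 0.8 * reps

    def test_zero_random_effect_matches_ols(self):
        import statsmodels.api as sm
        df = self._long_data(sigma_patient=0.0, seed=3)
        res = mixed_longitudinal(df["y"], df["t"], df["g"], df["pid"])
        X = sm.add_constant(pd.DataFrame({
            "t": df["t"].astype(float),
            "g": (df["g"] == "resp").astype(float),
            "t:g": df["t"] * (df["g"] == "resp")}))
        ols = sm.OLS(df["y"], X).fit()
        est = res.fixed_effects["estimate"]
        assert np.allclose(est[["t", "g", "t:g"]],
                           ols.params[["t", "g", "t:g"]], atol=1e-4)

    def test_no_replication_falls_back_to_ols(self):
        df = self._long_data(seed=5).groupby("pid").head(1)
        res = mixed_longitudinal(df["y"], df["t"], df["g"], df["pid"])
        assert not res.used_mixed

    def test_interaction_null_calibration(self):
        pvals = []
        for i in range(120):
            df = self._long_data(slope_resp=0.0, seed=200 + i)
            res = mixed_longitudinal(df["y"], df["t"], df["g"], df["pid"])
            pvals.append(res.fixed_effects.loc["t:g", "p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
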