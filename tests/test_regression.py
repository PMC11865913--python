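import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aphidscape.regression import (
    ExhaustiveAICcRegressor,
    PipelineConfig,
    VIFScreen,
    aicc_from_rss,
    anova_on_ranks,
    decide_pooling,
    exhaustive_aicc,
    fit_ols,
    run_pipeline,
    spearman_matrix,
    transform_dependent,
    tukey_hsd_ranks,
    vif_screen,
)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(-3, 3, 20)
        m = spearman_matrix(pd.DataFrame({"x": x, "y": x**3}))
        assert m.loc["x", "y"] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        x = np.arange(10.0)
        m = spearman_matrix(pd.DataFrame({"x": x, "y": -x}))
        assert m.loc["x", "y"] == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self, rng):
        a = rng.integers(0, 4, 10).astype(float)
        b = rng.integers(0, 4, 10).astype(float)
        m = spearman_matrix(pd.DataFrame({"a": a, "b": b}))
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        want = np.corrcoef(ra, rb)[0, 1]
        assert m.loc["a", "b"] == pytest.approx(want, abs=1e-12)

    def test_constant_column_warns_and_is_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            m = spearman_matrix(pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]}))
        assert math.isnan(m.loc["a", "b"])


class TestAnovaOnRanks:
    def test_separated_groups_highly_significant(self):
        vals = np.arange(1, 31, dtype=float)
        labels = np.repeat(["a", "b", "c"], 10)
        assert anova_on_ranks(vals, labels) < 0.001

    def test_invariant_under_monotone_transform(self, rng):
        vals = rng.normal(size=30)
        labels = np.repeat([1, 2, 3], 10)
        p1 = anova_on_ranks(vals, labels)
        p2 = anova_on_ranks(np.exp(vals), labels)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            anova_on_ranks([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestTukey:
    def test_identical_groups_p_near_one(self):
        vals = np.tile(np.arange(10.0), 2)
        labels = np.repeat(["x", "y"], 10)
        p = tukey_hsd_ranks(vals, labels)[("x", "y")]
        assert p > 0.99

    def test_two_group_studentized_range_closed_form(self, rng):
        # balanced k=2: p = SR.sf(q, 2, df) with q from the rank means
        vals = rng.normal(size=24)
        labels = np.repeat(["a", "b"], 12)
        got = tukey_hsd_ranks(vals, labels)[("a", "b")]
        ranks = stats.rankdata(vals)
        g1, g2 = ranks[:12], ranks[12:]
        df = 22
        s2 = (g1.var(ddof=1) * 11 + g2.var(ddof=1) * 11) / df
        q = abs(g1.mean() - g2.mean()) / math.sqrt(s2 / 2 * (1 / 12 + 1 / 12))
        want = stats.studentized_range.sf(q, 2, df)
        assert got == pytest.approx(want, rel=1e-6)

    def test_single_separated_pair_detected(self):
        vals = np.concatenate([np.arange(10.0), np.arange(10.0) + 0.5, np.arange(10.0) + 40])
        labels = np.repeat(["a", "b", "c"], 10)
        p = tukey_hsd_ranks(vals, labels)
        assert p[("a", "b")] >= 0.05
        assert p[("a", "c")] < 0.05 and p[("b", "c")] < 0.05

    def test_matches_statsmodels_on_ranks(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        vals = rng.normal(size=33)
        labels = np.repeat(["a", "b", "c"], [10, 12, 11])
        got = tukey_hsd_ranks(vals, labels)
        sm = pairwise_tukeyhsd(stats.rankdata(vals), labels)
        want = dict(zip([tuple(r) for r in sm.summary().data[1:]], sm.pvalues))
        for (a, b), p in got.items():
            sm_p = [v for k, v in want.items() if k[0] == a and k[1] == b][0]
            assert p == pytest.approx(sm_p, abs=1e-4)


class TestPooling:
    """Reproduces the published pooling decisions from printed p-values."""

    def test_predator_parasitoid_ratio_pools_first_two_years(self):
        d = decide_pooling(
            0.018,
            {(2017, 2018): 0.632, (2017, 2019): 0.079, (2018, 2019): 0.018},
            [2017, 2018, 2019],
        )
        assert d.pooled_years == (2017, 2018)

    def test_lady_beetle_response_pools_first_two_years(self):
        d = decide_pooling(
            0.016,
            {(2017, 2018): 0.940, (2017, 2019): 0.017, (2018, 2019): 0.046},
            [2017, 2018, 2019],
        )
        assert d.pooled_years == (2017, 2018)

    def test_parasitoid_response_pools_last_two_years(self):
        d = decide_pooling(
            0.0005,
            {(2017, 2018): 0.003, (2017, 2019): 0.0009, (2018, 2019): 0.561},
            [2017, 2018, 2019],
        )
        assert d.pooled_years == (2018, 2019)

    def test_nonsignificant_anova_pools_everything(self):
        d = decide_pooling(0.610, None, [2017, 2018, 2019])
        assert d.all_pooled and d.pooled_years == (2017, 2018, 2019)

    def test_all_pairs_significant_leaves_nothing_pooled(self):
        d = decide_pooling(
            0.001,
            {(1, 2): 0.01, (1, 3): 0.01, (2, 3): 0.01},
            [1, 2, 3],
        )
        assert d.pooled_years == () and d.leftover_years == (1, 2, 3)


class TestTransform:
    def test_log_of_one_is_zero(self):
        out, rec = transform_dependent(pd.DataFrame({"y": [1.0, math.e]}), ("y",))
        assert out["y"].tolist() == pytest.approx([0.0, 1.0])
        assert rec["y"] == "ln"

    def test_unlisted_column_unchanged(self):
        out, rec = transform_dependent(pd.DataFrame({"dtSAmax": [3.0, 7.0]}), ("nSAmax",))
        assert out["dtSAmax"].tolist() == [3.0, 7.0]
        assert rec["dtSAmax"] == "identity"

    def test_round_trip(self, rng):
        y = rng.uniform(0.5, 9, 20)
        out, _ = transform_dependent(pd.DataFrame({"y": y}), ("y",))
        np.testing.assert_allclose(np.exp(out["y"]), y, atol=1e-12)

    def test_nonpositive_named_in_error(self):
        with pytest.raises(ValueError, match="y"):
            transform_dependent(pd.DataFrame({"y": [1.0, 0.0, 2.0]}), ("y",))


class TestVIF:
    def test_orthogonal_candidates_all_one(self):
        n = 40
        t = np.arange(n)
        # mean-zero, mutually orthogonal square waves
        X = pd.DataFrame(
            {
                "a": (-1.0) ** t,
                "b": (-1.0) ** (t // 2),
                "c": (-1.0) ** (t // 4),
            }
        )
        retained, report = vif_screen(X, ["a", "b", "c"], threshold=10)
        assert retained == ["a", "b", "c"]
        assert np.allclose(report.loc[report["round"] == 0, "vif"], 1.0, atol=1e-8)

    def test_duplicate_column_removed_first(self, rng):
        base = rng.normal(size=30)
        X = pd.DataFrame({"a": base, "b": base, "c": rng.normal(size=30)})
        retained, _ = vif_screen(X, ["a", "b", "c"], threshold=10)
        assert "c" in retained and len(retained) == 2

    def test_matches_auxiliary_regression_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        X["a"] += 0.8 * X["b"]
        _, report = vif_screen(X, ["a", "b", "c"], threshold=1e9)
        for name in ["a", "b", "c"]:
            others = [c for c in ["a", "b", "c"] if c != name]
            D = np.column_stack([np.ones(50), X[others]])
            beta, *_ = np.linalg.lstsq(D, X[name], rcond=None)
            resid = X[name] - D @ beta
            r2 = 1 - (resid @ resid) / ((X[name] - X[name].mean()) ** 2).sum()
            want = 1 / (1 - r2)
            got = report.loc[report["candidate"] == name, "vif"].iloc[0]
            assert got == pytest.approx(want, abs=1e-10)

    def test_screen_terminates_below_threshold(self, rng):
        base = rng.normal(size=60)
        X = pd.DataFrame(
            {f"v{i}": base + rng.normal(0, 0.3, 60) for i in range(4)}
            | {"w": rng.normal(size=60)}
        )
        retained, report = vif_screen(X, list(X.columns), threshold=5.0)
        final = report[report["round"] == report["round"].max()]
        assert final["vif"].max() <= 5.0 or len(retained) == 1

    def test_sklearn_transformer_surface(self, rng):
        base = rng.normal(size=40)
        X = pd.DataFrame({"a": base, "b": base + rng.normal(0, 0.01, 40), "c": rng.normal(size=40)})
        t = VIFScreen(threshold=5.0).fit(X)
        assert set(t.retained_) | set(t.dropped_) == {"a", "b", "c"}
        assert list(t.transform(X).columns) == t.retained_


class TestOLS:
    def test_noiseless_line_recovered(self):
        x = np.arange(10.0)
        fit = fit_ols(3 + 2 * x, pd.DataFrame({"x": x}))
        assert fit.params["Intercept"] == pytest.approx(3.0)
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_intercept_only_r2_zero(self, rng):
        fit = fit_ols(rng.normal(size=15), None)
        assert fit.r2 == 0.0 and fit.adj_r2 == 0.0 and fit.k == 0

    def test_matches_statsmodels_and_formula_oracles(self, rng):
        import statsmodels.api as sm

        n, k = 20, 3
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=["a", "b", "c"])
        y = 1 + X["a"] - 2 * X["c"] + rng.normal(0, 0.7, n)
        fit = fit_ols(y.to_numpy(), X)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), ref.pvalues.to_numpy(), atol=1e-10)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-10)
        assert fit.f_pvalue == pytest.approx(ref.f_pvalue, abs=1e-10)
        # normal-equations coefficient oracle
        D = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)
        # AICc from the direct formula with p = k + 2
        rss = float(ref.resid @ ref.resid)
        p = k + 2
        want = n * math.log(rss / n) + n * (1 + math.log(2 * math.pi)) + 2 * p + 2 * p * (p + 1) / (n - p - 1)
        assert fit.aicc == pytest.approx(want, abs=1e-10)

    def test_aicc_arithmetic_pin(self):
        # n=30, k=2, RSS=12: every term evaluated by hand
        got = aicc_from_rss(12.0, 30, 2)
        want = 30 * math.log(0.4) + 30 * (1 + math.log(2 * math.pi)) + 8 + 40 / 25
        assert got == pytest.approx(want, abs=1e-12)

    def test_rank_deficiency_named(self, rng):
        x = rng.normal(size=12)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(np.linalg.LinAlgError, match="a.*b"):
            fit_ols(rng.normal(size=12), X)


class TestExhaustiveSelection:
    def test_no_candidates_single_intercept_model(self, rng):
        sel = exhaustive_aicc(rng.normal(size=12), pd.DataFrame(index=range(12)))
        assert len(sel.fits) == 1 and sel.optimal.k == 0
        assert sel.inclusion_frequencies.empty

    def test_enumerates_all_subsets(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 8)), columns=list("abcdefgh"))
        sel = exhaustive_aicc(rng.normal(size=60), X)
        assert len(sel.fits) + len(sel.skipped) == 256

    def test_optimum_beats_full_scan_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        y = 2 * X["b"] + rng.normal(size=30)
        sel = exhaustive_aicc(y.to_numpy(), X)
        import itertools

        scan = []
        for size in range(6):
            for combo in itertools.combinations(list("abcde"), size):
                scan.append(fit_ols(y.to_numpy(), X, combo).aicc)
        assert sel.optimal.aicc == pytest.approx(min(scan), abs=1e-8)
        assert all(sel.optimal.aicc <= f.aicc + 1e-8 for f in sel.fits)

    def test_strong_predictor_always_in_top_set(self, rng):
        n = 141
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=["true", "n1", "n2", "n3", "n4"])
        y = 1.0 * X["true"] + rng.normal(0, 0.5, n)
        sel = exhaustive_aicc(y.to_numpy(), X)
        assert "true" in sel.optimal.variables
        assert sel.inclusion_frequencies["true"] == 1.0
        assert (sel.inclusion_frequencies[["n1", "n2", "n3", "n4"]] < 1.0).any()

    def test_ranking_invariant_to_affine_rescaling(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        y = X["a"] - X["d"] + rng.normal(size=25)
        s1 = exhaustive_aicc(y.to_numpy(), X)
        X2 = X.copy()
        X2["a"] = 100 * X2["a"] - 7
        X2["c"] = 0.001 * X2["c"] + 3
        s2 = exhaustive_aicc(y.to_numpy(), X2)
        for f1, f2 in zip(s1.fits, s2.fits):
            assert f1.variables == f2.variables
            assert f1.aicc == pytest.approx(f2.aicc, abs=1e-8)

    def test_undersized_subsets_skipped(self, rng):
        X = pd.DataFrame(rng.normal(size=(7, 5)), columns=list("abcde"))
        with pytest.warns(UserWarning, match="skipped"):
            sel = exhaustive_aicc(rng.normal(size=7), X)
        assert len(sel.skipped) > 0
        assert all(f.n - f.k - 3 > 0 for f in sel.fits)

    def test_sklearn_estimator_surface(self, rng):
        from sklearn.base import clone

        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = 2 + 3 * X["a"].to_numpy() + rng.normal(0, 0.3, 40)
        est = ExhaustiveAICcRegressor(delta_threshold=2.0)
        est2 = clone(est).set_params(delta_threshold=4.0)
        assert est2.get_params()["delta_threshold"] == 4.0
        est.fit(X, y)
        pred = est.predict(X)
        manual = est.intercept_ + X.to_numpy() @ est.coef_
        np.testing.assert_allclose(pred, manual)
        assert est.best_model_.variables == ("a",)
        assert est.score(X, y) > 0.9


class TestPipeline:
    def make_tables(self, rng, n=60, beta=0.0):
        env = pd.DataFrame(
            {
                "site_id": [f"S{i}" for i in range(n)],
                "year": np.tile([2017, 2018], n // 2),
                "PLANDs": rng.uniform(0, 20, n),
                "PD": rng.uniform(0, 2, n),
                "SIDI": rng.uniform(0.2, 0.8, n),
                "maxTMAX": rng.normal(38, 2, n),
                "meanPPT": rng.gamma(2, 1.5, n),
            }
        )
        y = np.exp(0.3 + beta * env["PLANDs"] + rng.normal(0, 0.8, n))
        metrics = pd.DataFrame(
            {
                "site_id": env["site_id"],
                "year": env["year"],
                "nSAmax": y,
                "nSAmax_retained": True,
            }
        )
        return metrics, env

    def test_injected_effect_selected(self, rng):
        metrics, env = self.make_tables(rng, n=120, beta=0.1)
        cfg = PipelineConfig(candidate_sets={"nSAmax": ("PLANDs", "PD", "SIDI", "maxTMAX", "meanPPT")})
        res = run_pipeline(metrics, env, cfg)
        assert "PLANDs" in res.selections["nSAmax"].optimal.variables
        row = res.optimal_models
        assert (row["dependent"] == "ln(nSAmax)").any()

    def test_retention_flags_respected(self, rng):
        metrics, env = self.make_tables(rng, n=40)
        metrics.loc[:30, "nSAmax_retained"] = False
        cfg = PipelineConfig(candidate_sets={"nSAmax": ("PLANDs", "PD")}, min_n=10)
        res = run_pipeline(metrics, env, cfg)
        if "nSAmax" in res.selections:
            assert res.selections["nSAmax"].optimal.n <= 9
        else:
            assert "nSAmax" in res.skipped_metrics

    def test_small_sample_metric_skipped_with_reason(self, rng):
        metrics, env = self.make_tables(rng, n=8)
        res = run_pipeline(metrics, env, PipelineConfig(min_n=10))
        assert "nSAmax" in res.skipped_metrics
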