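import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oligomorph.stats import (
    analyze_table,
    box_m,
    diagnostics,
    effective_tests_simplem,
    fit_mixed_anova,
    group_ttest_cohend,
    select_transform,
)
from oligomorph.synthetic import CohortDesign, simulate_measurements


def table_from_values(ctrl, scz, metric="m"):
    rows = []
    for line, vals in ctrl.items():
        rows += [("Ctrl", line, i, metric, v) for i, v in enumerate(vals)]
    for line, vals in scz.items():
        rows += [("SCZ", line, i, metric, v) for i, v in enumerate(vals)]
    return pd.DataFrame(rows, columns=["group", "line", "fov", "metric", "value"])


class TestSelectTransform:
    def test_normal_sample_no_harmful_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        res = select_transform(x)
        w_identity = sps.shapiro(x).statistic
        assert res.shapiro_after >= w_identity - 0.01

    def test_lognormal_normalized(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(size=200))
        res = select_transform(x)
        assert res.shapiro_after > res.shapiro_before
        if res.transform == "box-cox":
            assert -0.2 <= res.params["lmbda"] <= 0.2
        else:
            assert res.transform in ("yeo-johnson", "ordernorm")

    def test_candidates_monotone_on_sample(self):
        from oligomorph.stats.transforms import _fit_one, _COMPLEXITY

        assert np.arcsinh(0.0) == 0.0
        rng = np.random.default_rng(2)
        x = np.sort(rng.gamma(2, 2, size=50))
        for name in _COMPLEXITY:
            fit = _fit_one(name, x)
            if fit is None:
                continue
            y, _ = fit
            assert (np.diff(y) >= -1e-12).all(), name

    def test_invertibility(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(3, 1, size=80)
        res = select_transform(x)
        back = res.inverse(res.values)
        if res.transform == "ordernorm":
            # rank-preserving round trip on training data
            assert (np.argsort(back) == np.argsort(res.values)).all()
            assert np.allclose(np.sort(back), np.sort(x), rtol=1e-6)
        else:
            assert np.allclose(back, np.sort(x) if False else x[np.isfinite(x)],
                               rtol=1e-8)

    def test_all_identical_degenerate(self):
        res = select_transform(np.full(10, 3.3))
        assert res.transform == "identity" and res.degenerate

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            select_transform([1.0, 2.0])


class TestDiagnostics:
    def test_identical_within_group_levene_zero(self):
        t = table_from_values({"a": [1, 1, 1], "b": [1, 1, 1]},
                              {"c": [2, 2, 2], "d": [2, 2, 2]})
        rep = diagnostics(t)
        assert rep["metrics"]["m"]["levene_stat"] == pytest.approx(0.0)

    def test_extreme_outlier_flagged(self):
        vals = list(np.linspace(0, 1, 20))
        q1, q3 = np.percentile(vals, [25, 75])
        outlier = q3 + 3.5 * (q3 - q1)
        t = table_from_values({"a": vals}, {"b": [outlier]})
        rep = diagnostics(t)
        assert rep["metrics"]["m"]["n_extreme_outliers"] >= 1

    def test_levene_type_I_calibration(self):
        rng = np.random.default_rng(4)
        reps, hits = 1000, 0
        for _ in range(reps):
            a, b = rng.normal(size=(2, 30))
            hits += sps.levene(a, b, center="median").pvalue < 0.05
        rate = hits / reps
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 2 * mc_se + 0.005

    def test_box_m_blocks(self):
        rng = np.random.default_rng(5)
        same = [rng.normal(size=(40, 2)), rng.normal(size=(40, 2))]
        res = box_m(same)
        assert res["p"] > 0.01
        diff = [rng.normal(size=(40, 2)), 3.0 * rng.normal(size=(40, 2))]
        assert box_m(diff)["p"] < 0.01

    def test_single_group_rejected(self):
        t = table_from_values({"a": [1, 2, 3]}, {})
        with pytest.raises(ValueError):
            diagnostics(t)


class TestMixedAnova:
    @staticmethod
    def _remove_line_effects(t):
        # exact zero between-line variation: re-centre every line on its
        # group mean so the random-intercept estimate hits the boundary
        gmeans = t.groupby("group")["value"].transform("mean")
        lmeans = t.groupby("line")["value"].transform("mean")
        t = t.copy()
        t["value"] = t["value"] - lmeans + gmeans
        return t

    def test_zero_line_variance_matches_oneway(self):
        d = CohortDesign(n_lines_per_group=5, n_fov_per_line=8, line_sd=0.0,
                         fov_sd=0.2, group_effect=0.1, metrics=("m",), seed=7)
        t = self._remove_line_effects(simulate_measurements(d))
        res = fit_mixed_anova(t, "m")
        a = t[t.group == "Ctrl"]["value"]
        b = t[t.group == "SCZ"]["value"]
        f_oneway = sps.f_oneway(a, b).statistic
        assert res.F == pytest.approx(f_oneway, rel=0.05)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        d = CohortDesign(n_lines_per_group=7, n_fov_per_line=10, line_sd=0.1,
                         fov_sd=0.15, group_effect=0.05, metrics=("m",), seed=42)
        t = simulate_measurements(d)
        res = fit_mixed_anova(t, "m")
        df = t.copy()
        df["g"] = (df.group == "SCZ").astype(float)
        sm_fit = smf.mixedlm("value ~ g", df, groups=df["line"]).fit(reml=True)
        assert res.estimate == pytest.approx(sm_fit.params["g"], abs=1e-6)
        assert res.se == pytest.approx(sm_fit.bse["g"], rel=1e-3)
        assert res.var_line == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert res.var_resid == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_df_between_within(self):
        d = CohortDesign(n_lines_per_group=7, metrics=("m",), seed=0)
        res = fit_mixed_anova(simulate_measurements(d), "m")
        assert res.df_den == 12  # 14 lines - 2

    def test_singular_fit_flagged(self):
        d = CohortDesign(n_lines_per_group=4, n_fov_per_line=6, line_sd=0.0,
                         fov_sd=0.2, metrics=("m",), seed=11)
        res = fit_mixed_anova(self._remove_line_effects(simulate_measurements(d)), "m")
        assert res.var_line == pytest.approx(0.0, abs=1e-6)
        assert res.singular

    def test_power_monotone_in_effect(self):
        reps = 300
        powers = []
        for mult in (0.5, 1.0, 1.5):
            hits = 0
            for i in range(reps):
                d = CohortDesign(n_lines_per_group=7, n_fov_per_line=10,
                                 line_sd=0.1, fov_sd=0.15,
                                 group_effect=mult * 0.1, metrics=("m",),
                                 seed=1_000_000 + i)
                hits += fit_mixed_anova(simulate_measurements(d), "m").p_value < 0.05
            powers.append(hits / reps)
        assert powers[0] < powers[1] < powers[2]

    def test_too_few_lines(self):
        t = table_from_values({"a": [1, 2]}, {"b": [3, 4], "c": [5, 6]})
        with pytest.raises(ValueError):
            fit_mixed_anova(t, "m")

    def test_missing_dropped(self):
        t = table_from_values({"a": [1, 2], "b": [2, 3]}, {"c": [3, 4], "d": [4, 5]})
        t.loc[0, "value"] = np.nan
        res = fit_mixed_anova(t, "m")
        assert res.n_obs == 7


class TestMixedModelRecovery:
    def test_group_effect_unbiased(self):
        reps, effect = 300, 0.2
        ests = []
        for i in range(reps):
            d = CohortDesign(n_lines_per_group=7, n_fov_per_line=10,
                             line_sd=0.1, fov_sd=0.15, group_effect=effect,
                             metrics=("m",), seed=9_000_000 + i)
            ests.append(fit_mixed_anova(simulate_measurements(d), "m").estimate)
        assert abs(np.mean(ests) - effect) < 0.05 * effect

    def test_line_variance_consistency(self):
        # estimation error (RMSE around the true 0.01) shrinks with more lines
        rmse = {}
        for n_lines in (4, 20):
            vals = []
            for i in range(150):
                d = CohortDesign(n_lines_per_group=n_lines, n_fov_per_line=8,
                                 line_sd=0.1, fov_sd=0.15, metrics=("m",),
                                 seed=8_000_000 + i)
                vals.append(fit_mixed_anova(simulate_measurements(d), "m").var_line)
            rmse[n_lines] = np.sqrt(np.mean((np.array(vals) - 0.01) ** 2))
        assert rmse[20] < rmse[4] / 2


class TestGroupTtestCohend:
    def test_identical_means(self):
        t = table_from_values({"a": [1.0], "b": [2.0]}, {"c": [1.0], "d": [2.0]})
        res = group_ttest_cohend(t, "m")
        assert res.cohen_d == 0.0
        assert res.p == 1.0

    def test_separation_enormous_d(self):
        rng = np.random.default_rng(0)
        ctrl = {f"c{i}": [0.0 + rng.normal(0, 1e-9)] for i in range(3)}
        scz = {f"s{i}": [1.0 + rng.normal(0, 1e-9)] for i in range(3)}
        res = group_ttest_cohend(table_from_values(ctrl, scz), "m")
        assert res.cohen_d > 1e6

    def test_closed_form(self):
        ctrl = {f"c{i}": [v] for i, v in enumerate([0.1, 0.2, 0.3, 0.4])}
        scz = {f"s{i}": [v] for i, v in enumerate([0.5, 0.6, 0.7, 0.8])}
        res = group_ttest_cohend(table_from_values(ctrl, scz), "m")
        pooled_sd = np.sqrt((3 * np.var([0.1, 0.2, 0.3, 0.4], ddof=1)
                             + 3 * np.var([0.5, 0.6, 0.7, 0.8], ddof=1)) / 6)
        assert res.mean_diff == pytest.approx(0.4)
        assert res.cohen_d == pytest.approx(0.4 / pooled_sd)
        assert res.df == 6

    def test_collapses_to_line_means(self):
        # fov replication inside a line must not inflate the test
        t = table_from_values({"a": [1, 1, 1, 1], "b": [2]},
                              {"c": [3], "d": [4, 4, 4, 4]})
        res = group_ttest_cohend(t, "m")
        assert res.df == 2

    def test_one_line_group_rejected(self):
        t = table_from_values({"a": [1, 2]}, {"b": [3], "c": [4]})
        t2 = t[t.line != "a"]
        with pytest.raises(ValueError):
            group_ttest_cohend(pd.concat([t2]), "m")


class TestSimpleM:
    def test_independent_columns(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 10))
        res = effective_tests_simplem(X)
        assert res.meff == 10
        assert res.adjusted_alpha == pytest.approx(0.005)

    def test_identical_columns(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        X = np.tile(x[:, None], (1, 10))
        assert effective_tests_simplem(X).meff == 1

    def test_two_perfect_blocks(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 400))
        X = np.column_stack([np.tile(a[:, None], (1, 5)), np.tile(b[:, None], (1, 5))])
        res = effective_tests_simplem(X)
        # brute-force spectrum of the exact block correlation matrix
        corr = np.corrcoef(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        cum = np.cumsum(np.clip(eig, 0, None))
        brute = int(np.searchsorted(cum, 0.995 * cum[-1] - 1e-12) + 1)
        assert res.meff == brute == 2

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(4)
        prev = None
        for rho in (0.0, 0.5, 0.9):
            z = rng.normal(size=(300, 1))
            X = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=(300, 8))
            res = effective_tests_simplem(X)
            assert 1 <= res.meff <= 8
            if prev is not None:
                assert res.meff <= prev
            prev = res.meff
        assert res.eigenvalues.sum() == pytest.approx(8, rel=1e-6)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.normal(size=(100, 3)), np.full(100, 2.0)])
        res = effective_tests_simplem(X)
        assert res.dropped_constant == 1
        assert res.m == 3

    def test_validation(self):
        with pytest.raises(ValueError):
            effective_tests_simplem(np.ones((2, 5)))


class TestSensitivityOrdering:
    def test_mixed_anova_at_least_as_powerful_as_line_ttest(self):
        reps = 400
        mixed_hits = ttest_hits = 0
        for i in range(reps):
            d = CohortDesign(n_lines_per_group=7, n_fov_per_line=10,
                             line_sd=0.1, fov_sd=0.15, group_effect=0.1,
                             metrics=("m",), seed=50_000 + i)
            t = simulate_measurements(d)
            mixed_hits += fit_mixed_anova(t, "m").p_value < 0.05
            ttest_hits += group_ttest_cohend(t, "m").p < 0.05
        assert mixed_hits >= ttest_hits


class TestAnalyzeTable:
    def test_report_structure(self):
        d = CohortDesign(n_lines_per_group=4, n_fov_per_line=6,
                         group_effect={"avg_branch_length": 0.2}, seed=6)
        rep = analyze_table(simulate_measurements(d))
        assert set(rep["metrics"]) == {"avg_branch_length", "avg_junction_number"}
        entry = rep["metrics"]["avg_branch_length"]
        assert "mixed_anova" in entry and "line_mean_ttest" in entry
        assert entry["mixed_anova"]["estimate"] > 0
        assert rep["diagnostics"]["box_m"] is not None
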