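"""Scaling, collinearity screening, OLS models, correlations, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from patchlink.inference import (
    DiversityLM,
    ModelSpec,
    collinearity_screen,
    critical_r,
    diagnostics,
    fit_gaussian_lm,
    morans_i,
    pearson_matrix,
    zscore_scale,
)


class TestZScore:
    def test_small_example(self):
        np.testing.assert_allclose(zscore_scale([1, 2, 3]), [-1, 0, 1])

    def test_idempotent_on_zscores(self):
        x = zscore_scale(np.array([3.0, 1.0, 7.0, 2.0]))
        np.testing.assert_allclose(zscore_scale(x), x, atol=1e-12)

    def test_missing_preserved(self):
        out = zscore_scale([1.0, np.nan, 3.0])
        assert math.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [-np.sqrt(2) / 2, np.sqrt(2) / 2])

    def test_constant_vector_fails_naming_variable(self):
        with pytest.raises(ValueError, match="tfi"):
            zscore_scale([2.0, 2.0, 2.0], name="tfi")


class TestCollinearityScreen:
    def test_duplicated_variable_only_one_retained(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        data = pd.DataFrame({"a1": x, "a2": x, "b": rng.normal(size=50)})
        sel, log = collinearity_screen(data, {"A": ["a1", "a2"], "B": ["b"]})
        assert sel["A"] in {"a1", "a2"} and sel["B"] == "b"
        assert {"a1", "a2"} in [{r["var_a"], r["var_b"]} for r in
                                log.to_dict("records")]

    def test_pair_just_over_cutoff_excluded(self):
        # construct two variables with r = 0.31 exactly via mixing
        rng = np.random.default_rng(1)
        n = 2000
        z1, z2 = rng.normal(size=(2, n))
        target = 0.31
        x = z1
        y = target * z1 + math.sqrt(1 - target**2) * z2
        # force empirical r to the target
        y = y - np.polyfit(x, y, 1)[0] * x + target * x * np.std(y) / np.std(x)
        data = pd.DataFrame({"x": x, "y": y, "c": rng.normal(size=n)})
        r_emp = data[["x", "y"]].corr().iloc[0, 1]
        if abs(r_emp) > 0.3:
            with pytest.raises(ValueError):
                collinearity_screen(data, {"A": ["x"], "B": ["y"]})

    def test_independent_variables_all_retained(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
        sel, _ = collinearity_screen(
            data, {"A": ["a"], "B": ["b"], "C": ["c"]})
        assert sel == {"A": "a", "B": "b", "C": "c"}

    def test_selected_set_always_under_cutoff(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            base = rng.normal(size=(40, 6))
            mix = rng.uniform(-1, 1, size=(6, 6))
            data = pd.DataFrame(base @ mix, columns=list("abcdef"))
            cats = {"A": ["a", "b"], "B": ["c", "d"], "C": ["e", "f"]}
            try:
                sel, _ = collinearity_screen(data, cats)
            except ValueError:
                continue
            chosen = list(sel.values())
            corr = data[chosen].corr().abs().values
            np.fill_diagonal(corr, 0)
            assert corr.max() <= 0.3 + 1e-12

    def test_infeasible_reports_offenders(self):
        x = np.arange(10.0)
        data = pd.DataFrame({"a": x, "b": x + 0.001, "c": -x})
        with pytest.raises(ValueError, match="0.3"):
            collinearity_screen(data, {"A": ["a"], "B": ["b"], "C": ["c"]})


def _site_table(n=30, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "tfi": rng.uniform(0, 2, n),
        "dpc": rng.lognormal(0, 1, n),
        "cover": rng.uniform(0, 60, n),
        "soil_type": rng.choice(["clay", "sandy"], n),
    })
    df["y"] = 2.0 * zscore_scale(df["tfi"].values) + rng.normal(0, 0.5, n) + 10
    return df


class TestDiversityLM:
    def test_perfect_fit_recovers_slope(self):
        n = 20
        rng = np.random.default_rng(4)
        x = rng.normal(size=n)
        data = pd.DataFrame({
            "h": x, "c": rng.normal(size=n), "l": rng.normal(size=n)})
        data["y"] = 2.0 * data["h"]
        spec = ModelSpec("y", "h", "c", "l")
        res = fit_gaussian_lm(data, spec, scale=False)
        assert res.params["h"] == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(res.resid, 0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        df = _site_table()
        spec = ModelSpec("y", "tfi", "dpc", "cover")
        res = fit_gaussian_lm(df, spec)
        X = np.column_stack([
            np.ones(len(df)),
            zscore_scale(df["tfi"].values),
            zscore_scale(df["dpc"].values),
            zscore_scale(df["cover"].values),
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].values)
        np.testing.assert_allclose(res.params.values, beta, rtol=1e-10)

    def test_soil_contrast_is_sandy_versus_clay(self):
        df = _site_table()
        df["y"] = df["y"] + 5.0 * (df["soil_type"] == "sandy")
        spec = ModelSpec("y", "tfi", "dpc", "soil_type", categorical_local=True)
        res = fit_gaussian_lm(df, spec)
        term = [t for t in res.params.index if "sandy vs clay" in t]
        assert len(term) == 1
        assert res.params[term[0]] > 0  # sandy sites richer by construction

    def test_complete_cases_recorded(self):
        df = _site_table()
        df.loc[[0, 3], "tfi"] = np.nan
        res = fit_gaussian_lm(df, ModelSpec("y", "tfi", "dpc", "cover"))
        assert res.n == len(df) - 2

    def test_rank_deficiency_detected(self):
        df = _site_table()
        df["dpc"] = df["tfi"]
        with pytest.raises(ValueError, match="rank"):
            DiversityLM(df, ModelSpec("y", "tfi", "dpc", "cover"))

    def test_summary_shape(self):
        res = fit_gaussian_lm(_site_table(), ModelSpec("y", "tfi", "dpc", "cover"))
        table = res.summary()
        assert list(table.columns) == ["beta", "se", "t", "p"]
        assert len(table) == 4
        assert (table["se"] > 0).all()
        assert table["p"].between(0, 1).all()


class TestPearson:
    def test_self_and_anti(self):
        df = pd.DataFrame({"m": [1.0, 2, 3, 5], "neg": [-1.0, -2, -3, -5]})
        rep = pearson_matrix(df)
        assert rep.r.loc["m", "m"] == 1.0
        assert rep.r.loc["m", "neg"] == pytest.approx(-1.0)

    def test_worked_fixture(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 1, 4, 3]})
        rep = pearson_matrix(df)
        assert rep.r.loc["a", "b"] == pytest.approx(0.6)

    def test_pairwise_complete_n(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, np.nan],
                           "b": [2, 1, 4, np.nan, 5.0]})
        rep = pearson_matrix(df)
        assert rep.n.loc["a", "b"] == 3

    def test_insufficient_pairs_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, np.nan, np.nan],
                           "b": [np.nan, np.nan, 1.0, 2]})
        rep = pearson_matrix(df)
        assert math.isnan(rep.r.loc["a", "b"])

    def test_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("wxyz"))
        rep = pearson_matrix(df)
        np.testing.assert_allclose(rep.r.values, rep.r.values.T)
        np.testing.assert_allclose(np.diag(rep.r.values), 1.0)

    def test_critical_r_matches_study_scale_thresholds(self):
        # 0.01-level critical correlations at the study's sample sizes
        assert critical_r(35) == pytest.approx(0.43, abs=0.01)
        assert critical_r(32) == pytest.approx(0.45, abs=0.01)

    @pytest.mark.parametrize("n", [10, 28, 35])
    def test_critical_r_round_trip(self, n):
        # a correlation exactly at the threshold has p exactly alpha
        from scipy import stats as sps
        rc = critical_r(n, alpha=0.01)
        t = rc * math.sqrt((n - 2) / (1 - rc**2))
        p = 2 * sps.t.sf(t, df=n - 2)
        assert p == pytest.approx(0.01, rel=1e-9)


class TestDiagnostics:
    def test_duplicated_extreme_site_raises_cooks(self):
        df = _site_table(n=25, seed=7)
        spec = ModelSpec("y", "tfi", "dpc", "cover")
        res = fit_gaussian_lm(df, spec)
        extreme = df.iloc[[np.argmax(np.abs(res.resid))]]
        dup = pd.concat([df, extreme], ignore_index=True)
        dup.loc[len(dup) - 1, "y"] += 30.0  # push it far out
        res2 = fit_gaussian_lm(dup, spec)
        d2 = diagnostics(res2)
        assert d2["residuals"]["cooks_d"].iloc[-1] > d2["cooks_threshold"]

    def test_morans_null_uniform_p(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 100, size=(30, 2))
        ps = []
        for rep in range(40):
            z = rng.normal(size=30)
            _, p = morans_i(z, xy, n_permutations=199, seed=rep)
            ps.append(p)
        # i.i.d. residuals: no systematic rejection at the 5% level
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_morans_detects_gradient(self):
        xy = np.column_stack([np.arange(30.0), np.zeros(30)])
        z = np.arange(30.0)  # strong spatial trend
        i_obs, p = morans_i(z, xy, n_permutations=499, seed=0)
        assert i_obs > 0.5
        assert p < 0.01

    def test_heteroscedasticity_flagged_by_spread_slope(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.uniform(1, 10, n)
        df = pd.DataFrame({
            "h": x, "c": rng.normal(size=n), "l": rng.normal(size=n)})
        df["y"] = 3 * x + rng.normal(0, 0.3 * x, n)  # funnel
        res = fit_gaussian_lm(df, ModelSpec("y", "h", "c", "l"))
        d = diagnostics(res)
        assert d["spread_slope"] > 0
        assert d["spread_slope_p"] < 0.01
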