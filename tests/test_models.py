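"""Collinearity screening, subset selection, OLS fit, and type-2 ANOVA."""

import numpy as np
import pandas as pd
import pytest

from canopybird.hierpart import Predictor, hier_part
from canopybird.models import (
    CollinearityGraph,
    HabitatModel,
    anova_type2,
    fit_ols,
    pairwise_association,
    residual_diagnostics,
    select_final_variables,
)
from _oracles import brute_force_selection


def graph_from_edges(names, edges, threshold=0.7):
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in edges:
        mat.loc[a, b] = mat.loc[b, a] = 0.9
    return CollinearityGraph(matrix=mat, threshold=threshold)


class TestAssociation:
    def test_self_association_is_one(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        g = pairwise_association(df)
        assert g.matrix.loc["a", "a"] == 1.0

    def test_separated_factor_creates_edge(self):
        df = pd.DataFrame(
            {"f": ["A"] * 3 + ["B"] * 3, "x": [1.0, 2, 3, 7, 8, 9]}
        )
        g = pairwise_association(df)
        assert g.matrix.loc["f", "x"] > 0.9
        assert ("f", "x") in g.edges or ("x", "f") in g.edges

    def test_independent_variables_make_no_edge(self, rng):
        df = pd.DataFrame(
            {
                "x": rng.normal(size=1000),
                "y": rng.normal(size=1000),
                "f": rng.choice(["a", "b", "c"], 1000),
            }
        )
        g = pairwise_association(df)
        off = g.matrix.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off < 0.2).all()
        assert g.edges == []

    def test_categorical_pair_uses_cramers_v(self, rng):
        f1 = rng.choice(["a", "b"], 400)
        df = pd.DataFrame({"f1": f1, "f2": f1})  # identical factors
        g = pairwise_association(df)
        assert g.matrix.loc["f1", "f2"] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_association(df)


class TestSelection:
    def test_worked_enumeration(self):
        effects = pd.Series({"A": 0.4, "B": 0.35, "C": 0.1})
        g = graph_from_edges(["A", "B", "C"], [("A", "B")])
        assert select_final_variables(effects, g, forced=()) == ["A", "C"]

    def test_no_edges_selects_everything(self):
        effects = pd.Series({"A": 0.4, "B": 0.3, "C": 0.1})
        g = graph_from_edges(["A", "B", "C"], [])
        assert select_final_variables(effects, g, forced=()) == ["A", "B", "C"]

    def test_collinear_pair_keeps_higher_independent_effect(self):
        # the variable with more independent effects survives a clash
        effects = pd.Series({"age": 0.30, "gap": 0.35, "area": 0.2})
        g = graph_from_edges(["age", "gap", "area"], [("age", "gap")])
        chosen = select_final_variables(effects, g, forced=("area",))
        assert "gap" in chosen and "age" not in chosen

    def test_forced_collinear_rejected(self):
        effects = pd.Series({"a": 0.2, "b": 0.3})
        g = graph_from_edges(["a", "b"], [("a", "b")])
        with pytest.raises(ValueError, match="mutually collinear"):
            select_final_variables(effects, g, forced=("a", "b"))

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(60):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(2, 10))
            names = [f"v{j}" for j in range(k)]
            effects = pd.Series(rng.uniform(-0.05, 0.4, k), index=names)
            edges = [
                (a, b)
                for i, a in enumerate(names)
                for b in names[i + 1:]
                if rng.random() < 0.3
            ]
            g = graph_from_edges(names, edges)
            forced = ("v0",) if not g.conflicts(("v0",)) else ()
            got = select_final_variables(effects, g, forced=forced)
            want = brute_force_selection(
                dict(effects), {frozenset(e) for e in edges}, forced
            )
            assert got == want


def _factor_frame(rng, n_per_cell=4, noise=1.0, effects=True):
    rows = []
    for a in ("a1", "a2"):
        for b in ("b1", "b2", "b3"):
            for _ in range(n_per_cell):
                mu = (a == "a2") * 2.0 + (b == "b3") * 1.0 if effects else 0.0
                rows.append({"A": a, "B": b, "mu": mu})
    df = pd.DataFrame(rows)
    df["y"] = df["mu"] + noise * rng.normal(size=len(df))
    return df


class TestOLS:
    def test_one_factor_recovers_group_means(self, rng):
        df = pd.DataFrame({"f": ["x"] * 5 + ["y"] * 5,
                           "y": np.r_[np.full(5, 2.0), np.full(5, 5.0)]})
        fit = fit_ols(df, "y", ["f"], baselines={"f": "x"})
        assert fit.params["Intercept"] == pytest.approx(2.0)
        assert fit.params["f[y]"] == pytest.approx(3.0)

    def test_against_statsmodels_oracle(self, rng):
        import statsmodels.formula.api as smf

        df = _factor_frame(rng)
        df["x"] = rng.normal(size=len(df))
        df["y"] = df["y"] + 0.5 * df["x"]
        fit = fit_ols(df, "y", ["A", "B", "x"], baselines={"A": "a1", "B": "b1"})
        ref = smf.ols("y ~ C(A, Treatment('a1')) + C(B, Treatment('b1')) + x", df).fit()
        assert fit.rsquared == pytest.approx(ref.rsquared, abs=1e-10)
        assert fit.params["x"] == pytest.approx(ref.params["x"], abs=1e-10)
        assert fit.bse["x"] == pytest.approx(ref.bse["x"], abs=1e-10)

    def test_noiseless_recovery(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": 2.0 + 3.0 * x})
        fit = fit_ols(df, "y", ["x"])
        assert fit.params["x"] == pytest.approx(3.0, abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0)

    def test_aliased_open_category_dropped_and_reported(self, rng):
        n = 40
        mgmt = rng.choice(["Conifer", "Broadleaved", "Open/other"], n)
        age = np.where(mgmt == "Open/other", "Not applicable",
                       rng.choice(["Mixed", "Mature"], n))
        df = pd.DataFrame({"management_simplified": mgmt, "age_simplified": age,
                           "y": rng.normal(size=n)})
        fit = fit_ols(df, "y", ["age_simplified", "management_simplified"])
        # the open/other indicator equals the not-applicable indicator:
        # whichever factor enters second loses that column
        assert any("Open/other" in c for c in fit.aliased)

    def test_too_few_rows_rejected(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=3), "z": rng.normal(size=3),
                           "w": rng.normal(size=3)})
        df["y"] = rng.normal(size=3)
        with pytest.raises(ValueError, match="rows"):
            fit_ols(df, "y", ["x", "z", "w"])


class TestAnovaType2:
    def test_balanced_design_equals_sequential(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = _factor_frame(rng)
        fit = fit_ols(df, "y", ["A", "B"], baselines={"A": "a1", "B": "b1"})
        table = anova_type2(fit)
        ref = anova_lm(smf.ols("y ~ A + B", df).fit(), typ=1)
        for term in ("A", "B"):
            assert table.loc[term, "sum_sq"] == pytest.approx(
                ref.loc[term, "sum_sq"], abs=1e-8
            )

    def test_matches_statsmodels_type2_when_unbalanced(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = _factor_frame(rng).iloc[3:]  # drop rows to unbalance
        df["x"] = rng.normal(size=len(df))
        fit = fit_ols(df, "y", ["A", "B", "x"], baselines={"A": "a1", "B": "b1"})
        table = anova_type2(fit)
        ref = anova_lm(smf.ols("y ~ A + B + x", df).fit(), typ=2)
        for term in ("A", "B", "x"):
            assert table.loc[term, "sum_sq"] == pytest.approx(
                ref.loc[term, "sum_sq"], abs=1e-8
            )
            assert table.loc[term, "p"] == pytest.approx(
                ref.loc[term, "PR(>F)"], abs=1e-8
            )

    def test_order_invariance(self, rng):
        df = _factor_frame(rng)
        df["x"] = rng.normal(size=len(df))
        t1 = anova_type2(fit_ols(df, "y", ["A", "B", "x"]))
        t2 = anova_type2(fit_ols(df, "y", ["x", "B", "A"]))
        for term in ("A", "B", "x"):
            assert t1.loc[term, "F"] == pytest.approx(t2.loc[term, "F"], abs=1e-10)

    def test_single_term_compared_to_intercept_only(self, rng):
        x = rng.normal(size=25)
        df = pd.DataFrame({"x": x, "y": x + rng.normal(size=25)})
        table = anova_type2(fit_ols(df, "y", ["x"]))
        assert table.loc["x", "sum_sq"] > 0


class TestDiagnostics:
    def test_well_specified_model_passes_mostly(self):
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=80)
            df = pd.DataFrame({"x": x, "y": 1 + x + rng.normal(size=80)})
            d = residual_diagnostics(fit_ols(df, "y", ["x"]))
            ok += d["normality_ok"] and d["homoscedastic_ok"]
        assert ok >= 90

    def test_heteroscedasticity_detected(self):
        flagged = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.uniform(1, 5, 120)
            y = x + rng.normal(size=120) * x  # variance grows with the mean
            df = pd.DataFrame({"x": x, "y": y})
            d = residual_diagnostics(fit_ols(df, "y", ["x"]))
            flagged += not d["homoscedastic_ok"]
        assert flagged >= 40

    def test_insufficient_data_guard(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=4), "y": rng.normal(size=4)})
        d = residual_diagnostics(fit_ols(df, "y", ["x"]))
        assert d["status"] == "insufficient data"


class TestHabitatModel:
    def test_model_results_roundtrip(self, rng):
        n = 40
        df = pd.DataFrame(
            {
                "log_total_area": rng.normal(size=n),
                "shrub_density": rng.normal(size=n),
                "age_simplified": rng.choice(["Mixed", "Mature", "Thicket/pole"], n),
            }
        )
        df["richness"] = (
            3.0 * df["log_total_area"]
            + (df["age_simplified"] == "Thicket/pole") * -2.0
            + rng.normal(size=n)
        )
        model = HabitatModel(
            df, "richness", ["log_total_area", "shrub_density", "age_simplified"]
        )
        res = model.fit()
        assert "log_total_area" in res.selected
        assert res.rsquared > 0.5
        assert res.hp.independent.sum() == pytest.approx(res.hp.r2_full, abs=1e-8)
        assert {"Residuals"} <= set(res.anova.index)
        text = res.summary()
        assert "richness" in text and "Type-2 ANOVA" in text
        pred = res.predict(df)
        assert np.allclose(pred, res.fit.fittedvalues)

    def test_selection_prefers_independent_high_effect_variable(self, rng):
        n = 60
        x = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "log_total_area": rng.normal(size=n),
                "a": x,
                "b": 0.95 * x + 0.05 * rng.normal(size=n),  # collinear with a
                "c": rng.normal(size=n),
            }
        )
        df["y"] = df["log_total_area"] + 2 * df["a"] + 0.3 * df["c"] + 0.5 * rng.normal(size=n)
        res = HabitatModel(df, "y", ["log_total_area", "a", "b", "c"]).fit()
        assert ("a" in res.selected) != ("b" in res.selected)  # not both
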