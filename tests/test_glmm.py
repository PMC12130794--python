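"""Model table assembly, transforms, VIF, Wald tests, mixed-model recovery."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from beepac.glmm import (
    add_transforms,
    assemble_model_table,
    fit_interspecific_model,
    fit_intraspecific_model,
    log_z,
    partial_residuals,
    vif,
    wald_tests,
)
from beepac.synthetic import (
    ScenarioCoefficients,
    ScenarioConfig,
    generate_competition_scenario,
)


class TestAssembleModelTable:
    def _inputs(self):
        d1, d2 = date(2020, 7, 1), date(2020, 7, 8)
        indices = pd.DataFrame(
            {
                "date": [d1, d1, d1, d2, d2],
                "species": ["A", "B", "C", "A", "B"],
                "inter_acting": [0.2, 0.3, 0.1, 0.25, 0.15],
                "intra": [0.5, 0.6, 0.4, 0.55, 0.45],
            }
        )
        abund = indices[["date", "species"]].assign(
            abundance_est=[0.5, 0.3, 0.2, 0.6, 0.4]
        )
        dens = pd.Series({d1: 20.0, d2: 15.0})
        traits = pd.DataFrame(
            {"bee_species": ["A", "B", "C"], "proboscis_mm": [7.0, 8.0, 13.0]}
        )
        return indices, abund, dens, traits

    def test_row_per_day_species_and_cellwise_identity(self):
        indices, abund, dens, traits = self._inputs()
        table = assemble_model_table(indices, abund, dens, traits)
        assert len(table) == 5
        merged = table.set_index(["date", "species"])
        assert merged.loc[(date(2020, 7, 1), "B"), "inter_acting"] == 0.3
        assert merged.loc[(date(2020, 7, 8), "A"), "floral_density"] == 15.0
        assert merged.loc[(date(2020, 7, 1), "C"), "proboscis_mm"] == 13.0
        assert (table["flowering_period"] == "early").all()

    def test_missing_trait_names_species(self):
        indices, abund, dens, traits = self._inputs()
        with pytest.raises(KeyError, match="C"):
            assemble_model_table(indices, abund, dens, traits.iloc[:2])


class TestLogZ:
    def test_closed_form_example(self):
        e = np.e
        out = log_z([e, e**2, e**3])
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_output_centered_and_unit_sd(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1, 0.5, 40)
        out = log_z(x)
        assert abs(out.mean()) < 1e-9
        assert out.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            log_z([5, 5, 5])
        with pytest.raises(ValueError):
            log_z([1.0, -2.0, 3.0])


class TestVIF:
    def test_orthogonal_predictors_are_one(self):
        n = 64
        t = np.arange(n)
        table = pd.DataFrame(
            {"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n)}
        )
        out = vif(table, predictors=["a", "b"])
        assert out["a"] == pytest.approx(1.0, abs=1e-9)
        assert out["b"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_predictor_is_singular(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"a": rng.normal(size=30)})
        table["b"] = table["a"]
        with pytest.raises(np.linalg.LinAlgError):
            vif(table, predictors=["a", "b"])

    def test_matches_auxiliary_regression_oracle(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(2)
        z = rng.normal(size=(50, 1))
        X = 0.7 * z + 0.5 * rng.normal(size=(50, 3))
        table = pd.DataFrame(X, columns=["a", "b", "c"])
        out = vif(table, predictors=["a", "b", "c"])
        design = np.column_stack([np.ones(50), X])
        for j, name in enumerate(["a", "b", "c"]):
            expected = variance_inflation_factor(design, j + 1)
            assert out[name] == pytest.approx(expected, rel=1e-8)


@pytest.fixture(scope="module")
def fitted(scenario_table):
    table, truth = scenario_table
    return fit_interspecific_model(table), table, truth


class TestFittedModel:
    def test_reports_full_structure(self, fitted):
        model, table, _ = fitted
        terms = set(model.fixed_effects["term"])
        assert "abundance_lz" in terms
        assert "abundance_lz:floral_density_lz" in terms
        assert any(t.startswith("C(year)") for t in terms)
        assert model.random_effect["sd"] >= 0
        assert model.n_obs == len(table)
        assert all(v >= 1 for v in model.vif.values())

    def test_single_df_wald_equals_z_squared(self, fitted):
        model, *_ = fitted
        fe = model.fixed_effects.set_index("term")
        wald = model.wald.set_index("term")
        for term in ("abundance_lz", "proboscis_z", "abundance_lz:floral_density_lz"):
            assert wald.loc[term, "chi2"] == pytest.approx(
                fe.loc[term, "z_value"] ** 2, rel=1e-6
            )
        assert "Intercept" not in wald.index
        assert (wald["df"].loc[["C(year)"]] == 4).all()

    def test_true_large_effect_detected(self, fitted):
        model, *_ = fitted
        wald = model.wald.set_index("term")
        assert wald.loc["abundance_lz", "p_value"] < 0.05

    def test_year_subset_refit_runs(self, fitted):
        _, table, _ = fitted
        sub = fit_interspecific_model(table, years=[2020, 2021, 2022])
        assert sub.n_obs == (table["year"] >= 2020).sum()
        assert set(sub.fixed_effects.columns) == {
            "term", "estimate", "std_error", "z_value", "p_value",
        }

    def test_row_order_and_label_invariance(self, fitted):
        _, table, _ = fitted
        base = fit_interspecific_model(table).fixed_effects.set_index("term")["estimate"]
        shuffled = table.sample(frac=1, random_state=0).reset_index(drop=True)
        relabeled = shuffled.assign(species=shuffled["species"].map(lambda s: "X" + s))
        again = fit_interspecific_model(relabeled).fixed_effects.set_index("term")["estimate"]
        pd.testing.assert_series_equal(base, again, atol=1e-6, rtol=1e-4)

    def test_intraspecific_uses_all_non_missing_rows(self, fitted):
        _, table, _ = fitted
        model = fit_intraspecific_model(table)
        assert model.n_obs == table["intra"].notna().sum()


class TestParameterRecovery:
    def test_planted_coefficients_recovered(self):
        hits = {"abundance": 0, "interaction": 0, "proboscis": 0}
        n_rep = 12
        for s in range(n_rep):
            table, truth = generate_competition_scenario(ScenarioConfig(seed=300 + s))
            coef = truth["coefficients"]
            fe = fit_interspecific_model(table).fixed_effects.set_index("term")
            ab = fe.loc["abundance_lz"]
            it = fe.loc["abundance_lz:floral_density_lz"]
            if abs(ab["estimate"] - coef["abundance"]) < 2 * ab["std_error"] and ab["estimate"] > 0:
                hits["abundance"] += 1
            if abs(it["estimate"] - coef["interaction"]) < 2 * it["std_error"] and it["estimate"] < 0:
                hits["interaction"] += 1
            pr = fit_intraspecific_model(table).fixed_effects.set_index("term").loc["proboscis_z"]
            if abs(pr["estimate"] - coef["proboscis"]) < 2 * pr["std_error"] and pr["estimate"] > 0:
                hits["proboscis"] += 1
        # smoke-scale recovery check; the full 50-replicate coverage check
        # lives in the acceptance suite
        for key, n in hits.items():
            assert n >= round(0.75 * n_rep), f"{key}: {n}/{n_rep}"

    def test_null_generator_estimates_near_zero(self):
        null = ScenarioCoefficients(
            abundance=0.0, density=0.0, proboscis=0.0, interaction=0.0,
            period_middle=0.0, period_late=0.0,
        )
        ok = 0
        n_rep = 8
        for s in range(n_rep):
            table, _ = generate_competition_scenario(
                ScenarioConfig(seed=800 + s, coefficients=null)
            )
            fe = fit_interspecific_model(table).fixed_effects.set_index("term")
            within = sum(
                abs(fe.loc[t, "estimate"]) < 2 * fe.loc[t, "std_error"]
                for t in ("abundance_lz", "floral_density_lz", "proboscis_z")
            )
            ok += within == 3
        assert ok >= round(0.75 * n_rep)


class TestPartialResiduals:
    def test_slope_matches_coefficient(self, fitted):
        model, *_ = fitted
        out = partial_residuals(model, "abundance_lz")
        pts = out["points"]
        slope = np.polyfit(pts["term_value"], pts["partial_residual"], 1)[0]
        coef = model.fixed_effects.set_index("term").loc["abundance_lz", "estimate"]
        assert slope == pytest.approx(coef, abs=0.02)

    def test_three_density_quantile_curves(self, fitted):
        model, *_ = fitted
        out = partial_residuals(model, "abundance_lz")
        assert out["lines"]["density_quantile"].nunique() == 3
        # lower density -> steeper positive abundance slope (negative interaction)
        lines = out["lines"]
        slopes = {
            q: np.polyfit(g["term_value"], g["predicted"], 1)[0]
            for q, g in lines.groupby("density_quantile")
        }
        assert slopes[0.1] > slopes[0.9]
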