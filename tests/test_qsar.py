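"""Response transforms, design matrices, OLS fitting and stepwise selection."""

import numpy as np
import pytest

import thioscreen as ts
from thioscreen import qsar
from thioscreen.errors import DimensionError, DomainError, SchemaError

MODEL1_DESCRIPTORS = ("e_lumo", "chi", "s_soft", "logp", "n_rotb")


class TestTransformResponse:
    def test_log10_of_one_micromolar_is_zero(self):
        assert ts.transform_response(1.0, "log10") == 0.0

    def test_pic50_of_least_active_on_colorectal(self):
        assert ts.transform_response(22.80, "log10_reciprocal") == pytest.approx(
            -1.358, abs=5e-4
        )

    def test_reciprocal_of_most_active_on_colorectal(self):
        assert ts.transform_response(0.06, "reciprocal") == pytest.approx(
            16.667, abs=5e-4
        )

    def test_log10_reciprocal_is_pointwise_negation_of_log10(self):
        x = np.array([0.06, 1.95, 22.80, 43.25])
        np.testing.assert_allclose(
            ts.transform_response(x, "log10_reciprocal"),
            -ts.transform_response(x, "log10"),
        )

    @pytest.mark.parametrize("kind", ["reciprocal", "log10", "log10_reciprocal"])
    def test_nonpositive_ic50_rejected(self, kind):
        with pytest.raises(DomainError):
            ts.transform_response(0.0, kind)

    @pytest.mark.parametrize(
        "kind", ["identity", "reciprocal", "log10", "log10_reciprocal"]
    )
    def test_inverse_transform_round_trip(self, kind):
        x = np.array([0.06, 1.95, 22.80])
        y = ts.transform_response(x, kind)
        np.testing.assert_allclose(qsar.inverse_transform(y, kind), x, rtol=1e-12)


class TestBuildDesignMatrix:
    def test_colorectal_panel_four_by_five(
        self, descriptors_aqueous, physchem, activities
    ):
        spec = ts.ModelSpec(
            response="identity",
            descriptor_names=MODEL1_DESCRIPTORS,
            phase="aqueous",
        )
        X, y, comps = ts.build_design_matrix(
            descriptors_aqueous, physchem, spec, activities, "HCT"
        )
        assert X.shape == (4, 5)
        assert comps == ["2H", "6H", "7H", "9H"]
        np.testing.assert_allclose(y, [22.80, 43.25, 1.95, 0.06])

    def test_single_descriptor_gives_single_column(self, physchem, activities):
        spec = ts.ModelSpec(response="identity", descriptor_names=("logp",))
        X, _, _ = ts.build_design_matrix(None, physchem, spec, activities, "HCT")
        assert X.shape == (4, 1)

    def test_lung_line_drops_untested_compounds(
        self, descriptors_aqueous, physchem, activities
    ):
        spec = ts.ModelSpec(response="identity", descriptor_names=("logp",))
        _, _, comps = ts.build_design_matrix(
            descriptors_aqueous, physchem, spec, activities, "A549"
        )
        assert comps == ["7H", "9H"]

    def test_unresolvable_descriptor_lists_valid_names(self, physchem, activities):
        spec = ts.ModelSpec(response="identity", descriptor_names=("bogus",))
        with pytest.raises(SchemaError, match="bogus"):
            ts.build_design_matrix(None, physchem, spec, activities, "HCT")

    def test_zero_usable_rows_is_domain_error(self, physchem, activities):
        spec = ts.ModelSpec(response="identity", descriptor_names=("logp",))
        with pytest.raises(DomainError):
            ts.build_design_matrix(None, physchem, spec, activities, "NOPE")


class TestFitOls:
    def test_exact_linear_data_recovers_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-2, 2, size=(20, 2))
        y = 1.0 + 2.0 * X[:, 0] - 3.0 * X[:, 1]
        fit = ts.fit_ols(X, y, names=["x1", "x2"])
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients["x1"] == pytest.approx(2.0, abs=1e-8)
        assert fit.coefficients["x2"] == pytest.approx(-3.0, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)
        assert not fit.underdetermined

    def test_four_compound_fit_is_flagged_underdetermined(
        self, descriptors_aqueous, physchem, activities
    ):
        spec = ts.ModelSpec(
            response="identity",
            descriptor_names=MODEL1_DESCRIPTORS,
            phase="aqueous",
        )
        X, y, _ = ts.build_design_matrix(
            descriptors_aqueous, physchem, spec, activities, "HCT"
        )
        fit = ts.fit_ols(X, y, names=spec.descriptor_names)
        assert fit.underdetermined
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)
        assert fit.adj_r2 is None
        assert fit.std_errors is None

    def test_constant_response_r2_zero_by_convention(self):
        X = np.arange(10, dtype=float)[:, None]
        y = np.full(10, 3.0)
        fit = ts.fit_ols(X, y)
        assert fit.r2 == 0.0

    def test_matches_statsmodels_on_noisy_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        y = 0.5 + X @ [1.0, -2.0, 0.3] + rng.normal(0, 0.2, 50)
        fit = ts.fit_ols(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            [fit.intercept, *fit.coefficients.values()], ref.params, rtol=1e-8
        )
        assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-10)
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj, rel=1e-10)
        np.testing.assert_allclose(
            [fit.intercept_se, *fit.std_errors.values()], ref.bse, rtol=1e-6
        )

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            ts.fit_ols(np.empty((0, 2)), np.empty(0))

    def test_non_finite_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(Exception):
            ts.fit_ols(X, np.array([1.0, 2.0]))

    def test_r2_invariant_under_descriptor_rescaling(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = X @ [1.0, 2.0] + rng.normal(0, 0.5, 30)
        r2a = ts.fit_ols(X, y).r2
        X2 = X.copy()
        X2[:, 0] = 100.0 * X2[:, 0] + 7.0
        r2b = ts.fit_ols(X2, y).r2
        assert r2b == pytest.approx(r2a, rel=1e-10)


class TestStepwiseForward:
    def test_recovers_true_two_descriptor_support(self):
        rng = np.random.default_rng(11)
        cols = {f"d{j}": rng.normal(size=40) for j in range(6)}
        y = 2.0 * cols["d2"] - 1.5 * cols["d4"]
        selected, trace = ts.stepwise_forward(cols, y, max_terms=4)
        assert set(selected[:2]) == {"d2", "d4"}
        assert trace[1]["r2"] == pytest.approx(1.0)
        # nothing improves after an exact fit
        assert len(selected) == 2

    def test_single_candidate_selected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        selected, _ = ts.stepwise_forward({"only": x}, 3 * x + 1, max_terms=3)
        assert selected == ["only"]

    def test_small_panel_caps_at_two_terms(self):
        rng = np.random.default_rng(4)
        cols = {f"d{j}": rng.normal(size=4) for j in range(5)}
        y = rng.normal(size=4)
        selected, _ = ts.stepwise_forward(cols, y, max_terms=3)
        assert len(selected) <= 2

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(DomainError):
            ts.stepwise_forward({}, np.zeros(5), max_terms=1)


class TestApplyModel:
    def test_simple_evaluation(self):
        pred = ts.apply_model(1.0, {"x": 2.0}, {"x": 3.0})
        assert pred[0] == pytest.approx(7.0)

    def test_all_zero_coefficients_give_intercept(self):
        rows = [{"a": 1.0}, {"a": -5.0}]
        np.testing.assert_allclose(ts.apply_model(2.5, {"a": 0.0}, rows), 2.5)

    def test_published_identity_model_does_not_reproduce_observed_activity(
        self, descriptors_gas, physchem
    ):
        # evaluating the published five-term linear model for IC50(HCT) on
        # the first compound's gas-phase descriptors gives ~-171, far from
        # the measured 22.80 uM: the printed equation is an evaluable
        # artifact, not a certified model
        coeffs = {
            "e_lumo": -3.58, "chi": 11.55, "s_soft": 50.9,
            "logp": -9.089, "n_rotb": -15.61,
        }
        desc = qsar.descriptor_frame(descriptors_gas, physchem)
        row = desc.loc[["2H"], list(coeffs)]
        pred = ts.apply_model(-223.0, coeffs, row)
        assert pred[0] == pytest.approx(-171.1, abs=0.5)
        assert abs(pred[0] - 22.80) > 100

    def test_missing_descriptor_is_schema_error(self):
        with pytest.raises(SchemaError, match="x"):
            ts.apply_model(0.0, {"x": 1.0}, {"y": 2.0})


class TestRSquared:
    def test_perfect_prediction(self):
        assert ts.r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_is_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert ts.r_squared(obs, np.full(4, obs.mean())) == 0.0

    def test_hand_computed_value(self):
        # SS_res = 0.01+0.01+0.04+0.04 = 0.10, SS_tot = 5.0
        obs = [1.0, 2.0, 3.0, 4.0]
        pred = [1.1, 1.9, 3.2, 3.8]
        assert ts.r_squared(obs, pred) == pytest.approx(0.980, abs=5e-4)

    def test_worse_than_mean_clamps_to_zero(self):
        assert ts.r_squared([1.0, 2.0], [10.0, -10.0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            ts.r_squared([1, 2, 3], [1, 2])


class TestPredictedVsObserved:
    def test_exact_fit_has_zero_residuals(self):
        X = np.linspace(0, 1, 10)[:, None]
        y = 2.0 + 3.0 * X[:, 0]
        fit = ts.fit_ols(X, y)
        table = ts.predicted_vs_observed(fit, X, y)
        np.testing.assert_allclose(table["residual"], 0.0, atol=1e-10)

    def test_residuals_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 2))
        y = 1.0 + X @ [0.5, -1.0] + rng.normal(0, 0.3, 25)
        fit = ts.fit_ols(X, y)
        table = ts.predicted_vs_observed(fit, X, y)
        assert table["residual"].sum() == pytest.approx(0.0, abs=1e-8)

    def test_empty_matrix_rejected(self):
        X = np.ones((3, 1))
        fit = ts.fit_ols(X, np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DimensionError):
            ts.predicted_vs_observed(fit, np.empty((0, 1)), np.empty(0))

    def test_log10_reciprocal_predictions_negate_log10(
        self, descriptors_aqueous, physchem, activities
    ):
        # the sign-flip relation between the third and fourth published
        # response transforms, on the same design
        names = ("logp", "n_rotb")
        for cell in ("HCT",):
            spec_a = ts.ModelSpec(response="log10_reciprocal", descriptor_names=names)
            spec_b = ts.ModelSpec(response="log10", descriptor_names=names)
            Xa, ya, _ = ts.build_design_matrix(
                descriptors_aqueous, physchem, spec_a, activities, cell
            )
            Xb, yb, _ = ts.build_design_matrix(
                descriptors_aqueous, physchem, spec_b, activities, cell
            )
            fa = ts.fit_ols(Xa, ya)
            fb = ts.fit_ols(Xb, yb)
            np.testing.assert_allclose(fa.predictions, -fb.predictions, atol=1e-10)
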