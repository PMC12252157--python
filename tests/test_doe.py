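"""Factorial design, centered regression, pruning, and comparison statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from printfid import doe
from printfid import synthgen as sg


def brute_force_ols(runs: pd.DataFrame, response: str, terms=doe.ALL_TERMS):
    """Independent normal-equations solve on the centered design matrix."""
    a = runs["nozzle_G"].to_numpy(float) - 26.0
    b = runs["pressure_kPa"].to_numpy(float) - 180.0
    c = runs["velocity_mm_s"].to_numpy(float) - 15.0
    cols = {"A": a, "B": b, "C": c}
    X = [np.ones(len(runs))]
    for t in terms:
        col = np.ones(len(runs))
        for letter in t:
            col = col * cols[letter]
        X.append(col)
    X = np.column_stack(X)
    y = runs[response].to_numpy(float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return dict(zip(("1", *terms), beta))


class TestDesign:
    def test_single_replicate_has_50_runs(self):
        runs = doe.build_full_factorial(1)
        assert len(runs) == 50
        assert runs[["nozzle_G", "pressure_kPa", "velocity_mm_s"]].drop_duplicates().shape[0] == 50

    def test_seventeen_replicates_give_850_runs(self):
        runs = doe.build_full_factorial(17)
        assert len(runs) == 850
        counts = runs.groupby(["nozzle_G", "pressure_kPa", "velocity_mm_s"]).size()
        assert (counts == 17).all()

    def test_centered_columns_sum_to_zero(self):
        runs = doe.build_full_factorial(3)
        assert (runs["nozzle_G"] - 26).sum() == 0
        assert (runs["pressure_kPa"] - 180).sum() == 0
        assert (runs["velocity_mm_s"] - 15).sum() == 0

    def test_replicates_must_be_positive(self):
        with pytest.raises(ValueError):
            doe.build_full_factorial(0)


class TestReferenceModels:
    def test_eq19_center_value(self):
        assert doe.reference_model("eq19").predict(26, 180, 15) == pytest.approx(1.0980)

    def test_eq20_center_value(self):
        assert doe.reference_model("eq20").predict(26, 180, 15) == pytest.approx(51.810)

    def test_27g_balanced_mean(self):
        """Averaging over the balanced pressure x velocity grid at 27G leaves
        only the intercept and the A main effect."""
        m = doe.reference_model("eq19")
        vals = [
            m.predict(27, b, c)
            for b, c in itertools.product((160, 170, 180, 190, 200), (5, 10, 15, 20, 25))
        ]
        assert np.mean(vals) == pytest.approx(0.5488, abs=1e-12)

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            doe.reference_model("eq21")

    def test_vectorized_predict(self):
        m = doe.reference_model("eq19")
        out = m.predict(np.array([25, 27]), 180, 15)
        assert out.shape == (2,)
        assert out[0] == pytest.approx(m.predict(25, 180, 15))


class TestFit:
    def test_noiseless_recovery(self):
        runs = sg.generate_doe_responses(
            doe.FactorialDesign(), sg.surface_truth("eq19", 0.0)
        )
        res = doe.fit_factorial_model(runs, "filament_diameter_mm")
        truth = doe.reference_model("eq19").params
        for term in ("1", *doe.ALL_TERMS):
            assert res.params[term] == pytest.approx(truth.get(term, 0.0), abs=1e-8)

    def test_agrees_with_normal_equations_oracle(self):
        runs = sg.generate_doe_responses(
            doe.FactorialDesign(), sg.surface_truth("eq20", 2.0), seed=9
        )
        res = doe.fit_factorial_model(runs, "ssim_pct")
        oracle = brute_force_ols(runs, "ssim_pct")
        for term, beta in oracle.items():
            assert res.params[term] == pytest.approx(beta, abs=1e-10)

    def test_constant_response(self):
        runs = doe.build_full_factorial(1).assign(y=5.0)
        res = doe.fit_factorial_model(runs, "y")
        assert res.params["1"] == 5.0
        assert all(res.params[t] == 0.0 for t in doe.ALL_TERMS)
        assert res.rsquared == 0.0

    def test_missing_cells_named(self):
        incomplete = doe.build_full_factorial(1).iloc[:-3].assign(y=1.0)
        with pytest.raises(ValueError, match="empty cells"):
            doe.FactorialModel.from_dataframe(incomplete, "y")

    def test_balanced_main_effects_equal_cell_mean_contrasts(self):
        """OLS main-effect predictions equal raw level means on balanced data."""
        runs = sg.generate_doe_responses(
            doe.FactorialDesign(replicates=2), sg.surface_truth("eq19", 0.1), seed=4
        )
        res = doe.fit_factorial_model(runs, "filament_diameter_mm")
        effects = doe.main_effects(runs, "filament_diameter_mm")
        for level, mean in effects["A"].items():
            others = [
                res.predict(level, b, c)
                for b, c in itertools.product((160, 170, 180, 190, 200), (5, 10, 15, 20, 25))
            ]
            assert mean == pytest.approx(np.mean(others), abs=1e-9)


class TestPrune:
    def test_recovers_eq19_support_under_small_noise(self):
        runs = sg.generate_doe_responses(
            doe.FactorialDesign(replicates=2), sg.surface_truth("eq19", 0.01), seed=1
        )
        res = doe.fit_factorial_model(runs, "filament_diameter_mm")
        pruned, trace = res.prune(alpha=0.01)
        assert pruned.terms == ("A", "B", "C", "AB", "AC")
        dropped = set(trace.loc[~trace.kept, "term"])
        assert dropped == {"BC", "ABC"}

    def test_alpha_one_keeps_everything(self):
        runs = sg.generate_doe_responses(
            doe.FactorialDesign(), sg.surface_truth("eq19", 0.05), seed=2
        )
        res = doe.fit_factorial_model(runs, "filament_diameter_mm")
        pruned, _ = res.prune(alpha=1.0 + 1e-9)
        assert pruned.terms == doe.ALL_TERMS

    def test_single_significant_term(self, rng):
        runs = doe.build_full_factorial(2)
        a = runs["nozzle_G"].to_numpy(float) - 26
        runs["y"] = 1.0 + 2.0 * a + rng.normal(0, 0.05, len(runs))
        pruned, _ = doe.fit_factorial_model(runs, "y").prune(alpha=0.01)
        assert pruned.terms == ("A",)

    def test_literal_model_cannot_be_pruned(self):
        with pytest.raises(ValueError, match="fitted model"):
            doe.reference_model("eq19").prune()


class TestMainEffectsAndSurface:
    def test_constant_response_level_means(self):
        runs = doe.build_full_factorial(1).assign(y=3.5)
        effects = doe.main_effects(runs, "y")
        for f in "ABC":
            assert (effects[f] == 3.5).all()

    def test_level_means_average_to_grand_mean(self):
        runs = sg.generate_doe_responses(
            doe.FactorialDesign(), sg.surface_truth("eq20", 1.0), seed=3
        )
        effects = doe.main_effects(runs, "ssim_pct")
        grand = runs["ssim_pct"].mean()
        for f in "ABC":
            assert effects[f].mean() == pytest.approx(grand, abs=1e-9)

    def test_eq19_main_effect_at_27g(self):
        runs = sg.generate_doe_responses(
            doe.FactorialDesign(), sg.surface_truth("eq19", 0.0)
        )
        effects = doe.main_effects(runs, "filament_diameter_mm")
        assert effects["A"][27] == pytest.approx(0.5488, abs=1e-12)

    def test_unbalanced_warns(self):
        runs = doe.build_full_factorial(2).assign(y=1.0)
        lopsided = pd.concat([runs, runs.head(5)], ignore_index=True)
        with pytest.warns(UserWarning, match="unbalanced"):
            doe.main_effects(lopsided, "y")

    def test_surface_monotone_decrease_with_velocity_at_27g(self):
        m = doe.reference_model("eq19")
        _, _, Z = doe.response_surface_grid(m, ("A", "C"), fixed_level=180.0)
        row_27 = Z[-1]  # A axis spans 25..27
        assert all(a > b for a, b in zip(row_27, row_27[1:]))

    def test_1x1_grid_equals_predict(self):
        m = doe.reference_model("eq20")
        xs, ys, Z = doe.response_surface_grid(m, ("B", "C"), num=1)
        assert Z[0, 0] == pytest.approx(m.predict(26, xs[0], ys[0]))

    def test_pruned_eq20_is_planar_in_b_at_fixed_a(self):
        """No BC term: at fixed nozzle the surface is linear in pressure."""
        m = doe.reference_model("eq20")
        _, _, Z = doe.response_surface_grid(m, ("B", "C"), fixed_level=26.0, num=5)
        second_diff = np.diff(Z, n=2, axis=0)
        assert np.allclose(second_diff, 0.0, atol=1e-10)

    def test_unknown_factor_rejected(self):
        with pytest.raises(KeyError):
            doe.response_surface_grid(doe.reference_model("eq19"), ("A", "D"))


class TestComparisonStats:
    def test_zero_error_when_identical(self):
        y = np.array([1.0, 2.0, 3.0])
        assert doe.mae(y, y) == 0.0
        assert doe.mse(y, y) == 0.0

    def test_perfect_linear_correlation(self):
        assert doe.pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        assert doe.pearson([1, 2, 3, 4], [4, 1, 3, 2]) == pytest.approx(-0.4)

    def test_pearson_properties(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert doe.pearson(x, y) == pytest.approx(doe.pearson(y, x))
        assert doe.pearson(2 * x + 3, y) == pytest.approx(doe.pearson(x, y))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            doe.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCoefficientRecoveryUnderNoise:
    def test_estimates_unbiased_over_seeds(self):
        """Mean estimation error over many noisy simulations stays within
        the Monte-Carlo standard error band."""
        sigma, n_seeds = 0.1, 200
        truth = doe.reference_model("eq19").params
        biases = {t: [] for t in ("A", "B", "C")}
        for seed in range(n_seeds):
            runs = sg.generate_doe_responses(
                doe.FactorialDesign(), sg.surface_truth("eq19", sigma), seed=seed
            )
            res = doe.fit_factorial_model(runs, "filament_diameter_mm")
            for t in biases:
                biases[t].append(res.params[t] - truth[t])
        for t, vals in biases.items():
            assert abs(np.mean(vals)) < 2 * sigma / np.sqrt(n_seeds)
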