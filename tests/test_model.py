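"""Unit tests for the Lp-SVM model core."""

import numpy as np
import pytest

from lpsvm.data import Dataset
from lpsvm.model import (
    FitOptions,
    compute_bias,
    decision_function,
    fit_irwp,
    penalty,
    predict,
    primal_from_dual,
    reweight_diag,
    selected_features,
    solve_weighted_dual,
)
from lpsvm.synthetic import WestonSpec, generate_weston, standardize


def weston_train(n=120, n_features=30, seed=42):
    data = generate_weston(WestonSpec(n_samples=n, n_features=n_features, seed=seed))
    std, _, _ = standardize(data)
    return std


class TestPenalty:
    @pytest.mark.parametrize(
        "w,p,expected",
        [
            ([1.0], 0.5, 0.5),
            ([1.0], 2.0, 0.5),
            ([0.0, 0.0, 0.0], 0.5, 0.0),
            ([2.0, -2.0], 2.0, 4.0),
        ],
    )
    def test_values(self, w, p, expected):
        assert penalty(np.array(w), p) == pytest.approx(expected)

    def test_rejects_nonfinite_and_bad_p(self):
        with pytest.raises(ValueError, match="non-finite"):
            penalty(np.array([np.nan]), 1.0)
        with pytest.raises(ValueError, match="p must"):
            penalty(np.array([1.0]), 0.0)


class TestReweightDiag:
    def test_p2_gives_exact_ones(self):
        w = np.array([0.0, 0.3, -7.0])
        np.testing.assert_array_equal(reweight_diag(w, 2.0, 1e-8), np.ones(3))

    def test_p1_matches_inverse_magnitude(self):
        v = reweight_diag(np.array([0.5]), 1.0, 1e-12)
        assert v[0] == pytest.approx(2.0, rel=1e-9)

    def test_epsilon_bounds_the_blowup_at_zero(self):
        v = reweight_diag(np.array([0.0]), 0.5, 1e-8)
        assert v[0] == pytest.approx(1e-8 ** (-1.5))  # = 1e12
        assert np.isfinite(v).all()

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError, match="epsilon"):
            reweight_diag(np.array([1.0]), 1.0, 0.0)


class TestWeightedDualAndPrimal:
    def test_toy_dual_and_primal(self, toy1d, hard_margin_opts):
        v = np.ones(1)
        sol = solve_weighted_dual(toy1d, v, hard_margin_opts)
        np.testing.assert_allclose(sol.alpha, [0.5, 0.5], atol=1e-9)
        w = primal_from_dual(toy1d, sol.alpha, v)
        np.testing.assert_allclose(w, [1.0], atol=1e-9)

    def test_zero_alpha_gives_zero_weights(self, sep2d):
        w = primal_from_dual(sep2d, np.zeros(4), np.ones(2))
        np.testing.assert_array_equal(w, np.zeros(2))

    def test_primal_scales_inversely_with_v(self, sep2d, hard_margin_opts):
        v = np.array([0.5, 2.0])
        sol = solve_weighted_dual(sep2d, v, hard_margin_opts)
        w = primal_from_dual(sep2d, sol.alpha, v)
        w_scaled = primal_from_dual(sep2d, sol.alpha, 3.0 * v)
        np.testing.assert_allclose(w_scaled, w / 3.0, rtol=1e-12)

    def test_nonseparable_hard_margin_instructs_finite_box(self):
        data = Dataset(np.array([[1.0], [1.0]]), np.array([1.0, -1.0]))
        with pytest.raises(ValueError, match="box_c"):
            solve_weighted_dual(data, np.ones(1), FitOptions(box_c=np.inf))

    def test_length_mismatch_rejected(self, sep2d):
        with pytest.raises(ValueError, match="length"):
            primal_from_dual(sep2d, np.zeros(3), np.ones(2))
        with pytest.raises(ValueError, match="length"):
            primal_from_dual(sep2d, np.zeros(4), np.ones(3))


class TestComputeBias:
    def test_toy_bias_is_zero(self, toy1d, hard_margin_opts):
        sol = solve_weighted_dual(toy1d, np.ones(1), hard_margin_opts)
        b = compute_bias(toy1d, np.array([1.0]), sol.alpha, hard_margin_opts)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_translation_shifts_bias(self, toy1d, hard_margin_opts):
        shift = 0.7
        moved = Dataset(toy1d.features + shift, toy1d.labels)
        sol = solve_weighted_dual(toy1d, np.ones(1), hard_margin_opts)
        w = np.array([1.0])
        b0 = compute_bias(toy1d, w, sol.alpha, hard_margin_opts)
        b1 = compute_bias(moved, w, sol.alpha, hard_margin_opts)
        assert b1 - b0 == pytest.approx(shift, abs=1e-9)

    def test_single_support_vector_is_exact(self, sep2d, hard_margin_opts):
        alpha = np.array([0.0, 0.9, 0.0, 0.0])
        w = np.array([0.4, -0.2])
        b = compute_bias(sep2d, w, alpha, hard_margin_opts)
        assert b == pytest.approx(w @ sep2d.features[1] - sep2d.labels[1])

    def test_empty_support_raises(self, sep2d, hard_margin_opts):
        with pytest.raises(ValueError, match="support"):
            compute_bias(sep2d, np.zeros(2), np.zeros(4), hard_margin_opts)


class TestFitIrwp:
    def test_toy_fixed_point_for_any_p(self, toy1d):
        for p in (0.3, 0.8, 1.0, 2.0):
            model = fit_irwp(toy1d, FitOptions(p=p, box_c=np.inf, smo_tol=1e-8))
            np.testing.assert_allclose(model.weights, [1.0], atol=1e-6)
            assert model.bias == pytest.approx(0.0, abs=1e-6)
            assert model.converged

    def test_p2_converges_in_two_outer_iterations(self, sep2d):
        model = fit_irwp(sep2d, FitOptions(p=2.0, box_c=np.inf, smo_tol=1e-8))
        assert model.n_outer_iters <= 2
        assert model.converged

    def test_single_class_data_rejected(self):
        data = Dataset(np.array([[1.0], [2.0]]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="both classes"):
            fit_irwp(data, FitOptions())

    def test_separable_fit_respects_margins(self, sep2d):
        model = fit_irwp(sep2d, FitOptions(p=1.0, box_c=np.inf, smo_tol=1e-8))
        margins = sep2d.labels * (sep2d.features @ model.weights - model.bias)
        assert (margins >= 1.0 - 1e-6).all()

    def test_trajectory_and_support_recorded(self):
        train = weston_train()
        model = fit_irwp(train, FitOptions(p=0.5))
        assert len(model.weight_trajectory) == model.n_outer_iters
        assert len(model.support_indices) >= 1

    def test_smoothed_penalty_descends(self):
        # majorize-minimize property, isolated from solver inexactness by
        # a tight inner tolerance
        train = weston_train()
        opts = FitOptions(p=0.5, smo_tol=1e-9)
        model = fit_irwp(train, opts)
        vals = [
            float(np.sum((np.abs(w) + opts.epsilon) ** opts.p)) / 2.0
            for w in model.weight_trajectory
        ]
        diffs = np.diff(vals)
        assert (diffs <= 1e-6).all()

    def test_noise_features_end_negligible_on_weston(self):
        # 500 training samples: the 94 noise coordinates collapse far
        # below the informative ones at p = 0.8
        pool = generate_weston(WestonSpec(n_samples=500, seed=11))
        train, _, _ = standardize(pool)
        opts = FitOptions(p=0.8)
        model = fit_irwp(train, opts)
        mags = np.abs(model.weights)
        cutoff = opts.feature_threshold * mags.max()
        assert (mags[6:] < cutoff).sum() >= 88

    def test_scale_equivariance_of_raw_fits(self, sep2d):
        c = 4.0
        opts = FitOptions(p=1.0, box_c=np.inf, smo_tol=1e-9)
        base = fit_irwp(sep2d, opts)
        scaled = fit_irwp(Dataset(c * sep2d.features, sep2d.labels), opts)
        # the epsilon smoother breaks exact equivariance on coordinates
        # that collapse to zero, hence the absolute floor
        np.testing.assert_allclose(
            c * scaled.weights,
            base.weights,
            rtol=1e-4,
            atol=1e-4 * np.abs(base.weights).max(),
        )
        np.testing.assert_array_equal(
            predict(scaled, c * sep2d.features), predict(base, sep2d.features)
        )


class TestPredict:
    def test_toy_decision_values_and_labels(self, toy1d):
        model = fit_irwp(toy1d, FitOptions(p=1.0, box_c=np.inf, smo_tol=1e-8))
        assert decision_function(model, np.array([3.0])) == pytest.approx(3.0, abs=1e-6)
        assert predict(model, np.array([[3.0], [-3.0]])).tolist() == [1.0, -1.0]

    def test_zero_input_gives_minus_bias(self, sep2d):
        model = fit_irwp(sep2d, FitOptions(p=2.0, box_c=np.inf, smo_tol=1e-8))
        val = decision_function(model, np.zeros(2))
        assert val == pytest.approx(-model.bias)
        assert predict(model, np.zeros((1, 2)))[0] == (1.0 if -model.bias >= 0 else -1.0)

    def test_support_vectors_sit_on_their_margin(self, sep2d):
        opts = FitOptions(p=2.0, box_c=np.inf, smo_tol=1e-8)
        model = fit_irwp(sep2d, opts)
        for k in model.support_indices:
            margin = sep2d.labels[k] * decision_function(model, sep2d.features[k])
            assert margin == pytest.approx(1.0, abs=1e-6)

    def test_training_points_classified_correctly(self, sep2d):
        model = fit_irwp(sep2d, FitOptions(p=1.0, box_c=np.inf, smo_tol=1e-8))
        np.testing.assert_array_equal(predict(model, sep2d.features), sep2d.labels)

    def test_dimension_mismatch_raises(self, sep2d):
        model = fit_irwp(sep2d, FitOptions(p=2.0))
        with pytest.raises(ValueError, match="features"):
            decision_function(model, np.zeros(5))
        with pytest.raises(ValueError, match="features"):
            predict(model, np.zeros((2, 5)))


class TestSelectedFeatures:
    def test_relative_threshold_rule(self, sep2d):
        model = fit_irwp(sep2d, FitOptions(p=2.0))
        model.weights = np.array([1.0, 1e-9, 0.5])
        opts = FitOptions(p=2.0, feature_threshold=1e-3)
        assert selected_features(model, opts) == frozenset({0, 2})

    def test_zero_threshold_keeps_all_nonzero(self, sep2d):
        model = fit_irwp(sep2d, FitOptions(p=2.0))
        assert selected_features(
            model, FitOptions(p=2.0, feature_threshold=0.0)
        ) == frozenset(range(2))

    def test_all_zero_weights_rejected(self, sep2d):
        model = fit_irwp(sep2d, FitOptions(p=2.0))
        model.weights = np.zeros(2)
        with pytest.raises(ValueError, match="zero"):
            selected_features(model, FitOptions(p=2.0))

    def test_weston_500_selection_is_relevant_dominated(self):
        # at p = 0.8 the selected set is drawn almost entirely from the 6
        # informative features; weak informative features (class-mean
        # 1.4) may fall below the dominance threshold
        opts = FitOptions(p=0.8)
        for seed in (10, 11, 12):
            pool = generate_weston(WestonSpec(n_samples=500, seed=seed))
            train, _, _ = standardize(pool)
            model = fit_irwp(train, opts)
            sel = selected_features(model, opts)
            relevant = frozenset(range(6))
            assert len(sel & relevant) >= 3
            assert len(sel - relevant) <= 1
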