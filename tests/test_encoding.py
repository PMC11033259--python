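"""Ridge TRF core: design matrices, the closed-form and brute-force ridge
oracles, lambda cross-validation, train/test protocols, the circular
shift null, and grand averaging."""

import numpy as np
import pytest

import loadtrf as lt
from loadtrf.encoding import (
    DesignMatrix,
    _fit_on_trials,
    build_design_matrix,
    default_lambda_grid,
    fit_ridge,
    predict,
)
from loadtrf.synth import default_topography


def _lag(fs, *samples):
    """LagSpec whose lag grid is exactly the given sample lags."""
    return lt.LagSpec(samples[0] * 1000.0 / fs, samples[-1] * 1000.0 / fs, fs)


class TestDesignMatrix:
    def test_zero_lag_is_identity(self):
        d = build_design_matrix(np.array([1.0, 2, 3]), _lag(250.0, 0), intercept=False)
        np.testing.assert_array_equal(d.X[:, 0], [1, 2, 3])

    def test_positive_lag_shifts_forward_with_zero_pad(self):
        d = build_design_matrix(np.array([1.0, 2, 3]), _lag(250.0, 0, 1), intercept=False)
        np.testing.assert_array_equal(d.X[:, 1], [0, 1, 2])

    def test_negative_lag_shifts_backward(self):
        d = build_design_matrix(np.array([1.0, 2, 3]), _lag(250.0, -1, 0), intercept=False)
        np.testing.assert_array_equal(d.X[:, 0], [2, 3, 0])

    def test_intercept_column_prepended(self, lag_spec):
        d = build_design_matrix(np.arange(10.0), lag_spec)
        assert d.X.shape[1] == lag_spec.n_lags + 1
        np.testing.assert_array_equal(d.X[:, 0], np.ones(10))

    def test_empty_stimulus_rejected(self, lag_spec):
        with pytest.raises(ValueError, match="empty"):
            build_design_matrix(np.array([]), lag_spec)


class TestFitRidge:
    def _single_column(self):
        return DesignMatrix(np.array([[1.0], [2.0]]), np.array([0.0]), 250.0,
                            has_intercept=False)

    def test_exact_fit_at_lambda_zero(self):
        m = fit_ridge(self._single_column(), np.array([1.0, 2.0]), 0.0)
        assert m.weights[0, 0] == pytest.approx(1.0)

    def test_closed_form_shrinkage(self):
        # w = S'R / (S'S + lambda) = 5 / (5 + 5)
        m = fit_ridge(self._single_column(), np.array([1.0, 2.0]), 5.0)
        assert m.weights[0, 0] == pytest.approx(0.5)

    def test_matches_independent_normal_equations_solver(self, rng):
        X = rng.normal(size=(200, 30))
        R = rng.normal(size=(200, 3))
        d = DesignMatrix(X, np.arange(29.0), 250.0, has_intercept=True)
        m = fit_ridge(d, R, 1.0)
        M = np.eye(30)
        M[0, 0] = 0.0
        w_oracle = np.linalg.solve(X.T @ X + 1.0 * M, X.T @ R)
        ours = np.vstack([m.bias, m.weights.T])
        assert np.max(np.abs(ours - w_oracle)) / np.max(np.abs(w_oracle)) < 1e-8

    def test_rank_deficient_at_lambda_zero_rejected(self):
        X = np.ones((4, 3))  # identical columns
        d = DesignMatrix(X, np.arange(3.0), 250.0, has_intercept=False)
        with pytest.raises(ValueError, match="lambda"):
            fit_ridge(d, np.ones(4), 0.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            fit_ridge(self._single_column(), np.array([1.0, 2.0]), -1.0)


class TestPredict:
    def test_impulse_trf_reproduces_stimulus(self):
        spec = _lag(250.0, 0, 3)
        w = np.zeros((1, 4))
        w[0, 0] = 1.0
        model = lt.TRFModel(w, np.zeros(1), 0.0, spec.lag_ms, 250.0)
        stim = np.arange(20.0)
        np.testing.assert_allclose(predict(stim, model)[0], stim)

    def test_zero_weights_predict_constant_bias(self):
        spec = _lag(250.0, 0, 3)
        model = lt.TRFModel(np.zeros((2, 4)), np.array([1.5, -2.0]), 0.0,
                            spec.lag_ms, 250.0)
        pred = predict(np.arange(10.0), model)
        np.testing.assert_allclose(pred[0], 1.5)
        np.testing.assert_allclose(pred[1], -2.0)

    def test_training_prediction_self_consistency(self, lag_spec, rng):
        stim = lt.Regressor(rng.normal(size=3000), 250.0)
        truth = lt.GroundTruthTRF(lt.PRESETS["P-envelope"], np.array([1.0, -0.7]),
                                  lag_spec)
        rec = lt.render_eeg(stim, truth, lt.NoiseSpec(snr_db=np.inf), seed=1)
        d = build_design_matrix(stim, lag_spec)
        model = fit_ridge(d, rec.samples.T, 1e-3)
        pred = predict(stim, model)
        for c in range(2):
            assert np.corrcoef(pred[c], rec.samples[c])[0, 1] >= 0.999

    def test_rate_mismatch_rejected(self, lag_spec):
        model = lt.TRFModel(np.zeros((1, lag_spec.n_lags)), np.zeros(1), 0.0,
                            lag_spec.lag_ms, 250.0)
        with pytest.raises(ValueError, match="fs"):
            predict(lt.Regressor(np.zeros(100), 500.0), model)


class TestLambdaGrid:
    def test_default_grid_is_21_half_decade_steps(self):
        grid = default_lambda_grid()
        assert len(grid) == 21
        np.testing.assert_allclose(np.log10(grid), np.arange(-5.0, 5.5, 0.5),
                                   atol=1e-12)


def _noiseless_trials(seed=3, duration=60.0, n_ch=2):
    """Noiseless forward render from a broadband (white) stimulus, so the
    design is well conditioned and the ridge path is purely about the
    penalty, not about stimulus collinearity."""
    lag_spec = lt.LagSpec()
    rng = np.random.default_rng(seed)
    stim = lt.Regressor(rng.standard_normal(int(duration * 250)), 250.0)
    truth = lt.GroundTruthTRF(lt.PRESETS["NP-envelope"],
                              default_topography(n_ch), lag_spec)
    rec = lt.render_eeg(stim, truth, lt.NoiseSpec(snr_db=np.inf), seed=seed)
    return lt.split_trials(stim, rec, 10), truth, lag_spec


class TestCrossvalLambda:
    def test_single_trial_rejected(self, lag_spec):
        trials, _, _ = _noiseless_trials()
        with pytest.raises(ValueError):
            lt.crossval_lambda(trials.subset([0]), lag_spec)

    def test_grid_of_one_returns_it(self, lag_spec):
        trials, _, _ = _noiseless_trials()
        cv = lt.crossval_lambda(trials.subset([0, 1, 2]), lag_spec,
                                grid=np.array([0.42]))
        assert cv.best_lambda == 0.42

    def test_noiseless_data_prefers_light_regularization_and_recovers(self):
        """On noiseless data the chosen penalty is small relative to the
        design's energy (the Gram diagonal) and the fit at that penalty
        recovers the generating kernel."""
        trials, truth, lag_spec = _noiseless_trials()
        cv = lt.crossval_lambda(trials, lag_spec)
        gram_scale = np.mean([
            np.mean(s**2) * len(s) for s in trials.stimuli[:-1]
        ]) * (trials.n_trials - 1)
        assert cv.best_lambda < 0.01 * gram_scale
        model = _fit_on_trials(trials, range(10), lag_spec, cv.best_lambda)
        k = truth.kernel()
        r = np.corrcoef(model.weights[0], k * truth.topography[0])[0, 1]
        assert r > 0.99


class TestTrainTestIndividual:
    def test_ten_trials_split_eight_two(self):
        trials, _, lag_spec = _noiseless_trials()
        model, res = lt.train_test_individual(trials, lag_spec)
        assert res.train_trials == list(range(8))
        assert res.test_trials == [8, 9]

    def test_test_trials_never_enter_cv_folds(self):
        trials, _, lag_spec = _noiseless_trials()
        _, res = lt.train_test_individual(trials, lag_spec)
        assert set(res.cv.fold_trials).isdisjoint(res.test_trials)
        assert sorted(res.cv.fold_trials) == res.train_trials

    def test_too_few_trials_rejected(self, lag_spec):
        trials, _, _ = _noiseless_trials()
        with pytest.raises(ValueError):
            lt.train_test_individual(trials.subset([0, 1, 2]), lag_spec)


class TestShiftedControl:
    def test_zero_shift_equals_unshifted_evaluation(self):
        trials, _, lag_spec = _noiseless_trials()
        _, res = lt.train_test_individual(trials, lag_spec)
        null = lt.shifted_control(trials, lag_spec, shift_s=0.0)
        np.testing.assert_allclose(null.per_trial, res.per_trial)

    def test_full_rotation_equals_zero_shift(self):
        trials, _, lag_spec = _noiseless_trials()
        trial_len_s = len(trials.stimuli[0]) / trials.fs
        a = lt.shifted_control(trials, lag_spec, shift_s=0.0)
        b = lt.shifted_control(trials, lag_spec, shift_s=trial_len_s)
        np.testing.assert_allclose(a.per_trial, b.per_trial)

    def test_trial_shorter_than_shift_rejected(self, lag_spec):
        trials, _, _ = _noiseless_trials(duration=10.0)
        with pytest.raises(ValueError, match="short"):
            lt.shifted_control(trials, lag_spec, shift_s=2.0)


class TestTrainTestGeneric:
    def test_identical_subjects_give_identical_generic_model(self):
        trials, _, lag_spec = _noiseless_trials()
        subjects = [trials, trials, trials]
        results = lt.train_test_generic(subjects, lag_spec)
        individual = _fit_on_trials(trials, range(10), lag_spec,
                                    results[0][0].lam)
        for gmodel, _ in results:
            np.testing.assert_allclose(gmodel.weights, individual.weights,
                                       atol=1e-6)

    def test_held_out_subject_not_in_training(self):
        trials, _, lag_spec = _noiseless_trials()
        subjects = [trials, trials, trials, trials]
        results = lt.train_test_generic(subjects, lag_spec)
        for held, (_, res) in enumerate(results):
            assert held not in res.train_trials
            assert sorted(res.train_trials + [held]) == list(range(4))

    def test_mismatched_channel_sets_rejected(self, lag_spec):
        a, _, _ = _noiseless_trials(n_ch=2)
        b, _, _ = _noiseless_trials(n_ch=3)
        with pytest.raises(ValueError, match="channel"):
            lt.train_test_generic([a, a, b], lag_spec)

    def test_pooled_mode_agrees_with_average_for_identical_subjects(self):
        trials, _, lag_spec = _noiseless_trials()
        avg = lt.train_test_generic([trials] * 3, lag_spec, method="average")
        pooled = lt.train_test_generic([trials] * 3, lag_spec, method="pooled")
        np.testing.assert_allclose(avg[0][0].weights, pooled[0][0].weights,
                                   atol=1e-6)


class TestGrandAverage:
    def _models(self, weights_list, lag_spec):
        return [
            lt.TRFModel(w, np.zeros(w.shape[0]), 1.0, lag_spec.lag_ms, 250.0,
                        channel_labels=["Fz"])
            for w in weights_list
        ]

    def test_identical_models_have_zero_sem(self, lag_spec):
        w = np.random.default_rng(0).normal(size=(1, lag_spec.n_lags))
        mean, sem, _ = lt.grand_average(self._models([w] * 5, lag_spec), "Fz")
        np.testing.assert_allclose(mean, w[0])
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)

    def test_opposite_models_average_to_zero(self, lag_spec):
        w = np.random.default_rng(1).normal(size=(1, lag_spec.n_lags))
        mean, _, _ = lt.grand_average(self._models([w, -w], lag_spec), "Fz")
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)

    def test_sem_matches_direct_formula(self, lag_spec, rng):
        ws = [rng.normal(size=(1, lag_spec.n_lags)) for _ in range(29)]
        _, sem, _ = lt.grand_average(self._models(ws, lag_spec), "Fz")
        stack = np.array([w[0] for w in ws])
        expected = stack.std(axis=0, ddof=1) / np.sqrt(29)
        np.testing.assert_allclose(sem, expected)

    def test_mixed_lag_axes_rejected(self, lag_spec):
        a = self._models([np.zeros((1, lag_spec.n_lags))], lag_spec)[0]
        other = lt.LagSpec(0.0, 400.0, 250.0)
        b = lt.TRFModel(np.zeros((1, other.n_lags)), np.zeros(1), 1.0,
                        other.lag_ms, 250.0, channel_labels=["Fz"])
        with pytest.raises(ValueError, match="lag"):
            lt.grand_average([a, b], "Fz")


class TestShrinkage:
    def test_weight_norm_non_increasing_and_limits(self):
        """Penalized weight norm shrinks monotonically over the grid, and
        at lambda = 1e5 the prediction is nearer intercept-only than at
        1e-5."""
        lag_spec = lt.LagSpec()
        env = lt.simulate_envelope(60.0, 250.0, seed=17)
        truth = lt.GroundTruthTRF(lt.PRESETS["NP-envelope"],
                                  default_topography(2), lag_spec)
        rec = lt.render_eeg(env, truth, lt.NoiseSpec(snr_db=0.0), seed=17)
        d = build_design_matrix(env, lag_spec)
        grid = default_lambda_grid()
        norms, preds = [], {}
        for lam in grid:
            m = fit_ridge(d, rec.samples.T, lam)
            norms.append(np.linalg.norm(m.weights))
            if lam in (grid[0], grid[-1]):
                preds[lam] = predict(env, m)
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
        resp_mean = rec.samples.mean(axis=1, keepdims=True)
        d_small = np.linalg.norm(preds[grid[0]] - resp_mean)
        d_large = np.linalg.norm(preds[grid[-1]] - resp_mean)
        assert d_large < d_small
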