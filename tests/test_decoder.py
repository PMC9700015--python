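"""Penalized logistic decoding: solver, CV machinery, task battery."""

import numpy as np
import pytest
from dataclasses import replace

from kinedecode import _cd, decoder, synth
from kinedecode.kinematics import zscore_within_responder


def _toy(n=8, p=2, seed=0, sep=1.5):
    rng = np.random.default_rng(seed)
    y = np.repeat([0.0, 1.0], n // 2)
    X = rng.normal(0, 1, (n, p))
    X[:, 0] += sep * (y - 0.5)
    return X, y


class TestPredictProb:
    def test_zero_model_gives_half(self):
        m = decoder.ElasticNetLRModel(np.zeros(3), 0.0, 1.0, 0.95)
        assert decoder.predict_prob(m, np.ones(3)) == 0.5

    def test_large_bias_saturates(self):
        m = decoder.ElasticNetLRModel(np.zeros(2), 50.0, 1.0, 0.95)
        assert decoder.predict_prob(m, np.zeros(2)) > 1 - 1e-9

    def test_log3_gives_three_quarters(self):
        beta = np.zeros(4)
        beta[0] = 1.0
        m = decoder.ElasticNetLRModel(beta, 0.0, 1.0, 0.95)
        K = np.zeros(4)
        K[0] = np.log(3.0)
        assert decoder.predict_prob(m, K) == pytest.approx(0.75)

    def test_dimension_mismatch(self):
        m = decoder.ElasticNetLRModel(np.zeros(3), 0.0, 1.0, 0.95)
        with pytest.raises(ValueError, match="dimension"):
            decoder.predict_prob(m, np.zeros(5))


class TestClassRebalanceWeights:
    def test_balanced_labels_give_unit_weights(self):
        w = decoder.class_rebalance_weights(np.repeat([0.0, 1.0], 5))
        np.testing.assert_allclose(w, 1.0)

    def test_eight_two_split(self):
        y = np.array([1.0] * 8 + [0.0] * 2)
        w = decoder.class_rebalance_weights(y)
        np.testing.assert_allclose(w[:8], 0.625)
        np.testing.assert_allclose(w[8:], 2.5)

    def test_class_masses_equalized(self, rng):
        for _ in range(5):
            y = (rng.random(30) < rng.uniform(0.2, 0.8)).astype(float)
            if y.min() == y.max():
                continue
            w = decoder.class_rebalance_weights(y)
            assert w[y == 0].sum() == pytest.approx(w[y == 1].sum())
            assert w.mean() == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            decoder.class_rebalance_weights(np.ones(6))


class TestBalancedAccuracy:
    def test_perfect(self):
        assert decoder.balanced_accuracy([1, 0, 1], [1, 0, 1]) == 1.0

    def test_mixed_example(self):
        y_true = [1, 1, 1, 1, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 0]
        assert decoder.balanced_accuracy(y_true, y_pred) == pytest.approx(0.625)

    def test_all_positive_predictor_is_chance(self, rng):
        y = (rng.random(20) < 0.7).astype(float)
        assert decoder.balanced_accuracy(y, np.ones(20)) == 0.5

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            decoder.balanced_accuracy([1, 1], [1, 0])


class TestFitPenalizedLR:
    def test_full_shrinkage_limit(self):
        X, y = _toy(n=12)
        m = decoder.fit_penalized_lr(X, y, lam=1e4)
        np.testing.assert_array_equal(m.beta, 0.0)
        # with rebalancing weights the weighted class masses are equal, so
        # the weighted log-odds intercept is 0
        assert abs(m.beta0) < 1e-6
        # with uniform weights the intercept is the raw log-odds
        y2 = np.array([1.0] * 9 + [0.0] * 3)
        X2 = np.zeros((12, 2))
        m2 = decoder.fit_penalized_lr(X2, y2, lam=1e4, weights=np.ones(12))
        assert m2.beta0 == pytest.approx(np.log(3.0), abs=1e-5)

    def test_objective_matches_brute_force_grid(self):
        """Coordinate-descent optimum vs exhaustive grid + local refine."""
        X, y = _toy(n=8, p=2, seed=1)
        lam, alpha = 0.1, 1.0
        w = decoder.class_rebalance_weights(y)
        m = decoder.fit_penalized_lr(X, y, lam, alpha)
        obj_fit = _cd.enet_objective(X, y, w, lam, alpha, m.beta, m.beta0)
        # exhaustive grid over (beta1, beta2, beta0)
        grid = np.linspace(-3, 3, 61)
        best = np.inf
        for b1 in grid:
            for b2 in grid:
                eta = X @ np.array([b1, b2])
                for b0 in grid:
                    e = eta + b0
                    nll = np.mean(w * (np.logaddexp(0, e) - y * e))
                    pen = lam * (abs(b1) + abs(b2))
                    best = min(best, nll + pen)
        assert obj_fit <= best + 1e-9
        assert abs(obj_fit - best) < 1e-3

    def test_objective_matches_sklearn_saga(self):
        """Independent solver route: same optimum as scikit-learn."""
        from sklearn.linear_model import LogisticRegression

        X, y = _toy(n=20, p=5, seed=2)
        lam, alpha = 0.05, 0.95
        w = decoder.class_rebalance_weights(y)
        mine = decoder.fit_penalized_lr(X, y, lam, alpha)
        clf = LogisticRegression(
            solver="saga", l1_ratio=alpha, C=1.0 / (len(y) * lam),
            max_iter=100000, tol=1e-10,
        )
        clf.fit(X, y, sample_weight=w)
        obj_mine = _cd.enet_objective(X, y, w, lam, alpha, mine.beta, mine.beta0)
        obj_sk = _cd.enet_objective(
            X, y, w, lam, alpha, clf.coef_[0].copy(), float(clf.intercept_[0])
        )
        assert obj_mine <= obj_sk + 1e-7
        np.testing.assert_allclose(mine.beta, clf.coef_[0], atol=1e-4)

    def test_lasso_at_least_as_sparse_as_ridge(self):
        X, y = _toy(n=16, p=6, seed=3)
        m_ridge = decoder.fit_penalized_lr(X, y, 0.1, alpha=0.0)
        m_lasso = decoder.fit_penalized_lr(X, y, 0.1, alpha=1.0)
        assert np.sum(m_lasso.beta == 0) >= np.sum(m_ridge.beta == 0)


class TestLotoCV:
    def test_one_prediction_per_trial(self):
        X, y = _toy(n=14, p=3)
        cv = decoder.loto_cv_decode(X, y, lambda_grid=(1.0, 0.1))
        assert cv.y_pred.shape == (14,)
        assert cv.fold_betas.shape == (14, 3)

    def test_separable_data_perfectly_decoded(self):
        X, y = _toy(n=16, p=4, seed=4, sep=20.0)
        cv = decoder.loto_cv_decode(X, y, lambda_grid=(1.0, 0.1, 0.01))
        assert cv.balanced_accuracy == 1.0

    def test_no_leakage_outer_fold_model_ignores_held_out_label(self):
        """Flipping trial t's label must not change fold t's model."""
        X, y = _toy(n=12, p=3, seed=5)
        cv1 = decoder.loto_cv_decode(X, y, lambda_grid=(1.0, 0.1))
        y_flip = y.copy()
        y_flip[4] = 1.0 - y_flip[4]
        cv2 = decoder.loto_cv_decode(X, y_flip, lambda_grid=(1.0, 0.1))
        np.testing.assert_array_equal(cv1.fold_betas[4], cv2.fold_betas[4])
        assert cv1.fold_beta0s[4] == cv2.fold_beta0s[4]
        assert cv1.fold_lambdas[4] == cv2.fold_lambdas[4]

    def test_accuracy_monotone_in_effect_size(self):
        """Averaged over seeds, accuracy grows with the planted effect."""
        mean_accs = []
        for scale in (0.0, 0.6, 1.4):
            accs = []
            for seed in range(3):
                prof = synth.make_profile(
                    "r", 50 + seed, effect_scale=scale,
                    accept_curve={o: 0.5 for o in range(1, 6)},
                )
                trials = synth.simulate_choices(
                    prof, synth.make_design(1, 60 + seed), 70 + seed
                )
                X = synth.simulate_features(prof, trials, 80 + seed)
                idx = [i for i, t in enumerate(trials) if not t.is_control]
                y = np.array([float(trials[i].choice) for i in idx])
                cv = decoder.loto_cv_decode(X[idx], y, lambda_grid=(1.0, 0.1))
                accs.append(cv.balanced_accuracy)
            mean_accs.append(np.mean(accs))
        assert mean_accs[0] < mean_accs[1] <= mean_accs[2] + 0.02
        assert mean_accs[2] > 0.8


class TestRunTask:
    def test_unfair_only_filter(self, small_cohort):
        trials, Xz, _ = small_cohort
        task = decoder.task_battery()["choice_unfair"]
        prepared, _ = decoder.prepare_task(trials, Xz, task, "right", min_per_class=1)
        for r, prep in prepared.items():
            mask = (
                (trials["responder"] == r)
                & (trials["side"] == "right")
                & (~trials["is_control"].astype(bool))
                & trials["offer"].isin((1, 2))
            )
            assert prep.y_train.size == mask.sum()

    def test_sides_never_share_trials(self, small_cohort):
        trials, Xz, _ = small_cohort
        task = decoder.task_battery()["choice"]
        left, _ = decoder.prepare_task(trials, Xz, task, "left")
        right, _ = decoder.prepare_task(trials, Xz, task, "right")
        for r in set(left) & set(right):
            nl, nr = left[r].y_train.size, right[r].y_train.size
            total = (
                (trials["responder"] == r)
                & (~trials["is_control"].astype(bool))
                & trials["offer"].isin((1, 2, 4, 5))
            ).sum()
            assert nl + nr == total

    def test_inclusion_rule_excludes_and_logs(self):
        prof = synth.make_profile(
            "r00", 0, accept_curve={o: 0.99 for o in range(1, 6)}
        )
        trials, X = synth.simulate_dataset([prof], 2, 0)
        Xz, _ = zscore_within_responder(X, trials["responder"].to_numpy())
        task = decoder.task_battery()["choice"]
        run = decoder.run_task(trials, Xz, task, "right", lambda_grid=(1.0,))
        assert run.results == {}
        assert any("fewer than 4" in reason for _, reason in run.excluded)

    def test_data_fraction_subsamples_stratified(self, small_cohort):
        trials, Xz, _ = small_cohort
        task = replace(decoder.task_battery()["choice"], data_fraction=0.5)
        full, _ = decoder.prepare_task(trials, Xz, decoder.task_battery()["choice"], "right")
        half, _ = decoder.prepare_task(trials, Xz, task, "right", min_per_class=1)
        for r in full:
            n_full, n_half = full[r].y_train.size, half[r].y_train.size
            assert abs(n_half - n_full / 2) <= 1
            for cls in (0.0, 1.0):
                frac_full = np.mean(full[r].y_train == cls)
                frac_half = np.mean(half[r].y_train == cls)
                assert abs(frac_full - frac_half) < 0.15

    def test_generalization_to_mid_offers_consistent_with_planted_model(self):
        """EUR 3 choices driven by the same planted effect are decodable."""
        prof = synth.make_profile(
            "r00", 11, effect_scale=1.2,
            accept_curve={1: 0.35, 2: 0.45, 3: 0.5, 4: 0.55, 5: 0.65},
        )
        trials, X = synth.simulate_dataset([prof], 2, 12)
        Xz, _ = zscore_within_responder(X, trials["responder"].to_numpy())
        battery = decoder.task_battery()
        gen = decoder.run_task(
            trials, Xz, battery["generalize_mid"], "right", lambda_grid=(1.0, 0.1)
        )
        within = decoder.run_task(
            trials, Xz, battery["choice"], "right", lambda_grid=(1.0, 0.1)
        )
        assert within.results["r00"].balanced_accuracy > 0.8
        assert gen.results["r00"].balanced_accuracy > 0.7

    def test_generalization_task_test_offers_are_mid_only(self, small_cohort):
        trials, Xz, _ = small_cohort
        task = decoder.task_battery()["generalize_mid"]
        prepared, _ = decoder.prepare_task(trials, Xz, task, "right", min_per_class=1)
        for r, prep in prepared.items():
            mask = (
                (trials["responder"] == r)
                & (trials["side"] == "right")
                & (~trials["is_control"].astype(bool))
                & (trials["offer"] == 3)
            )
            if prep.y_test is not None:
                assert prep.y_test.size == mask.sum()
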