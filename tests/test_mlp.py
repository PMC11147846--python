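import numpy as np
import pytest

from fcbench.baselines import avg_predictor
from fcbench.core import make_folds
from fcbench.evaluation import per_subject_correlation
from fcbench.mlp import (
    FoldModel,
    MLPConfig,
    _forward,
    _loss_grad_wrt_predictions,
    _train_single,
    loss,
    predict,
    predict_all,
    resampled_sc_edges,
    train,
)


class TestLoss:
    def test_perfect_prediction_zero_loss(self, rng):
        Y = rng.standard_normal((4, 20))
        cfg = MLPConfig(n_layers=2, gamma=0.0, lambda_reg=0.0)
        assert loss(Y, Y, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_gamma_zero_ignores_between_subject_similarity(self, rng):
        Y = rng.standard_normal((4, 20))
        cfg = MLPConfig(n_layers=2, gamma=0.0, lambda_reg=0.0)
        # two prediction sets with identical per-subject correlations to Y
        # but very different between-subject structure score the same
        P1 = Y + 0.5 * rng.standard_normal(Y.shape)
        shared = rng.standard_normal(20)
        P2 = P1 + 5.0 * shared  # strongly inter-correlated predictions
        r1 = [np.corrcoef(P1[i], Y[i])[0, 1] for i in range(4)]
        expect1 = 1 - np.mean(r1)
        assert loss(P1, Y, cfg) == pytest.approx(expect1, abs=1e-12)
        assert loss(P2, Y, cfg) != pytest.approx(loss(P1, Y, cfg), abs=1e-6)
        # with gamma=0 the between term is absent: direct-evaluation oracle
        r2 = [np.corrcoef(P2[i], Y[i])[0, 1] for i in range(4)]
        assert loss(P2, Y, cfg) == pytest.approx(1 - np.mean(r2), abs=1e-12)

    def test_identical_predictions_gamma_one_loss_one(self, rng):
        Y = rng.standard_normal((5, 30))
        P = np.tile(rng.standard_normal(30), (5, 1))
        cfg = MLPConfig(n_layers=2, gamma=1.0, lambda_reg=0.0)
        assert loss(P, Y, cfg) == pytest.approx(1.0, abs=1e-9)

    def test_single_subject_batch_with_gamma_rejected(self, rng):
        cfg = MLPConfig(n_layers=2, gamma=0.4)
        with pytest.raises(ValueError, match="batch of 1"):
            loss(rng.standard_normal((1, 10)), rng.standard_normal((1, 10)), cfg)

    def test_gradient_matches_finite_differences(self, rng):
        P = rng.standard_normal((4, 10))
        Y = rng.standard_normal((4, 10))
        cfg = MLPConfig(n_layers=2, gamma=0.4, lambda_reg=0.0)
        g = _loss_grad_wrt_predictions(P, Y, cfg)
        h = 1e-6
        for i, j in [(0, 0), (1, 5), (3, 9)]:
            Pp, Pm = P.copy(), P.copy()
            Pp[i, j] += h
            Pm[i, j] -= h
            num = (loss(Pp, Y, cfg) - loss(Pm, Y, cfg)) / (2 * h)
            assert g[i, j] == pytest.approx(num, abs=1e-7)


class TestTraining:
    def test_recovers_linear_map(self, rng):
        n, d = 50, 24
        X = rng.standard_normal((n, d))
        A = rng.standard_normal((d, d)) / np.sqrt(d)
        Y = X @ A
        cfg = MLPConfig(n_layers=3, width=48, gamma=0.0, lambda_reg=0.0,
                        epochs=600, learning_rate=3e-3, seed=0)
        w, b, hist = _train_single(X, Y, cfg, np.random.default_rng(0),
                                   _loss_grad_wrt_predictions)
        P = _forward(w, b, X)
        r = np.mean([np.corrcoef(P[i], Y[i])[0, 1] for i in range(n)])
        assert r > 0.95

    def test_loss_decreases_over_epochs(self, rng):
        n, d = 40, 20
        X = rng.standard_normal((n, d))
        Y = X @ (rng.standard_normal((d, d)) / np.sqrt(d))
        cfg = MLPConfig(n_layers=3, width=32, gamma=0.0, lambda_reg=0.0,
                        epochs=300, learning_rate=3e-3, seed=1)
        _, _, hist = _train_single(X, Y, cfg, np.random.default_rng(1),
                                   _loss_grad_wrt_predictions)
        q = len(hist) // 4
        assert hist[-q:].mean() < hist[:q].mean()

    def test_cv_training_and_leakage_guard(self, small_cohort):
        folds = make_folds(len(small_cohort), 3, seed=0)
        X = resampled_sc_edges(small_cohort, seed=0)
        cfg = MLPConfig(n_layers=3, width=32, epochs=30, seed=0)
        models = train(small_cohort, folds, cfg, sc_edges=X)
        assert len(models) == 3
        # inference is deterministic: identical inputs, identical outputs
        p1 = predict(models[0], X[:2])
        p2 = predict(models[0], X[:2])
        assert np.array_equal(p1, p2)
        # batch size may change BLAS kernel: equal to float tolerance
        assert np.allclose(p1[0], predict(models[0], X[0:1])[0], atol=1e-10)
        # predicting a training subject by id raises
        train_id = sorted(models[0].training_ids)[0]
        idx = small_cohort.subject_ids.index(train_id)
        with pytest.raises(ValueError, match="leakage"):
            predict(models[0], X[idx: idx + 1], subject_ids=[train_id])
        out = predict_all(models, small_cohort, folds, sc_edges=X)
        assert out.edge_predictions.shape == X.shape

    def test_dimension_mismatch_rejected(self, small_cohort):
        folds = make_folds(len(small_cohort), 3, seed=0)
        X = resampled_sc_edges(small_cohort, seed=0)
        cfg = MLPConfig(n_layers=2, width=16, epochs=5, seed=0)
        models = train(small_cohort, folds, cfg, sc_edges=X)
        with pytest.raises(ValueError, match="dimension"):
            predict(models[0], X[:2, :-3])

    def test_decoupled_sc_does_not_beat_group_average(self, small_cohort, rng):
        # shuffling SC across subjects severs any SC-FC link; the trained
        # model's validation performance must not exceed the group-average
        # baseline
        folds = make_folds(len(small_cohort), 3, seed=1)
        X = resampled_sc_edges(small_cohort, seed=0)
        X = X[rng.permutation(X.shape[0])]
        cfg = MLPConfig(n_layers=3, width=32, epochs=60, seed=2)
        models = train(small_cohort, folds, cfg, sc_edges=X)
        out = predict_all(models, small_cohort, folds, sc_edges=X)
        r_mlp = np.nanmean(per_subject_correlation(out, small_cohort))
        r_avg = np.nanmean(
            per_subject_correlation(avg_predictor(small_cohort, folds), small_cohort)
        )
        assert r_mlp <= r_avg + 0.01

    def test_missing_sc_rejected(self, small_cohort):
        from fcbench.core import Cohort, Subject

        bare = Cohort(
            atlas=small_cohort.atlas,
            subjects=[Subject(s.subject_id, efc=s.efc) for s in small_cohort],
        )
        folds = make_folds(len(bare), 3, seed=0)
        with pytest.raises(ValueError, match="no SC"):
            train(bare, folds, MLPConfig(n_layers=2, width=8, epochs=1))


class TestConfig:
    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            MLPConfig(gamma=1.5)

    def test_desk_scale_preset(self):
        cfg = MLPConfig.desk_scale(seed=3)
        assert cfg.width == 256 and cfg.epochs == 2000 and cfg.seed == 3
        # published-scale values remain the dataclass defaults
        full = MLPConfig()
        assert full.n_layers == 10 and full.width == 1024
        assert full.gamma == 0.4 and full.lambda_reg == 0.01 and full.epochs == 20000
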