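"""DBN regression: CD correctness, back-prop, training behaviour, ensembles."""

import numpy as np
import pytest

from oscillobp.cohort import MeasurementRecord, generate_cohort, CohortConfig, split_cohort
from oscillobp.dbn import (
    DBNModel,
    RBMLayer,
    Standardizer,
    TrainConfig,
    cd_gradient,
    cd_update,
    ensemble_predict,
    ensemble_train_predict,
    fine_tune,
    mlp_loss_grads,
    predict,
    pretrain,
    standardize,
)
from oscillobp.errors import ShapeError, ValidationError


def identity_stats(n):
    return Standardizer(np.zeros(n), np.ones(n), [f"f{i}" for i in range(n)])


def linear_records(rng, n, A, start=0, scale=4.0):
    recs = []
    for i in range(n):
        f = rng.standard_normal(11) * scale
        y = A @ f + np.array([112.0, 66.5])
        recs.append(
            MeasurementRecord(f"S{start + i:05d}", 1, f, float(y[0]), float(y[1]))
        )
    return recs


def exact_rbm_gradient(layer, data):
    """Exact log-likelihood gradient by enumeration of all RBM states."""
    nv, nh = layer.W.shape
    states_v = np.array(
        [[int(b) for b in np.binary_repr(i, nv)] for i in range(2**nv)], float
    )
    states_h = np.array(
        [[int(b) for b in np.binary_repr(i, nh)] for i in range(2**nh)], float
    )
    logp = np.array(
        [
            [
                v @ layer.W @ h + layer.c_visible @ v + layer.b_hidden @ h
                for h in states_h
            ]
            for v in states_v
        ]
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    Evh = np.zeros((nv, nh))
    Ev = np.zeros(nv)
    Eh = np.zeros(nh)
    for i, v in enumerate(states_v):
        for j, h in enumerate(states_h):
            Evh += p[i, j] * np.outer(v, h)
            Ev += p[i, j] * v
            Eh += p[i, j] * h
    hp = layer.hidden_probs(data)
    return (
        data.T @ hp / len(data) - Evh,
        data.mean(axis=0) - Ev,
        hp.mean(axis=0) - Eh,
    )


class TestCD:
    def test_zero_parameters_half_activation(self):
        layer = RBMLayer(np.zeros((3, 4)), np.zeros(4), np.zeros(3))
        probs = layer.hidden_probs(np.ones((2, 3)))
        np.testing.assert_array_equal(probs, np.full((2, 4), 0.5))

    def test_shape_mismatch(self):
        layer = RBMLayer(np.zeros((3, 4)), np.zeros(4), np.zeros(3))
        with pytest.raises(ShapeError):
            cd_gradient(layer, np.ones((2, 5)), np.random.default_rng(0))

    def test_cd1_positively_correlated_with_exact(self):
        """Even at k=1 the CD direction has positive overlap with the
        exact gradient for random enumerable models."""
        cosines = []
        for m in range(10):
            rng = np.random.default_rng(m)
            layer = RBMLayer(
                rng.normal(0, 1, (2, 2)), rng.normal(0, 1, 2), rng.normal(0, 1, 2)
            )
            data = (rng.random((4000, 2)) < 0.5).astype(float)
            gW, gc, gb = exact_rbm_gradient(layer, data)
            cW, cc, cb = cd_gradient(layer, data, rng, k=1)
            g = np.concatenate([gW.ravel(), gc, gb])
            c = np.concatenate([cW.ravel(), cc, cb])
            cosines.append(g @ c / (np.linalg.norm(g) * np.linalg.norm(c)))
        assert np.mean(cosines) > 0.5

    def test_reconstruction_error_decreases(self):
        """Bernoulli RBM reconstruction MSE drops from epoch 1 to epoch 50."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            proto = (rng.random((4, 6)) < 0.5).astype(float)
            data = proto[rng.integers(0, 4, 200)]
            data = np.abs(data - (rng.random(data.shape) < 0.05))
            layer = RBMLayer(
                rng.uniform(-0.1, 0.1, (6, 8)), np.zeros(8), np.zeros(6)
            )
            velocity = None
            errs = []
            for epoch in range(50):
                for start in range(0, 200, 10):
                    batch = data[start : start + 10]
                    layer, velocity = cd_update(
                        layer, batch, (0.05, 0.05, 0.05), 0.5, velocity, rng
                    )
                recon = layer.visible_mean(
                    (rng.random((200, 8)) < layer.hidden_probs(data)).astype(float)
                )
                errs.append(np.mean((data - recon) ** 2))
            wins += errs[-1] < errs[0]
        assert wins >= 19


class TestStandardize:
    def test_round_trip_identity(self, small_cohort):
        Z, T, fstats, tstats = standardize(small_cohort)
        X = np.array([r.features for r in small_cohort])
        np.testing.assert_allclose(fstats.inverse(Z), X, atol=1e-10)

    def test_train_columns_standardized(self, small_cohort):
        Z, T, _, _ = standardize(small_cohort)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-10)
        np.testing.assert_allclose(T.mean(axis=0), 0, atol=1e-10)

    def test_constant_target_column_named(self):
        recs = [
            MeasurementRecord("a", i, np.arange(11.0) + i, 110.0, 60.0 + i)
            for i in range(4)
        ]
        with pytest.raises(ValidationError, match="ref_sbp"):
            standardize(recs)


class TestForward:
    def test_hand_set_single_unit(self):
        layer = RBMLayer(np.array([[1.0]]), np.array([0.0]), np.array([0.0]))
        model = DBNModel(
            layers=[layer],
            output_W=np.array([[2.0, 2.0]]),
            output_b=np.array([1.0, 1.0]),
            feature_stats=identity_stats(1),
            target_stats=identity_stats(2),
        )
        out = predict(model, np.array([0.0]))
        np.testing.assert_allclose(out, [2.0, 2.0])  # 2*sigm(0)+1

    def test_zero_net_predicts_target_means(self):
        layer = RBMLayer(np.zeros((11, 4)), np.zeros(4), np.zeros(11))
        tstats = Standardizer(
            np.array([120.0, 70.0]), np.array([10.0, 5.0]), ["s", "d"]
        )
        model = DBNModel(
            layers=[layer],
            output_W=np.zeros((4, 2)),
            output_b=np.zeros(2),
            feature_stats=identity_stats(11),
            target_stats=tstats,
        )
        out = predict(model, np.random.default_rng(0).standard_normal((3, 11)))
        np.testing.assert_allclose(out, np.tile([120.0, 70.0], (3, 1)))

    def test_standardization_equivariance(self):
        rng = np.random.default_rng(1)
        layer = RBMLayer(
            rng.normal(0, 1, (11, 5)), rng.normal(0, 1, 5), np.zeros(11)
        )
        model = DBNModel(
            layers=[layer],
            output_W=rng.normal(0, 1, (5, 2)),
            output_b=np.zeros(2),
            feature_stats=identity_stats(11),
            target_stats=identity_stats(2),
        )
        x = rng.standard_normal(11)
        base = predict(model, x)
        shifted = x.copy()
        shifted[3] += 10.0
        model.feature_stats.mean = model.feature_stats.mean.copy()
        model.feature_stats.mean[3] += 10.0
        np.testing.assert_allclose(predict(model, shifted), base, atol=1e-12)

    def test_width_mismatch(self):
        layer = RBMLayer(np.zeros((11, 4)), np.zeros(4), np.zeros(11))
        model = DBNModel(
            layers=[layer],
            output_W=np.zeros((4, 2)),
            output_b=np.zeros(2),
            feature_stats=identity_stats(11),
            target_stats=identity_stats(2),
        )
        with pytest.raises(ShapeError):
            predict(model, np.zeros(7))


class TestPretrain:
    def test_zero_epochs_is_initialization(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 11))
        cfg0 = TrainConfig(epochs_pretrain=0, seed=4)
        a = pretrain(X, cfg0)
        b = pretrain(X, cfg0)
        trained = pretrain(X, TrainConfig(epochs_pretrain=5, seed=4))
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.W, lb.W)
        assert not np.array_equal(a.layers[0].W, trained.layers[0].W)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 11))
        cfg = TrainConfig(epochs_pretrain=3, seed=8)
        a = pretrain(X, cfg)
        b = pretrain(X, cfg)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.W, lb.W)
            np.testing.assert_array_equal(la.b_hidden, lb.b_hidden)

    def test_default_architecture(self):
        X = np.random.default_rng(0).standard_normal((20, 11))
        model = pretrain(X, TrainConfig(epochs_pretrain=0))
        widths = [l.n_visible for l in model.layers] + [model.layers[-1].n_hidden]
        assert widths == [11, 32, 32, 32]
        assert model.layers[0].visible_kind == "gaussian"
        assert all(l.visible_kind == "bernoulli" for l in model.layers[1:])
        assert model.output_W.shape == (32, 2)


class TestFineTune:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 11))
        Y = X[:, :2] * 0.5 + rng.standard_normal((40, 2)) * 0.05
        model = pretrain(X, TrainConfig(epochs_pretrain=0, seed=seed))
        return model, X, Y

    def test_zero_lr_is_noop(self):
        model, X, Y = self._toy()
        W0 = model.layers[0].W.copy()
        out0 = model.forward_standardized(X)
        cfg = TrainConfig(lr_weights=0.0, epochs_finetune=5)
        fine_tune(model, X, Y, cfg)
        np.testing.assert_array_equal(model.layers[0].W, W0)
        np.testing.assert_array_equal(model.forward_standardized(X), out0)

    def test_training_reduces_mse(self):
        wins = 0
        for seed in range(10):
            model, X, Y = self._toy(seed)
            loss0, *_ = mlp_loss_grads(model, X, Y)
            fine_tune(model, X, Y, TrainConfig(epochs_finetune=50, seed=seed))
            loss1, *_ = mlp_loss_grads(model, X, Y)
            wins += loss1 < loss0
        assert wins == 10

    def test_backprop_matches_finite_differences(self):
        """Central finite differences on a 3-unit toy net, 1e-5 relative."""
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((6, 2))
        T = rng.standard_normal((6, 2))
        model = pretrain(Z, TrainConfig(hidden_sizes=(3,), epochs_pretrain=0, seed=1))
        model.output_W = rng.normal(0, 0.5, (3, 2))
        model.output_b = rng.normal(0, 0.1, 2)
        _, grads, dW_out, db_out = mlp_loss_grads(model, Z, T)
        eps = 1e-6

        def loss_with(param, i, j, delta):
            param[i, j] += delta
            l, *_ = mlp_loss_grads(model, Z, T)
            param[i, j] -= delta
            return l

        for (analytic, param) in [
            (grads[0][0], model.layers[0].W),
            (dW_out, model.output_W),
        ]:
            for i in range(param.shape[0]):
                for j in range(param.shape[1]):
                    num = (
                        loss_with(param, i, j, eps) - loss_with(param, i, j, -eps)
                    ) / (2 * eps)
                    assert analytic[i, j] == pytest.approx(
                        num, rel=1e-5, abs=1e-8
                    )


class TestEnsemble:
    def test_duplicate_members_equal_single(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 11))
        model = pretrain(
            rng.standard_normal((20, 11)), TrainConfig(epochs_pretrain=0, seed=3)
        )
        model.output_W = rng.normal(0, 1, (32, 2))
        single = predict(model, X)
        np.testing.assert_allclose(ensemble_predict([model, model], X), single)

    def test_variance_reduction(self, small_cohort, tiny_train_config):
        train, test = split_cohort(small_cohort, 8)
        models, preds = ensemble_train_predict(
            train, test, tiny_train_config, augment_N=20
        )
        X_test = np.array([r.features for r in test])
        member_vars = [predict(m, X_test)[:, 0].var() for m in models]
        ens_var = preds["sbp_est"].to_numpy().var()
        assert ens_var <= max(member_vars) + 1e-9

    def test_aami_scale_errors_on_synthetic_cohort(self):
        """A modest ensemble reaches AAMI-scale errors on synthetic data
        whose attainable noise floor is a few mmHg."""
        from oscillobp.evaluation import error_summary

        records = generate_cohort(CohortConfig(n_subjects=14, seed=3))
        train, test = split_cohort(records, 10)
        cfg = TrainConfig(
            epochs_pretrain=20, epochs_finetune=100, ensemble_size=3, seed=5
        )
        _, preds = ensemble_train_predict(train, test, cfg, augment_N=30)
        s = error_summary(preds["sbp_est"], preds["ref_sbp"])
        assert abs(s.me) < 5.0
        assert s.sde < 8.0

    def test_noiseless_linear_map_recovery(self):
        """With noiseless linear targets the ensemble recovers the map to
        sub-mmHg test RMSE at the default epoch budget."""
        rng = np.random.default_rng(42)
        A = np.vstack([rng.normal(0, 0.3, 11), rng.normal(0, 0.22, 11)])
        train = linear_records(rng, 2000, A)
        test = linear_records(rng, 200, A, start=5000)
        cfg = TrainConfig(ensemble_size=2, seed=9)
        _, preds = ensemble_train_predict(train, test, cfg)
        rmse_s = np.sqrt(np.mean((preds.sbp_est - preds.ref_sbp) ** 2))
        rmse_d = np.sqrt(np.mean((preds.dbp_est - preds.ref_dbp) ** 2))
        assert rmse_s < 1.0
        assert rmse_d < 1.0
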