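import numpy as np
import pytest

from latentconn.autoencoder import (
    EncoderSpec,
    TrainedModel,
    _init_params,
    evaluate_reconstruction,
    make_splits,
    mse_loss,
    train,
    train_group_models,
)
from latentconn.data import EdgeScaler, EdgeTable


def _tiny_model(input_dim=6, hidden=(4,), bottleneck=2, seed=0):
    spec = EncoderSpec(
        hidden_sizes=list(hidden), bottleneck=bottleneck, input_dropout=0.0,
        learning_rate=0.1, max_epochs=1,
    )
    params = _init_params(spec.layer_sizes(input_dim), np.random.default_rng(seed))
    return TrainedModel(
        spec=spec, params=params, input_dim=input_dim,
        loss_trace=np.zeros((1, 2)), selected_epoch=0,
    )


class TestMakeSplits:
    def test_paper_counts_partition(self):
        plans = make_splits(80, counts=(45, 20, 15), n_repeats=3, seed=0)
        assert len(plans) == 3
        for plan in plans:
            plan.validate(80)
            assert len(plan.train) == 45
            assert len(plan.validation) == 20
            assert len(plan.test) == 15

    def test_same_seed_identical_plans(self):
        a = make_splits(61, counts=(33, 16, 12), n_repeats=5, seed=9)
        b = make_splits(61, counts=(33, 16, 12), n_repeats=5, seed=9)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.train, pb.train)
            assert np.array_equal(pa.test, pb.test)

    def test_oversized_counts_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            make_splits(80, counts=(70, 20, 15), n_repeats=1, seed=0)

    def test_fraction_defaults_are_exhaustive(self):
        (plan,) = make_splits(61, n_repeats=1, seed=0)
        plan.validate(61)


class TestEncodeDecode:
    def test_bottleneck_dimension(self):
        model = _tiny_model(input_dim=10, bottleneck=3)
        z = model.encode(np.zeros((4, 10)))
        assert z.shape == (4, 3)

    def test_zero_weights_give_zero_output(self):
        model = _tiny_model()
        model.params = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.params]
        y = model.reconstruct(np.random.default_rng(0).normal(size=6))
        assert np.array_equal(y, np.zeros((1, 6)))

    def test_outputs_inside_tanh_range(self):
        model = _tiny_model()
        x = np.random.default_rng(1).normal(size=(8, 6)) * 100
        assert np.abs(model.reconstruct(x)).max() < 1
        assert np.abs(model.encode(x)).max() < 1

    def test_dimension_mismatch_rejected(self):
        model = _tiny_model(input_dim=6)
        with pytest.raises(ValueError, match="dimension"):
            model.encode(np.zeros((2, 7)))


class TestLoss:
    def test_identical_vectors_zero(self):
        x = np.arange(5.0)
        assert mse_loss(x, x) == 0.0

    def test_worked_example(self):
        # sum of squared differences over n: ((1-0)^2 + 0) / 2
        assert mse_loss(np.array([1.0, 0.0]), np.array([0.0, 0.0])) == 0.5

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=7), rng.normal(size=7)
        assert mse_loss(x, y) == mse_loss(y, x)


@pytest.fixture(scope="module")
def rank3_run():
    rng = np.random.default_rng(3)
    d = 45  # 10-parcel hemisphere
    X = 3.0 + rng.standard_normal((120, 3)) @ (
        rng.standard_normal((3, d)) * 0.5 / np.sqrt(3)
    )
    scaler = EdgeScaler().fit(X[:90])
    spec = EncoderSpec(
        hidden_sizes=[32], bottleneck=4, input_dropout=0.0,
        learning_rate=0.2, max_epochs=800,
    )
    return train(
        scaler.transform(X[:90]), scaler.transform(X[90:]), spec, seed=4,
        scaler=scaler,
    )


class TestTrain:

    def test_validation_loss_drops_below_10pct_of_initial(self, rank3_run):
        trace = rank3_run.loss_trace
        assert trace[-1, 1] < 0.1 * trace[0, 1]

    def test_selected_epoch_minimizes_validation_loss(self, rank3_run):
        trace = rank3_run.loss_trace
        assert rank3_run.selected_epoch == int(np.argmin(trace[:, 1]))
        assert trace[rank3_run.selected_epoch, 0] <= trace[0, 0]

    def test_fixed_seed_identical_trace(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 10))
        spec = EncoderSpec(
            hidden_sizes=[8], bottleneck=2, input_dropout=0.3,
            learning_rate=0.05, max_epochs=20,
        )
        m1 = train(X[:30], X[30:], spec, seed=11)
        m2 = train(X[:30], X[30:], spec, seed=11)
        assert np.array_equal(m1.loss_trace, m2.loss_trace)

    def test_nonfinite_loss_aborts_with_diagnostic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 8))
        X[3, 2] = np.nan  # propagates to a non-finite loss
        spec = EncoderSpec(
            hidden_sizes=[8], bottleneck=2, input_dropout=0.0,
            learning_rate=0.1, max_epochs=50,
        )
        with pytest.raises(FloatingPointError, match="epoch"):
            train(X[:15], X[15:], spec, seed=0)


class TestEvaluateReconstruction:
    def test_perfect_reconstruction_r_one(self, small_trained_model):
        model, plan, X = small_trained_model
        x = model.scaler.transform(X[plan.test])
        rs = np.array([np.corrcoef(xi, xi)[0, 1] for xi in x])
        assert np.allclose(rs, 1.0)

    def test_trained_model_reconstructs_test_set(self, small_trained_model):
        model, plan, X = small_trained_model
        rs, (mean_r, sd_r) = evaluate_reconstruction(
            model, model.scaler.transform(X[plan.test])
        )
        assert mean_r > 0.8

    def test_zero_variance_input_reported_missing(self, small_trained_model):
        model, _, _ = small_trained_model
        x = np.zeros((1, model.input_dim))
        with pytest.warns(UserWarning, match="zero-variance"):
            rs, _ = evaluate_reconstruction(model, x)
        assert np.isnan(rs[0])


@pytest.fixture(scope="module")
def group_setup():
    rng = np.random.default_rng(7)
    n, d = 40, 21
    values = rng.normal(size=(n, d))
    edge_index = np.array([(i, j) for i in range(7) for j in range(i + 1, 7)])
    tables = {
        "L": EdgeTable(values, [f"s{i}" for i in range(n)], edge_index, "L"),
        "R": EdgeTable(values + 0.1, [f"s{i}" for i in range(n)], edge_index, "R"),
    }
    labels = np.array(["autism"] * 22 + ["control"] * 18)
    return tables, labels


class TestTrainGroupModels:

    def test_two_groups_two_hemispheres_one_repeat(self, group_setup):
        tables, labels = group_setup
        spec = EncoderSpec(
            hidden_sizes=[8], bottleneck=2, input_dropout=0.0,
            learning_rate=0.05, max_epochs=5,
        )
        ms = train_group_models(tables, labels, spec, n_repeats=1, seed=0)
        assert len(ms.models) == 4
        assert all(len(v) == 1 for v in ms.models.values())

    def test_per_group_split_counts(self, group_setup):
        tables, labels = group_setup
        spec = EncoderSpec(
            hidden_sizes=[8], bottleneck=2, input_dropout=0.0,
            learning_rate=0.05, max_epochs=2,
        )
        counts = {"autism": (12, 6, 4), "control": (10, 4, 4)}
        ms = train_group_models(tables, labels, spec, counts=counts, n_repeats=2, seed=0)
        assert len(ms.splits["autism"][0].train) == 12
        assert len(ms.splits["control"][1].test) == 4

    def test_single_group_rejected(self):
        values = np.zeros((4, 3))
        table = EdgeTable(values, list("abcd"), np.array([(0, 1), (0, 2), (1, 2)]), "L")
        with pytest.raises(ValueError, match="two groups"):
            train_group_models(
                {"L": table}, np.array(["x"] * 4), EncoderSpec(), n_repeats=1
            )
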