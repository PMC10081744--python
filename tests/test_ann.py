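"""Backprop MLP engine: gradients, stopping rules, prediction, greedy search."""

import numpy as np
import pytest

from mfisplit.ann import (
    Architecture,
    SearchConfig,
    TrainConfig,
    TrainedModel,
    _gradients,
    _forward,
    _sweep,
    compute_rmse,
    desk_config,
    load_model,
    predict,
    predict_proba,
    save_model,
    search_architecture,
    train_mlp,
)


def separable_toy(n=200, seed=0):
    """Two well-separated Gaussian blobs: a zero-training-error problem."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(-2.0, 0.4, size=(n // 2, 2))
    X1 = rng.normal(+2.0, 0.4, size=(n // 2, 2))
    X = np.vstack([X0, X1])
    Y = np.zeros((n, 2))
    Y[: n // 2, 0] = 1
    Y[n // 2:, 1] = 1
    return X, Y


class TestArchitecture:
    def test_zero_hidden_layers_rejected(self):
        with pytest.raises(ValueError):
            Architecture(4, (), 2)

    def test_four_hidden_layers_rejected(self):
        with pytest.raises(ValueError):
            Architecture(4, (3, 3, 3, 3), 2)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            Architecture(4, (0,), 2)


class TestComputeRmse:
    def test_identical_is_zero(self):
        a = np.ones((3, 2))
        assert compute_rmse(a, a) == 0.0

    def test_single_cell(self):
        assert compute_rmse([[0.5]], [[1.0]]) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [2, 4, 9])
    def test_all_zero_outputs_against_one_hot(self, k):
        # closed form sqrt(1/k) regardless of row count
        Y = np.eye(k)[np.arange(10) % k]
        assert compute_rmse(np.zeros_like(Y), Y) == pytest.approx(np.sqrt(1 / k))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_rmse(np.empty((0, 2)), np.empty((0, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_rmse(np.zeros((2, 2)), np.zeros((2, 3)))


class TestGradients:
    def test_match_central_finite_differences(self, rng):
        """Analytic backprop equals numeric gradients to 1e-5 relative error."""
        X = rng.normal(size=(7, 3))
        Y = (rng.random((7, 2)) > 0.5).astype(float)
        arch = Architecture(3, (4, 3), 2)
        weights, biases = [], []
        dims = [3, 4, 3, 2]
        for a, b in zip(dims, dims[1:]):
            weights.append(rng.uniform(-0.5, 0.5, size=(a, b)))
            biases.append(rng.uniform(-0.5, 0.5, size=b))

        def loss():
            out = _forward(X, weights, biases)[-1]
            return 0.5 * np.sum((out - Y) ** 2) / X.shape[0]

        gW, gb = _gradients(X, Y, weights, biases)
        eps = 1e-6
        for params, grads in ((weights, gW), (biases, gb)):
            for P, G in zip(params, grads):
                it = np.nditer(P, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = P[idx]
                    P[idx] = orig + eps
                    up = loss()
                    P[idx] = orig - eps
                    down = loss()
                    P[idx] = orig
                    num = (up - down) / (2 * eps)
                    assert abs(G[idx] - num) <= 1e-5 * max(1.0, abs(num))


class TestTraining:
    def test_separable_toy_converges(self):
        X, Y = separable_toy()
        cfg = desk_config(seed=1)
        model = train_mlp(X, Y, Architecture(2, (4,), 2), cfg)
        final_rmse = model.log[-1][1]
        assert final_rmse < 0.05
        assert model.stop_reason == "rmse_target"
        preds = predict(model, X)
        assert np.mean(preds == np.argmax(Y, axis=1)) == 1.0

    def test_rmse_non_increasing_at_checkpoints(self):
        X, Y = separable_toy()
        model = train_mlp(X, Y, Architecture(2, (4,), 2), desk_config(seed=2))
        rmses = [r for _, r in model.log]
        assert all(b <= a + 1e-6 for a, b in zip(rmses, rmses[1:]))

    def test_deterministic_given_seed(self):
        X, Y = separable_toy()
        cfg = desk_config(seed=7, max_epochs=2_000)
        m1 = train_mlp(X, Y, Architecture(2, (3,), 2), cfg)
        m2 = train_mlp(X, Y, Architecture(2, (3,), 2), cfg)
        for W1, W2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(W1, W2)
        assert m1.log == m2.log

    def test_dimension_mismatch_rejected(self):
        X, Y = separable_toy()
        with pytest.raises(ValueError, match="dims"):
            train_mlp(X, Y, Architecture(3, (4,), 2), desk_config())

    def test_plateau_stop_on_noise(self, rng):
        # pure-noise labels: RMSE stalls, plateau rule fires before max_epochs
        X = rng.normal(size=(50, 3))
        Y = np.eye(2)[rng.integers(0, 2, 50)]
        cfg = desk_config(seed=3, max_epochs=50_000)
        model = train_mlp(X, Y, Architecture(3, (2,), 2), cfg)
        assert model.stop_reason in ("plateau", "rmse_target")
        assert model.log[-1][0] < 50_000


class TestPredict:
    def test_outputs_in_unit_interval(self):
        X, Y = separable_toy()
        model = train_mlp(X, Y, Architecture(2, (3,), 2), desk_config(seed=4, max_epochs=2000))
        out = predict_proba(model, X)
        assert np.all(out > 0) and np.all(out < 1)

    def test_exact_tie_goes_to_first_class(self):
        # zeroed weights make every output 0.5: ties resolve to class index 0
        arch = Architecture(2, (2,), 3)
        model = TrainedModel(
            architecture=arch,
            weights=[np.zeros((2, 2)), np.zeros((2, 3))],
            biases=[np.zeros(2), np.zeros(3)],
            log=[], seed=0,
        )
        preds = predict(model, np.array([[0.3, 0.9]]), classes=("home", "rehab", "death"))
        assert preds[0] == "home"

    def test_column_mismatch_rejected(self):
        X, Y = separable_toy()
        model = train_mlp(X, Y, Architecture(2, (3,), 2), desk_config(seed=5, max_epochs=2000))
        with pytest.raises(ValueError, match="columns"):
            predict(model, np.zeros((4, 3)))


class TestSweep:
    def test_unimodal_profile_matches_exhaustive_argmax(self):
        profile = {2: 0.30, 3: 0.35, 4: 0.42, 5: 0.40, 6: 0.33, 7: 0.31, 8: 0.30}
        best, score, trace = _sweep(profile.get, sorted(profile))
        assert best == max(profile, key=profile.get)
        assert score == max(profile.values())

    def test_stops_after_two_consecutive_degradations(self):
        profile = {2: 0.5, 3: 0.4, 4: 0.3, 5: 0.9}
        best, _, trace = _sweep(profile.get, sorted(profile))
        assert best == 2
        assert [s for s, _ in trace] == [2, 3, 4]  # size 5 never evaluated

    def test_tie_does_not_count_as_degradation(self):
        profile = {2: 0.5, 3: 0.4, 4: 0.5, 5: 0.6, 6: 0.1, 7: 0.1}
        best, _, trace = _sweep(profile.get, sorted(profile))
        assert best == 5

    def test_none_candidates_skipped(self):
        profile = {2: None, 3: 0.4, 4: None, 5: 0.5}
        best, _, _ = _sweep(profile.get, sorted(profile))
        assert best == 5


class TestSearchArchitecture:
    def test_search_returns_trained_optimum_on_toy(self):
        X, Y = separable_toy(n=120, seed=3)
        cfg = desk_config(seed=6, min_epochs=500, max_epochs=1_000, epoch_step=250,
                          plateau_window=250)
        search = SearchConfig(max_depth=1, increment=2)
        arch, model, acc = search_architecture(X, Y, X, Y, cfg, search)
        assert acc == 1.0
        assert 1 <= len(arch.hidden_layers) <= 3
        lo, hi = np.ceil(2 / 3), 4 * 2
        assert lo <= arch.hidden_layers[0] <= hi

    def test_sweep_range_follows_preceding_layer(self):
        s = SearchConfig(increment=1)
        assert s.sweep_sizes(6) == list(range(2, 25))
        assert s.sweep_sizes(2)[0] == 1


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        X, Y = separable_toy()
        model = train_mlp(X, Y, Architecture(2, (4,), 2), desk_config(seed=8, max_epochs=2000))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(predict(model, X), predict(back, X))
        assert back.architecture == model.architecture
        assert back.log == model.log
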