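"""The from-scratch network: transfer functions, objective, backprop, decoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from posewatch.neural import (
    NO_LABEL,
    BackpropMLP,
    NetworkConfig,
    TrainingSet,
    predict_label,
    sigmoid,
    size_hidden,
)


def make_net(n_in, n_hidden, n_out, seed=0, **kw):
    """A fitted net on tiny random data (weights then freely overwritable)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(max(3 * n_out, 6), n_in))
    y = np.array([f"c{i % n_out}" for i in range(len(X))])
    mlp = BackpropMLP(n_hidden=n_hidden, max_epochs=1, learning_rate=0.0, random_state=seed, **kw)
    return mlp.fit(X, y), X, y


class TestSigmoid:
    def test_closed_forms(self):
        assert sigmoid(0.0) == pytest.approx(0.5)
        assert sigmoid(math.log(3)) == pytest.approx(0.75)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-700, 700))
    def test_symmetry_identity(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_stable_at_extremes(self):
        assert sigmoid(700.0) == pytest.approx(1.0)
        assert sigmoid(-700.0) == pytest.approx(0.0, abs=1e-300)
        assert np.isfinite(sigmoid(np.array([-700.0, 700.0]))).all()


class TestSizeHidden:
    @pytest.mark.parametrize("n_in,n_out,expected", [(15, 5, 13), (18, 2, 13), (3, 3, 4)])
    def test_two_thirds_heuristic(self, n_in, n_out, expected):
        assert size_hidden(n_in, n_out) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            size_hidden(0, 2)


class TestForward:
    def test_zero_weights_give_half_everywhere(self):
        mlp, X, _ = make_net(4, 3, 2)
        mlp.w_hidden_[:] = 0; mlp.b_hidden_[:] = 0
        mlp.w_out_[:] = 0; mlp.b_out_[:] = 0
        _, O = mlp.forward(X)
        assert np.allclose(O, 0.5)

    def test_single_chain_hand_evaluation(self):
        # 1-1-1 chain, w=1, theta=0, x=0: o = s(s(0)) = s(0.5)
        mlp, _, _ = make_net(1, 1, 2)
        mlp.w_hidden_[:] = 1.0; mlp.b_hidden_[:] = 0.0
        mlp.w_out_[:] = 1.0; mlp.b_out_[:] = 0.0
        _, O = mlp.forward(np.array([[0.0]]))
        assert O[0, 0] == pytest.approx(sigmoid(0.5))
        assert O[0, 0] == pytest.approx(0.622459, abs=1e-6)

    def test_dimension_mismatch_is_shape_error(self):
        mlp, _, _ = make_net(4, 3, 2)
        with pytest.raises(ValueError, match="does not match"):
            mlp.forward(np.zeros((2, 5)))


class TestMSE:
    def test_perfect_fit_is_zero(self):
        mlp, _, _ = make_net(2, 2, 2)
        mlp.w_hidden_[:] = 0; mlp.b_hidden_[:] = 0; mlp.w_out_[:] = 0
        # drive outputs to (~1, ~0) and feed matching targets
        mlp.b_out_ = np.array([-60.0, 60.0])
        X = np.array([[0.3, 0.7]])
        assert mlp.mse(X, [mlp.classes_[0]]) == pytest.approx(0.0, abs=1e-20)

    def test_single_pattern_half_square_terms(self):
        # zero net: both outputs 0.5; the hit class contributes 1/2*(1-0.5)^2
        # = 0.125 and the miss class another 1/2*(0-0.5)^2 = 0.125
        mlp, _, _ = make_net(2, 2, 2)
        for arr in (mlp.w_hidden_, mlp.b_hidden_, mlp.w_out_, mlp.b_out_):
            arr[:] = 0
        E = mlp.mse(np.array([[0.1, 0.9]]), [mlp.classes_[0]])
        assert E == pytest.approx(0.125 + 0.125)

    def test_matches_hand_summed_double_loop(self):
        mlp, X, y = make_net(5, 4, 3, seed=3)
        classes = list(mlp.classes_)
        _, O = mlp.forward(X)
        total = 0.0
        for p in range(len(X)):  # independent brute-force summation
            for k in range(len(classes)):
                d = 1.0 if classes[k] == y[p] else 0.0
                total += (d - O[p, k]) ** 2
        assert mlp.mse(X, y) == pytest.approx(0.5 * total, abs=1e-12)

    def test_empty_set_rejected(self):
        mlp, _, _ = make_net(2, 2, 2)
        with pytest.raises(ValueError):
            mlp.mse(np.zeros((0, 2)), [])


def analytic_gradient(n_in, n_hidden, n_out, transfer, seed):
    """Gradient implied by one training step vs. central finite differences."""
    rng = np.random.default_rng(seed)
    n = 3 * n_out
    X = rng.uniform(0, 1, size=(n, n_in))
    y = np.array([f"c{i % n_out}" for i in range(n)])

    frozen = BackpropMLP(
        n_hidden=n_hidden, learning_rate=0.0, max_epochs=1, transfer=transfer, random_state=7
    ).fit(X, y)
    stepped = BackpropMLP(
        n_hidden=n_hidden, learning_rate=1.0, max_epochs=1, transfer=transfer, random_state=7
    ).fit(X, y)

    h = 1e-5
    results = []
    for name in ("w_hidden_", "b_hidden_", "w_out_", "b_out_"):
        W0, W1 = getattr(frozen, name), getattr(stepped, name)
        grad_impl = -(W1 - W0) * n  # update = -(lr/P) * grad, lr = 1
        grad_fd = np.zeros_like(W0)
        it = np.nditer(W0, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = W0[idx]
            W0[idx] = orig + h
            e_plus = frozen.mse(X, y)
            W0[idx] = orig - h
            e_minus = frozen.mse(X, y)
            W0[idx] = orig
            grad_fd[idx] = (e_plus - e_minus) / (2 * h)
        results.append(np.max(np.abs(grad_impl - grad_fd)))
    return max(results)


class TestTraining:
    @pytest.mark.parametrize("transfer", ["sigmoid", "tanh"])
    def test_gradient_matches_finite_differences(self, transfer):
        assert analytic_gradient(4, 3, 2, transfer, seed=1) < 1e-6

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (10, 3))
        y = np.array(["a", "b"] * 5)
        fits = [
            BackpropMLP(n_hidden=4, learning_rate=0.0, max_epochs=e, random_state=5).fit(X, y)
            for e in (1, 200)
        ]
        for name in ("w_hidden_", "b_hidden_", "w_out_", "b_out_"):
            assert np.array_equal(getattr(fits[0], name), getattr(fits[1], name))

    def test_small_step_decreases_error(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (30, 4))
        y = np.array(["a", "b", "c"] * 10)
        mlp = BackpropMLP(n_hidden=5, learning_rate=1e-3, max_epochs=2, random_state=9).fit(X, y)
        assert mlp.loss_curve_[1] < mlp.loss_curve_[0]

    def test_separable_blobs_converge_with_full_accuracy(self):
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal(0.25, 0.05, (20, 2)), rng.normal(0.75, 0.05, (20, 2))]
        ).clip(0, 1)
        y = np.array(["low"] * 20 + ["high"] * 20)
        # measured convergence for this seed/config: epoch 5914
        mlp = BackpropMLP(n_hidden=3, max_error=0.05, max_epochs=8000, random_state=1).fit(X, y)
        assert mlp.converged_ and mlp.n_epochs_ <= 8000
        assert mlp.loss_curve_[-1] <= 0.05
        assert (mlp.predict(X) == y).all()

    def test_bit_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (24, 5))
        y = np.array(["a", "b", "c"] * 8)
        a = BackpropMLP(n_hidden=4, max_epochs=300, random_state=3).fit(X, y)
        b = BackpropMLP(n_hidden=4, max_epochs=300, random_state=3).fit(X, y)
        for name in ("w_hidden_", "b_hidden_", "w_out_", "b_out_"):
            assert np.array_equal(getattr(a, name), getattr(b, name))
        assert np.array_equal(a.loss_curve_, b.loss_curve_)

    def test_trace_converged_flag_matches_threshold(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (12, 3))
        y = np.array(["a", "b"] * 6)
        mlp = BackpropMLP(n_hidden=3, max_error=1e-9, max_epochs=50, random_state=0).fit(X, y)
        trace = mlp.training_trace()
        assert trace.converged == (trace.errors[-1] <= 1e-9)
        assert not trace.converged  # 50 epochs cannot reach 1e-9 here

    def test_tanh_hidden_range_and_rescaled_outputs(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, (20, 3))
        y = np.array(["a", "b"] * 10)
        mlp = BackpropMLP(n_hidden=4, transfer="tanh", max_epochs=500, random_state=2).fit(X, y)
        Y, O = mlp.forward(X)
        assert Y.min() > -1 and Y.max() < 1
        assert O.min() > 0 and O.max() < 1


class TestLabelDecoding:
    LABELS = ["c0", "c1", "c2"]

    @pytest.mark.parametrize(
        "outputs,expected",
        [
            ((0.9, 0.1, 0.1), "c0"),
            ((0.4, 0.4, 0.4), NO_LABEL),  # below threshold
            ((0.8, 0.8, 0.1), NO_LABEL),  # tie resolved to index 0, then margin
            ((0.51, 0.2, 0.7), "c2"),
        ],
    )
    def test_threshold_and_margin_rules(self, outputs, expected):
        assert predict_label(outputs, self.LABELS, 0.5, 0.05) == expected

    def test_two_way_tie_with_margin(self):
        assert predict_label((0.8, 0.8), ["a", "b"], 0.5, 0.05) == NO_LABEL

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            predict_label((0.5, 0.5), ["a"])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_in=0, n_out=2),
            dict(n_in=3, n_out=2, n_hidden=0),
            dict(n_in=3, n_out=2, learning_rate=-0.1),
            dict(n_in=3, n_out=2, max_epochs=0),
            dict(n_in=3, n_out=2, transfer="relu"),
            dict(n_in=3, n_out=2, init_scale=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            NetworkConfig(**kw)

    def test_hidden_defaults_to_heuristic(self):
        assert NetworkConfig(n_in=15, n_out=5).hidden == 13

    def test_training_set_validation(self):
        with pytest.raises(ValueError):
            TrainingSet(X=np.zeros((3, 2)), y=np.array(["a"]))
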