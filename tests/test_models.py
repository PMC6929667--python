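"""Connectome filters, architecture assembly, and training behavior."""

import numpy as np
import pytest

import painconn as pc
from painconn.models import ArchitectureSpec, Network, TrainConfig, _softmax


class TestFilterPrimitives:
    def test_e2e_hand_example(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = pc.e2e_forward(a, np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert np.array_equal(out, [[4.0, 5.0], [6.0, 7.0]])

    def test_zero_weights_zero_output(self, rng):
        a = rng.standard_normal((5, 5))
        assert np.allclose(pc.e2e_forward(a, np.zeros(5), np.zeros(5)), 0)
        assert np.allclose(pc.e2n_forward(a, np.zeros(5)), 0)
        assert pc.n2g_forward(np.ones(5), np.zeros(5)) == 0.0

    def test_e2n_row_sums_and_selection(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.array_equal(pc.e2n_forward(a, np.ones(2)), [3.0, 7.0])
        e1 = np.array([0.0, 1.0])
        assert np.array_equal(pc.e2n_forward(a, e1), a[:, 1])

    def test_n2g_dot_product(self):
        assert pc.n2g_forward(np.array([3.0, 5.0]), np.array([2.0, 0.0])) == 6.0
        e0 = np.array([1.0, 0.0])
        assert pc.n2g_forward(np.array([3.0, 5.0]), e0) == 3.0

    def test_filters_match_triple_loop_oracle(self, rng):
        """100 random small instances against naive loop implementations."""
        for _ in range(100):
            n = int(rng.integers(2, 7))
            a = rng.standard_normal((n, n))
            r = rng.standard_normal(n)
            c = rng.standard_normal(n)
            e2e_oracle = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    e2e_oracle[i, j] = sum(r[k] * a[i, k] for k in range(n)) + \
                        sum(c[k] * a[k, j] for k in range(n))
            assert np.allclose(pc.e2e_forward(a, r, c), e2e_oracle, atol=1e-6)
            e2n_oracle = [sum(r[k] * a[i, k] for k in range(n)) for i in range(n)]
            assert np.allclose(pc.e2n_forward(a, r), e2n_oracle, atol=1e-6)
            assert pc.n2g_forward(a[0], c) == pytest.approx(
                sum(c[i] * a[0, i] for i in range(n)))

    def test_e2e_symmetry_equivariance(self, rng):
        a = rng.standard_normal((6, 6))
        a = a + a.T
        w = rng.standard_normal(6)
        out = pc.e2e_forward(a, w, w)
        assert np.allclose(out, out.T)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pc.e2e_forward(rng.standard_normal((3, 3)), np.zeros(4), np.zeros(3))
        with pytest.raises(ValueError):
            pc.e2n_forward(rng.standard_normal((3, 4)), np.zeros(3))


class TestArchitectures:
    @pytest.mark.parametrize("name", ["ann4brains", "ann4brains_batch", "conv1d_net"])
    def test_parameter_count_matches_closed_form(self, name):
        spec = ArchitectureSpec(name=name, n_regions=10)
        net = pc.build_architecture(spec, seed=0)
        assert net.n_parameters() == pc.expected_parameter_count(spec)

    @pytest.mark.parametrize("name", ["ann4brains", "ann4brains_batch", "conv1d_net"])
    def test_probabilities_sum_to_one_with_random_weights(self, name, rng):
        spec = ArchitectureSpec(name=name, n_regions=8)
        net = pc.build_architecture(spec, seed=1)
        x = rng.standard_normal((7, 8, 8))
        p = net.predict_proba(x)
        assert p.shape == (7, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_batch_norm_variant_differs_only_by_norm_layers(self):
        plain = pc.build_architecture(ArchitectureSpec("ann4brains", 8), seed=0)
        bn = pc.build_architecture(ArchitectureSpec("ann4brains_batch", 8,
                                                    batch_norm=True), seed=0)
        kinds_plain = [type(l).__name__ for l in plain.layers]
        kinds_bn = [type(l).__name__ for l in bn.layers]
        assert [k for k in kinds_bn if k != "BatchNorm"] == kinds_plain
        assert kinds_bn.count("BatchNorm") == 3

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            pc.build_architecture(ArchitectureSpec("resnet", 8))

    def test_gradients_match_finite_differences(self, rng):
        """Backprop through the full E2E/E2N/N2G stack vs numeric gradients."""
        spec = ArchitectureSpec("ann4brains", n_regions=4, e2e_filters=2,
                                e2n_filters=3, n2g_units=4, fc_sizes=(4, 3, 2))
        net = pc.build_architecture(spec, seed=3)
        x = rng.standard_normal((5, 4, 4))
        y = rng.integers(0, 2, 5)
        net.loss_and_backward(x, y)
        params = net.params()
        for p in params[::3]:
            flat = p.value.ravel()
            k = int(rng.integers(flat.size))
            eps = 1e-6
            orig = flat[k]
            flat[k] = orig + eps
            lp = _ce(net, x, y)
            flat[k] = orig - eps
            lm = _ce(net, x, y)
            flat[k] = orig
            net.loss_and_backward(x, y)
            assert p.grad.ravel()[k] == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)


def _ce(net: Network, x, y):
    p = _softmax(net.forward(x, training=True))
    return float(-np.log(p[np.arange(len(y)), y]).mean())


def _gaussian_matrix_task(rng, n=6, per_class=120, sep=5.0):
    """Two Gaussian classes of symmetric matrices, widely separated."""
    base = rng.standard_normal((per_class * 2, n, n))
    base = (base + base.transpose(0, 2, 1)) / 2
    base[per_class:] += sep / np.sqrt(n)
    y = np.repeat([0, 1], per_class)
    order = rng.permutation(len(y))
    return base[order], y[order]


class TestTraining:
    def test_separable_classes_are_fit(self, rng):
        x, y = _gaussian_matrix_task(rng)
        spec = ArchitectureSpec("ann4brains", 6, e2e_filters=4, e2n_filters=8,
                                n2g_units=16, fc_sizes=(16, 8, 2),
                                learning_rate=0.01)
        net = pc.build_architecture(spec, seed=0)
        trained = pc.train_model(net, x[:180], y[:180], x[180:220], y[180:220],
                                 spec, TrainConfig(epochs=30), seed=0)
        p = pc.predict_proba(trained, x[:180])
        ba = pc.balanced_accuracy(y[:180], (p[:, 1] >= 0.5).astype(int))
        assert ba >= 0.95
        assert p[y[:180] == 1, 1].mean() > 0.9
        assert trained.history, "training history must be recorded"

    def test_untrained_model_is_at_chance(self, rng):
        x, y = _gaussian_matrix_task(rng, sep=0.0)
        net = pc.build_architecture(ArchitectureSpec("conv1d_net", 6), seed=2)
        p = net.predict_proba(x)
        ba = pc.balanced_accuracy(y, (p[:, 1] >= 0.5).astype(int))
        assert 0.3 <= ba <= 0.7

    def test_l1_penalty_shrinks_weights(self, rng):
        """Across seeds, lambda_1 = 0.1 ends with smaller total |w| than 0."""
        shrunk = 0
        for seed in range(5):
            l1_sums = {}
            for lam in (0.0, 0.1):
                r = np.random.default_rng(100 + seed)
                x, y = _gaussian_matrix_task(r, per_class=60)
                spec = ArchitectureSpec("conv1d_net", 6, l1_lambda=lam,
                                        learning_rate=0.01)
                net = pc.build_architecture(spec, seed=seed)
                pc.train_model(net, x[:90], y[:90], x[90:120], y[90:120],
                               spec, TrainConfig(epochs=15), seed=seed)
                l1_sums[lam] = net.weight_l1()
            shrunk += l1_sums[0.1] < l1_sums[0.0]
        assert shrunk >= 4

    def test_seeded_training_is_deterministic(self, rng):
        x, y = _gaussian_matrix_task(rng, per_class=40)
        losses = []
        for _ in range(2):
            spec = ArchitectureSpec("ann4brains", 6, e2e_filters=2,
                                    e2n_filters=4, n2g_units=8,
                                    fc_sizes=(8, 4, 2), dropout=0.3,
                                    learning_rate=0.01)
            net = pc.build_architecture(spec, seed=5)
            tr = pc.train_model(net, x[:60], y[:60], x[60:80], y[60:80],
                                spec, TrainConfig(epochs=8), seed=5)
            losses.append(tr.history[-1]["val_loss"])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_nonfinite_loss_aborts_with_diagnostic(self, rng):
        x, y = _gaussian_matrix_task(rng, per_class=30)
        spec = ArchitectureSpec("conv1d_net", 6, learning_rate=1e4)
        net = pc.build_architecture(spec, seed=1)
        with pytest.raises(RuntimeError, match="non-finite"):
            pc.train_model(net, 1e3 * x[:40], y[:40], x[40:60], y[40:60],
                           spec, TrainConfig(epochs=10), seed=1)


class TestPredictProba:
    def test_duplicated_rows_get_identical_probabilities(self, rng):
        net = pc.build_architecture(
            ArchitectureSpec("ann4brains", 5, dropout=0.5), seed=0)
        x = rng.standard_normal((1, 5, 5))
        batch = np.concatenate([x, x, x])
        p = net.predict_proba(batch)
        assert np.array_equal(p[0], p[1]) and np.array_equal(p[1], p[2])

    def test_wrong_feature_dimension_rejected(self, rng):
        net = pc.build_architecture(ArchitectureSpec("ann4brains", 5), seed=0)
        trained = pc.TrainedModel(network=net, spec=net.spec)
        with pytest.raises(ValueError):
            pc.predict_proba(trained, rng.standard_normal((2, 4, 4)))
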