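"""Class weighting, the weighted loss, augmentation, SGDM and the train loop."""

import numpy as np
import pytest

import _oracles as oracle
from segbrain.io_data import SlicePair
from segbrain.layers import ConvParams
from segbrain.network import build_architecture, forward, init_params, predict_labels
from segbrain.phantom import PhantomSpec, generate_dataset, generate_phantom
from segbrain.training import (
    TrainConfig,
    augment_pair,
    compute_class_weights,
    init_optimizer_state,
    loss_gradients,
    sgdm_step,
    train,
    weighted_cross_entropy,
)


class TestClassWeights:
    def test_equal_frequencies_give_unit_weights(self):
        labels = np.repeat(np.arange(4), 25).reshape(10, 10)
        np.testing.assert_allclose(compute_class_weights([labels]), 1.0)

    def test_hand_computed_frequencies(self):
        # frequencies (0.5, 0.25, 0.15, 0.1); median 0.2
        counts = [50, 25, 15, 10]
        labels = np.concatenate([np.full(c, i) for i, c in enumerate(counts)]).reshape(10, 10)
        np.testing.assert_allclose(compute_class_weights([labels]),
                                   [0.4, 0.8, 4 / 3, 2.0])

    def test_phantom_background_downweighted(self, small_pair):
        w = compute_class_weights([small_pair.labels])
        freq = np.bincount(small_pair.labels.ravel(), minlength=4) / small_pair.labels.size
        assert w[0] < 1.0  # dominant background
        assert w[np.argmin(freq)] > 1.0

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            compute_class_weights([np.zeros((4, 4), dtype=int)])


class TestWeightedCrossEntropy:
    def test_perfect_one_hot_loss_vanishes(self, rng):
        truth = rng.integers(0, 4, size=(2, 4, 4))
        probs = np.zeros((2, 4, 4, 4))
        for n in range(2):
            for c in range(4):
                probs[n, c][truth[n] == c] = 1.0
        assert weighted_cross_entropy(probs, truth, np.ones(4)) <= 1e-6

    def test_uniform_predictions_give_ln4(self, rng):
        truth = rng.integers(0, 4, size=(1, 6, 6))
        probs = np.full((1, 4, 6, 6), 0.25)
        assert weighted_cross_entropy(probs, truth, np.ones(4)) == pytest.approx(np.log(4))

    def test_matches_per_pixel_loop_oracle(self, rng):
        probs = rng.dirichlet(np.ones(4), size=(2, 5, 5)).transpose(0, 3, 1, 2)
        truth = rng.integers(0, 4, size=(2, 5, 5))
        w = rng.uniform(0.2, 3.0, size=4)
        assert weighted_cross_entropy(probs, truth, w) == pytest.approx(
            oracle.wce_loops(probs, truth, w), abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            weighted_cross_entropy(rng.random((1, 4, 4, 4)), np.zeros((1, 5, 5), int), np.ones(4))


class TestLossGradients:
    def test_finite_difference_agreement_small_net(self, rng):
        """Central differences on a width-4 net with 8x8 inputs, double precision."""
        arch = build_architecture(4)
        params = init_params(arch, 5, dtype=np.float64)
        x = rng.normal(size=(2, 1, 8, 8))
        y = rng.integers(0, 4, size=(2, 8, 8))
        w = np.array([0.5, 1.5, 1.0, 2.0])
        _, _, grads = loss_gradients(params, (x, y), w, arch, mode="train")

        def loss_now():
            probs, _ = forward(params, x, mode="train", arch=arch)
            return weighted_cross_entropy(probs, y, w)

        eps = 1e-6
        checked = passed = 0
        for name, p in params.items():
            arrays = (p.kernels, p.bias) if isinstance(p, ConvParams) else (p.gamma, p.beta)
            for ai, arr in enumerate(arrays):
                flat = arr.ravel()
                for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp = loss_now()
                    flat[i] = orig - eps
                    lm = loss_now()
                    flat[i] = orig
                    fd = (lp - lm) / (2 * eps)
                    an = grads[name][ai].ravel()[i]
                    checked += 1
                    if abs(fd) < 1e-8 and abs(an) < 1e-8:
                        passed += 1
                    elif abs(fd - an) / max(abs(fd), abs(an)) < 1e-4:
                        passed += 1
        assert passed / checked >= 0.99

    def test_duplicated_batch_same_gradient(self, rng):
        """Mean normalization: replicating a batch leaves gradients unchanged."""
        arch = build_architecture(3)
        params = init_params(arch, 2, dtype=np.float64)
        x = rng.normal(size=(2, 1, 8, 8))
        y = rng.integers(0, 4, size=(2, 8, 8))
        w = np.ones(4)
        _, _, g1 = loss_gradients(params, (x, y), w, arch)
        _, _, g2 = loss_gradients(params, (np.tile(x, (2, 1, 1, 1)), np.tile(y, (2, 1, 1))),
                                  w, arch)
        for name in g1:
            for a, b in zip(g1[name], g2[name]):
                np.testing.assert_allclose(a, b, atol=1e-10)


class TestAugmentation:
    def test_zero_rotation_no_flip_is_identity(self, small_pair):
        pair = SlicePair(image=small_pair.image, labels=small_pair.labels)

        class FixedRng:
            def random(self):
                return 0.9  # no flip

            def uniform(self, a, b):
                return 0.0

        out = augment_pair(pair, FixedRng(), rotation_range=10.0)
        np.testing.assert_array_equal(out.image, pair.image)
        np.testing.assert_array_equal(out.labels, pair.labels)

    def test_labels_stay_valid_and_shapes_preserved(self, small_pair, rng):
        pair = SlicePair(image=small_pair.image, labels=small_pair.labels)
        for _ in range(10):
            out = augment_pair(pair, rng)
            assert out.image.shape == pair.image.shape
            assert set(np.unique(out.labels)) <= {0, 1, 2, 3}

    def test_double_flip_is_identity(self, small_pair):
        pair = SlicePair(image=small_pair.image, labels=small_pair.labels)

        class FlipOnly:
            def random(self):
                return 0.1  # always flip

            def uniform(self, a, b):
                return 0.0

        once = augment_pair(pair, FlipOnly(), rotation_range=0.0)
        twice = augment_pair(once, FlipOnly(), rotation_range=0.0)
        np.testing.assert_array_equal(twice.image, pair.image)
        np.testing.assert_array_equal(twice.labels, pair.labels)


class TestSgdm:
    def test_plain_gradient_step(self):
        params = init_params(build_architecture(2), 0, dtype=np.float64)
        state = init_optimizer_state(params)
        grads = {"encoder1_conv1": (np.ones_like(params["encoder1_conv1"].kernels),
                                    np.zeros_like(params["encoder1_conv1"].bias))}
        before = params["encoder1_conv1"].kernels.copy()
        sgdm_step(params, grads, state, lr=0.1, momentum=0.0)
        np.testing.assert_allclose(params["encoder1_conv1"].kernels, before - 0.1, atol=1e-12)

    def test_two_momentum_steps_hand_recursion(self):
        params = init_params(build_architecture(2), 0, dtype=np.float64)
        state = init_optimizer_state(params)
        k = params["encoder1_conv1"].kernels
        before = k.copy()
        grads = {"encoder1_conv1": (np.ones_like(k), np.zeros(2))}
        sgdm_step(params, grads, state, lr=0.1, momentum=0.9)
        sgdm_step(params, grads, state, lr=0.1, momentum=0.9)
        # v1 = -0.1, v2 = -0.19 -> cumulative -0.29
        np.testing.assert_allclose(k, before - 0.29, atol=1e-12)

    def test_zero_gradients_leave_parameters_fixed(self):
        params = init_params(build_architecture(2), 0, dtype=np.float64)
        state = init_optimizer_state(params)
        before = params["encoder1_conv1"].kernels.copy()
        zeros = {"encoder1_conv1": (np.zeros_like(before), np.zeros(2))}
        for _ in range(5):
            sgdm_step(params, zeros, state, lr=0.5, momentum=0.9)
        np.testing.assert_array_equal(params["encoder1_conv1"].kernels, before)


class TestTrainLoop:
    def _tiny_dataset(self, n=4, hw=16, seed=0):
        spec = PhantomSpec(height=hw, width=hw, seed=seed)
        return [generate_phantom(spec, np.random.default_rng(seed + i)) for i in range(n)]

    def test_epoch_and_minibatch_bookkeeping(self):
        data = self._tiny_dataset(16)
        cfg = TrainConfig(max_epochs=1, batch_size=8, filter_width=2, augment=False)
        _, hist = train(data, cfg)
        assert len(hist) == 1
        assert set(hist.epochs[0]) >= {"epoch", "loss", "train_accuracy", "wall_time_s"}

    def test_same_seed_identical_parameters(self):
        data = self._tiny_dataset(4)
        cfg = TrainConfig(max_epochs=2, batch_size=4, filter_width=2, seed=9)
        p1, _ = train(data, cfg)
        p2, _ = train(data, cfg)
        for name in p1:
            for a, b in zip(vars(p1[name]).values(), vars(p2[name]).values()):
                if isinstance(a, np.ndarray):
                    np.testing.assert_array_equal(a, b)

    def test_missing_class_rejected_at_weighting(self):
        bad = [SlicePair(image=np.zeros((8, 8)), labels=np.zeros((8, 8), dtype=np.uint8))]
        with pytest.raises(ValueError, match="absent"):
            train(bad, TrainConfig(max_epochs=1, filter_width=2))

    def test_overfit_small_run_reaches_high_training_accuracy(self):
        """A reduced net driven hard on 4 phantoms must essentially memorize
        them (loss-decrease sanity check for the whole loop)."""
        data = self._tiny_dataset(4, hw=16, seed=3)
        cfg = TrainConfig(max_epochs=60, batch_size=4, filter_width=8, augment=False,
                          learning_rate=0.25, seed=1, early_stop_patience=60)
        params, hist = train(data, cfg)
        assert hist.epochs[-1]["train_accuracy"] > 0.95
        first = np.median([r["loss"] for r in hist.epochs[:5]])
        last = np.median([r["loss"] for r in hist.epochs[-5:]])
        assert last < first
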