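"""ANN training, recognition with hold-previous, and PCA diagnostics."""

import numpy as np
import pytest

from myoctl import pattern
from myoctl.pattern import (
    AnnConfig,
    AnnModel,
    RecognizerState,
    TrainingBlock,
    TrainingStore,
    add_block_and_train,
    backprop_gradients,
    forward,
    init_ann,
    pca_contribution,
    recognize,
)
from myoctl.simulate import MotionLabel


def make_block(rng, center, label, spread=0.02):
    return TrainingBlock(
        vectors=center + spread * rng.standard_normal((20, 16)), label=label
    )


def zero_model(config=AnnConfig()):
    n_in, n_hid, n_out = config.layers
    return AnnModel(
        w1=np.zeros((n_hid, n_in)),
        b1=np.zeros(n_hid),
        w2=np.zeros((n_out, n_hid)),
        b2=np.zeros(n_out),
        config=config,
    )


class TestInitAndForward:
    def test_same_seed_identical(self):
        a, b = init_ann(AnnConfig(init_seed=5)), init_ann(AnnConfig(init_seed=5))
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)
        assert np.array_equal(a.b1, b.b1) and np.array_equal(a.b2, b.b2)

    def test_zero_weights_give_half(self):
        out = forward(zero_model(), np.ones(16))
        assert np.allclose(out, 0.5)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AnnConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            AnnConfig(target_hot=0.5, recognition_threshold=0.65)

    def test_tiny_network_by_hand(self):
        """2-2-1 forward pass against a pencil-and-paper computation."""
        cfg = AnnConfig(layers=(2, 2, 1))
        model = AnnModel(
            w1=np.array([[1.0, -1.0], [0.5, 0.5]]),
            b1=np.array([0.0, 1.0]),
            w2=np.array([[2.0, -1.0]]),
            b2=np.array([0.5]),
            config=cfg,
        )
        x = np.array([1.0, 2.0])
        sig = lambda z: 1 / (1 + np.exp(-z))
        h = sig(np.array([1.0 - 2.0, 0.5 + 1.0 + 1.0]))
        expected = sig(2.0 * h[0] - 1.0 * h[1] + 0.5)
        assert forward(model, x)[0] == pytest.approx(float(expected), rel=1e-12)

    def test_outputs_bounded(self, rng):
        model = init_ann(AnnConfig(init_seed=1))
        for _ in range(20):
            out = forward(model, rng.uniform(0, 1, 16))
            assert np.all((out > 0) & (out < 1))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            forward(init_ann(), np.zeros(15))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        cfg = AnnConfig(layers=(4, 5, 3), init_seed=3)
        model = init_ann(cfg)
        x = rng.uniform(0, 1, 4)
        t = rng.uniform(0, 1, 3)
        gw1, gb1, gw2, gb2 = backprop_gradients(model, x, t)

        def loss():
            o = forward(model, x)
            return 0.5 * np.sum((o - t) ** 2)

        eps = 1e-6
        for arr, grad in ((model.w1, gw1), (model.b1, gb1), (model.w2, gw2), (model.b2, gb2)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss()
                arr[idx] = orig - eps
                lm = loss()
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestTraining:
    def test_separable_clusters_reach_full_train_accuracy(self, rng):
        c1, c2 = np.zeros(16), np.zeros(16)
        c1[2] = 1.0
        c2[10] = 1.0
        model = init_ann(AnnConfig(init_seed=0))
        store = TrainingStore()
        model, _ = add_block_and_train(model, store, make_block(rng, c1, MotionLabel.GRASP))
        model, acc = add_block_and_train(model, store, make_block(rng, c2, MotionLabel.OPEN))
        assert acc == 1.0

    def test_single_block_memorized(self, rng):
        c = np.zeros(16)
        c[5] = 1.0
        model = init_ann(AnnConfig(init_seed=1))
        store = TrainingStore()
        model, acc = add_block_and_train(model, store, make_block(rng, c, MotionLabel.GRASP))
        assert acc == 1.0
        state = RecognizerState()
        assert recognize(model, store.blocks[0].vectors[0], store, state) == MotionLabel.GRASP

    def test_training_deterministic(self, rng):
        c = np.zeros(16)
        c[5] = 1.0
        blocks = [make_block(rng, c, MotionLabel.GRASP)]
        finals = []
        for _ in range(2):
            model = init_ann(AnnConfig(init_seed=7))
            store = TrainingStore()
            for b in blocks:
                model, _ = add_block_and_train(model, store, b)
            finals.append(model)
        assert np.array_equal(finals[0].w1, finals[1].w1)
        assert np.array_equal(finals[0].w2, finals[1].w2)

    def test_too_many_labels_rejected(self, rng):
        store = TrainingStore()
        # fill all 8 output neurons with synthetic labels not equal to GRASP
        for n, k in enumerate(range(10, 18)):
            store.neuron_of[k] = n
        with pytest.raises(ValueError):
            store.add(make_block(rng, np.zeros(16), MotionLabel.GRASP))

    def test_block_size_enforced(self):
        with pytest.raises(ValueError):
            TrainingBlock(vectors=np.zeros((19, 16)), label=MotionLabel.REST)


class TestRecognize:
    def _store_two_labels(self):
        store = TrainingStore()
        store.neuron_of = {MotionLabel.GRASP: 0, MotionLabel.OPEN: 1}
        return store

    def test_firing_neuron_identified(self):
        store = self._store_two_labels()
        model = zero_model()
        model.b2[0] = 2.0  # sigmoid(2) ~ 0.88 >= 0.65
        state = RecognizerState()
        assert recognize(model, np.zeros(16), store, state) == MotionLabel.GRASP
        assert state.previous_label == MotionLabel.GRASP

    def test_hold_previous_when_nothing_fires(self):
        store = self._store_two_labels()
        model = zero_model()  # all outputs 0.5 < 0.65
        state = RecognizerState(previous_label=MotionLabel.GRASP)
        assert recognize(model, np.zeros(16), store, state) == MotionLabel.GRASP

    def test_untrained_model_holds_rest(self):
        store = self._store_two_labels()
        state = RecognizerState()
        assert recognize(zero_model(), np.zeros(16), store, state) == MotionLabel.REST

    def test_never_emits_unregistered_label(self, rng):
        store = self._store_two_labels()
        model = init_ann(AnnConfig(init_seed=2))
        state = RecognizerState()
        seen = {
            recognize(model, rng.uniform(0, 1, 16), store, state) for _ in range(200)
        }
        assert seen <= {MotionLabel.GRASP, MotionLabel.OPEN, MotionLabel.REST}
        # rest only ever appears as the initial hold, never as a decision
        model2 = zero_model()
        model2.b2[2] = 5.0  # unregistered neuron fires hard
        state2 = RecognizerState(previous_label=MotionLabel.GRASP)
        assert recognize(model2, np.zeros(16), store, state2) == MotionLabel.GRASP

    def test_tie_goes_to_lowest_neuron(self):
        store = self._store_two_labels()
        model = zero_model()
        model.b2[0] = model.b2[1] = 2.0
        state = RecognizerState()
        assert recognize(model, np.zeros(16), store, state) == MotionLabel.GRASP

    def test_label_permutation_equivariance(self, rng):
        """Swapping the label->neuron map and the matching output rows
        leaves recognition decisions unchanged."""
        model = init_ann(AnnConfig(init_seed=4))
        store = self._store_two_labels()
        swapped = TrainingStore()
        swapped.neuron_of = {MotionLabel.GRASP: 1, MotionLabel.OPEN: 0}
        model_sw = init_ann(AnnConfig(init_seed=4))
        model_sw.w2[[0, 1]] = model_sw.w2[[1, 0]]
        model_sw.b2[[0, 1]] = model_sw.b2[[1, 0]]
        for _ in range(50):
            x = rng.uniform(0, 1, 16)
            s1, s2 = RecognizerState(), RecognizerState()
            assert recognize(model, x, store, s1) == recognize(model_sw, x, swapped, s2)


class TestPca:
    def test_rank_one_data(self, rng):
        direction = rng.standard_normal(16)
        coeffs = rng.standard_normal(40)
        store = TrainingStore()
        store.add(TrainingBlock(np.outer(coeffs[:20], direction), MotionLabel.GRASP))
        store.add(TrainingBlock(np.outer(coeffs[20:], direction), MotionLabel.OPEN))
        ratios, scores, labels = pca_contribution(store)
        assert ratios[0] == pytest.approx(1.0, abs=1e-10)
        assert labels.shape == (40,)

    def test_isotropic_gaussian_splits_evenly(self, rng):
        x = np.zeros((2000, 16))
        x[:, :2] = rng.standard_normal((2000, 2))
        store = TrainingStore()
        for k in range(100):
            store.add(TrainingBlock(x[20 * k : 20 * (k + 1)], MotionLabel.REST))
        ratios, _, _ = pca_contribution(store)
        assert ratios[0] == pytest.approx(0.5, abs=0.05)
        assert ratios[1] == pytest.approx(0.5, abs=0.05)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.decomposition import PCA

        x = rng.standard_normal((60, 16))
        store = TrainingStore()
        for k in range(3):
            store.add(TrainingBlock(x[20 * k : 20 * (k + 1)], MotionLabel(k)))
        ratios, scores, _ = pca_contribution(store)
        ref = PCA().fit(x)
        assert np.allclose(ratios, ref.explained_variance_ratio_, atol=1e-10)
        ref_scores = ref.transform(x)[:, :2]
        for j in range(2):  # eigenvector sign is arbitrary
            assert np.allclose(scores[:, j], ref_scores[:, j], atol=1e-8) or np.allclose(
                scores[:, j], -ref_scores[:, j], atol=1e-8
            )

    def test_degenerate_data_rejected(self):
        store = TrainingStore()
        store.add(TrainingBlock(np.ones((20, 16)), MotionLabel.REST))
        with pytest.raises(ValueError):
            pca_contribution(store)


class TestPersistence:
    def test_model_json_roundtrip(self, tmp_path, rng):
        c = np.zeros(16)
        c[3] = 1.0
        model = init_ann(AnnConfig(init_seed=9))
        store = TrainingStore()
        model, _ = add_block_and_train(model, store, make_block(rng, c, MotionLabel.OPEN))
        path = tmp_path / "model.json"
        pattern.save_model(model, store, path)
        back, back_store = pattern.load_model(path)
        assert np.allclose(back.w1, model.w1) and np.allclose(back.w2, model.w2)
        assert back_store.neuron_of == store.neuron_of
        x = store.blocks[0].vectors[0]
        assert np.allclose(forward(back, x), forward(model, x))

    def test_store_json_roundtrip(self, tmp_path, rng):
        store = TrainingStore()
        store.add(make_block(rng, np.zeros(16), MotionLabel.GRASP))
        path = tmp_path / "store.json"
        store.to_json(path)
        back = TrainingStore.from_json(path)
        assert back.neuron_of == store.neuron_of
        assert np.allclose(back.blocks[0].vectors, store.blocks[0].vectors)
        assert back.blocks[0].label == MotionLabel.GRASP
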