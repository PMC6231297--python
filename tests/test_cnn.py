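import numpy as np
import pytest

from mcipredict.cnn import (
    CnnConfig,
    CnnModel,
    build_cnn,
    classify_subject_by_patch_vote,
    extract_cnn_features,
    majority_vote,
    n_minibatches,
    softmax,
    softmax_cross_entropy,
    train_cnn,
)
from mcipredict.patches import Patch25D, PatchLocation, extract_patch_set, sample_locations
from mcipredict.synthetic import SyntheticConfig, generate_cohort


def _random_patches(n, rng, sid="s"):
    return [
        Patch25D(rng.normal(size=(32, 32, 3)).astype(np.float32), PatchLocation(16, 16, 16), sid)
        for _ in range(n)
    ]


@pytest.fixture(scope="module")
def separable_training():
    """20 subjects, strong atrophy, 20 patches each: easily separable."""
    cfg = SyntheticConfig(
        n_per_group={"AD": 10, "NC": 10, "MCIc": 0, "MCInc": 0},
        atrophy_effect={"AD": 0.8, "MCIc": 0.4, "MCInc": 0.1, "NC": 0.0},
        noise_sd=2.0,
        seed=11,
    )
    records, volumes, mask = generate_cohort(cfg)
    locs = sample_locations(mask, n=20, seed=11)
    patches, labels = [], []
    for rec, vol in zip(records, volumes):
        ps = extract_patch_set(vol, locs)
        patches.extend(ps)
        labels.extend([1 if rec.group == "AD" else 0] * len(ps))
    return patches, labels


@pytest.fixture(scope="module")
def trained_model(separable_training):
    patches, labels = separable_training
    model = build_cnn(CnnConfig(epochs=6, batch_size=64, seed=11))
    train_cnn(model, patches, labels)
    return model


class TestArchitecture:
    def test_flattened_feature_dim_1024(self):
        model = build_cnn(CnnConfig())
        assert model.feature_dim == 1024

    def test_forward_feature_length(self, rng):
        model = build_cnn(CnnConfig())
        f = model.forward_features(model._prep(_random_patches(2, rng)))
        assert f.shape == (2, 1024)

    def test_spatial_trace(self):
        # (32,32,32)->(32,16,16)->(32,16,16)->(32,8,8)->(64,8,8)->(64,4,4)
        from mcipredict.cnn import Conv2D, Pool2D

        model = build_cnn(CnnConfig())
        x = np.zeros((1, 3, 32, 32), dtype=np.float32)
        shapes = []
        for layer in model.feature_layers:
            x = layer.forward(x)
            if isinstance(layer, (Conv2D, Pool2D)):
                shapes.append(x.shape[1:])
        assert shapes == [
            (32, 32, 32),
            (32, 16, 16),
            (32, 16, 16),
            (32, 8, 8),
            (64, 8, 8),
            (64, 4, 4),
        ]

    def test_softmax_sums_to_one_untrained(self, rng):
        model = build_cnn(CnnConfig())
        probs = model.predict_proba(_random_patches(3, rng))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_bad_pool_kind(self):
        with pytest.raises(ValueError, match="pool"):
            build_cnn(CnnConfig(pool_types=("max", "avg", "median")))

    def test_channel_pool_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            CnnConfig(channels=(32, 64), pool_types=("max", "avg", "avg"))


class TestGradients:
    def test_backward_matches_central_differences(self, rng):
        cfg = CnnConfig(channels=(3, 3, 4), init_std=0.1, init_scheme="gaussian",
                        seed=3, lrn_alpha=0.05)
        model = CnnModel(cfg)
        for layer, name in model.parameters():
            layer.params[name] = layer.params[name].astype(np.float64)
        x = rng.normal(size=(2, 3, 32, 32))
        y = np.array([0, 1])

        def loss():
            return softmax_cross_entropy(model.forward_logits(x), y)[0]

        _, grad = softmax_cross_entropy(model.forward_logits(x), y)
        model.backward(grad)
        eps = 1e-6
        for layer, name in model.parameters():
            p, ana = layer.params[name], layer.grads[name]
            for _ in range(4):
                idx = tuple(rng.integers(s) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - ana[idx]) <= 1e-5 * max(1.0, abs(num))


class TestTraining:
    def test_zero_epochs_leaves_weights(self, rng):
        model = build_cnn(CnnConfig(epochs=0, seed=1))
        before = [(layer, name, layer.params[name].copy())
                  for layer, name in model.parameters()]
        patches = _random_patches(8, rng)
        train_cnn(model, patches, [0, 1] * 4)
        for layer, name, saved in before:
            np.testing.assert_array_equal(layer.params[name], saved)

    def test_empty_training_set(self):
        model = build_cnn(CnnConfig())
        with pytest.raises(ValueError, match="empty"):
            train_cnn(model, [], [])

    def test_single_class_rejected(self, rng):
        model = build_cnn(CnnConfig())
        with pytest.raises(ValueError, match="both classes"):
            train_cnn(model, _random_patches(4, rng), [1, 1, 1, 1])

    def test_determinism(self, separable_training):
        patches, labels = separable_training
        cfg = CnnConfig(epochs=1, batch_size=64, seed=5)
        subset = slice(150, 250)  # spans both classes
        m1 = train_cnn(build_cnn(cfg), patches[subset], labels[subset])
        m2 = train_cnn(build_cnn(cfg), patches[subset], labels[subset])
        for (l1, n1), (l2, n2) in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(l1.params[n1], l2.params[n2])

    def test_loss_decreases_and_training_accuracy(self, trained_model, separable_training):
        patches, labels = separable_training
        log = trained_model.training_log
        assert log[-1]["loss"] < log[0]["loss"]
        probs = trained_model.predict_proba(patches)
        acc = (probs.argmax(axis=1) == np.asarray(labels)).mean()
        assert acc >= 0.95

    def test_minibatch_count(self):
        # 417 subjects x 151 patches at batch 151 -> 417 mini-batches
        assert n_minibatches(62967, 151) == 417
        assert n_minibatches(10, 3) == 4
        with pytest.raises(ValueError):
            n_minibatches(10, 0)


class TestFeatureExtraction:
    def test_identical_patches_identical_rows(self, trained_model, rng):
        p = _random_patches(1, rng)[0]
        fm = extract_cnn_features(trained_model, [p, p])
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_feature_matrix_shape_and_content(self, trained_model, separable_training):
        patches, _ = separable_training
        fm = extract_cnn_features(trained_model, patches[:10])
        assert fm.values.shape == (10, 1024)
        assert np.all(np.isfinite(fm.values))
        assert np.any(fm.values != 0)

    def test_untrained_model_features_defined(self, rng):
        model = build_cnn(CnnConfig(seed=2))
        fm = extract_cnn_features(model, _random_patches(2, rng))
        assert fm.values.shape == (2, 1024)

    def test_empty_patch_list(self, trained_model):
        with pytest.raises(ValueError, match="no patches"):
            extract_cnn_features(trained_model, [])


class TestPatchVote:
    def test_unanimity(self):
        assert majority_vote([1] * 151) == 1
        assert majority_vote([0] * 151) == 0

    def test_majority_oracle_76_vs_75(self):
        votes = [1] * 76 + [0] * 75
        # brute-force count oracle
        assert sum(votes) > len(votes) - sum(votes)
        assert majority_vote(votes) == 1
        assert majority_vote([0] * 76 + [1] * 75) == 0

    def test_tie_goes_positive(self):
        assert majority_vote([1, 0]) == 1

    def test_single_patch(self, trained_model, separable_training):
        patches, labels = separable_training
        vote = classify_subject_by_patch_vote(trained_model, patches[:1])
        probs = trained_model.predict_proba(patches[:1])
        assert vote == int(probs[0].argmax())

    def test_empty(self, trained_model):
        with pytest.raises(ValueError):
            classify_subject_by_patch_vote(trained_model, [])


class TestPersistence:
    def test_save_load_roundtrip(self, trained_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        back = CnnModel.load(path)
        x = _random_patches(3, rng)
        np.testing.assert_allclose(
            trained_model.predict_proba(x), back.predict_proba(x), atol=1e-7
        )
        assert back.trained


def test_softmax_normalization(rng):
    logits = rng.normal(size=(5, 2)) * 10
    np.testing.assert_allclose(softmax(logits).sum(axis=1), 1.0, atol=1e-12)
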