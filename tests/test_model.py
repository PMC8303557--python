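"""Classifier architecture, focal loss, schedule, training contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sijbme import nn
from sijbme.model import (
    ClassifierConfig,
    Classifier,
    build_classifier,
    cosine_lr,
    focal_loss,
    load_checkpoint,
    predict_slice,
    save_checkpoint,
    train,
)


class TestFocalLoss:
    def test_reduces_to_cross_entropy_at_half(self):
        assert focal_loss(0.5, alpha=1.0, gamma=0.0) == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_computed_value(self):
        # 0.25 * 0.1^2 * (-ln 0.9) = 2.634e-4
        expected = 0.25 * 0.1**2 * -np.log(0.9)
        assert focal_loss(0.9, alpha=0.25, gamma=2.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_to_zero(self):
        ps = np.linspace(0.05, 1.0, 50)
        losses = [focal_loss(p, 0.25, 2.0) for p in ps]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert losses[-1] == pytest.approx(0.0, abs=1e-12)
        assert min(losses) >= 0.0

    @given(st.floats(1e-6, 1.0 - 1e-9))
    def test_gamma_zero_alpha_one_is_bce(self, p):
        assert focal_loss(p, alpha=1.0, gamma=0.0) == pytest.approx(-np.log(p), abs=1e-12)


class TestCosineSchedule:
    def test_endpoints_and_midpoint(self):
        assert cosine_lr(0, 50, 0.03) == pytest.approx(0.03)
        assert cosine_lr(50, 50, 0.03) == pytest.approx(0.0, abs=1e-15)
        assert cosine_lr(25, 50, 0.03) == pytest.approx(0.015)

    def test_out_of_range_epoch_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(51, 50, 0.03)
        with pytest.raises(ValueError):
            cosine_lr(0, 0, 0.03)

    def test_monotone_decay(self):
        lrs = [cosine_lr(t, 50, 0.03) for t in range(51)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


class TestBuild:
    def test_tiny_forward_in_unit_range(self):
        cfg = ClassifierConfig(backbone="tiny", input_size=(64, 64), seed=0)
        clf = build_classifier(cfg)
        out = clf.forward(np.random.default_rng(0).random((3, 1, 64, 64)))
        assert out.shape == (3, 2)
        assert (out >= 0).all() and (out <= 1).all()

    def test_resnet18_depth(self):
        cfg = ClassifierConfig(backbone="resnet18", input_size=(64, 64), seed=0)
        clf = build_classifier(cfg)
        assert clf.backbone_depth == 18

    def test_identical_seed_identical_weights(self):
        cfg = ClassifierConfig(backbone="tiny", input_size=(64, 64), seed=5)
        a, b = build_classifier(cfg), build_classifier(cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(backbone="vgg")

    def test_pretrained_unavailable(self):
        with pytest.raises(ValueError, match="pretrained"):
            build_classifier(ClassifierConfig(backbone="resnet18", pretrained=True))

    def test_invalid_hyperparameters_rejected(self):
        for kw in ({"batch_size": 0}, {"initial_lr": 0.0}, {"focal_gamma": -1},
                   {"focal_alpha": 0.0}, {"focal_alpha": 1.5}, {"output_mode": "softmax"}):
            with pytest.raises(ValueError):
                ClassifierConfig(**kw)


class TestPredict:
    def test_zeroed_final_layer_scores_half(self):
        cfg = ClassifierConfig(backbone="tiny", input_size=(64, 64), seed=0)
        clf = build_classifier(cfg)
        final = clf.head.layers[-1]
        final.weight.value[...] = 0.0
        final.bias.value[...] = 0.0
        score = predict_slice(clf, np.zeros((64, 64)))
        assert score == pytest.approx(0.5)

    def test_size_mismatch_rejected(self):
        clf = build_classifier(ClassifierConfig(backbone="tiny", input_size=(64, 64)))
        with pytest.raises(ValueError):
            predict_slice(clf, np.zeros((32, 32)))

    def test_single_logit_mode_scores(self):
        cfg = ClassifierConfig(
            backbone="tiny", input_size=(64, 64), output_mode="single_logit", seed=1
        )
        clf = build_classifier(cfg)
        p = clf.predict_proba(np.random.default_rng(1).random((2, 64, 64)))
        assert p.shape == (2,)
        assert ((p >= 0) & (p <= 1)).all()


def _toy_sets(rng, n=24, size=16):
    """Trivially separable toy data: bright blob present or absent."""
    x = rng.random((n, size, size)) * 0.2
    y = rng.integers(0, 2, size=n)
    for i in np.flatnonzero(y):
        x[i, 6:10, 6:10] = 0.95
    return x, y


class TestTraining:
    def test_history_contract_and_schedule(self):
        rng = np.random.default_rng(0)
        x, y = _toy_sets(rng)
        cfg = ClassifierConfig(
            backbone="tiny", input_size=(16, 16), epochs=3, seed=0, augment=False
        )
        clf, history = train((x, y), (x, y), cfg)
        assert len(history) == 3
        expected = [cosine_lr(t, 3, cfg.initial_lr) for t in range(3)]
        np.testing.assert_allclose(history["lr"], expected)
        assert {"train_loss", "train_accuracy", "val_accuracy"} <= set(history.columns)

    def test_single_class_warns_but_trains(self):
        rng = np.random.default_rng(1)
        x = rng.random((8, 16, 16))
        cfg = ClassifierConfig(backbone="tiny", input_size=(16, 16), epochs=1, seed=0)
        with pytest.warns(UserWarning, match="single class"):
            train((x, np.zeros(8, dtype=int)), None, cfg)

    def test_learns_separable_toy_data(self):
        rng = np.random.default_rng(2)
        x, y = _toy_sets(rng, n=40)
        cfg = ClassifierConfig(
            backbone="tiny", input_size=(16, 16), epochs=10, seed=0, augment=False
        )
        clf, history = train((x, y), None, cfg)
        assert (clf.predict(x) == y).mean() >= 0.9

    def test_training_deterministic(self):
        rng = np.random.default_rng(3)
        x, y = _toy_sets(rng, n=16)
        cfg = ClassifierConfig(backbone="tiny", input_size=(16, 16), epochs=2, seed=4)
        a, _ = train((x, y), None, cfg)
        b, _ = train((x, y), None, cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_checkpoint_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        x, y = _toy_sets(rng, n=16)
        cfg = ClassifierConfig(backbone="tiny", input_size=(16, 16), epochs=2, seed=5)
        clf, history = train((x, y), None, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(clf, path, history=history)
        back = load_checkpoint(path)
        np.testing.assert_allclose(back.predict_proba(x), clf.predict_proba(x), atol=1e-12)


class TestBackprop:
    def test_numerical_gradients(self):
        """End-to-end analytic gradients match central differences."""
        rng = np.random.default_rng(0)
        net = nn.Sequential(
            nn.Conv2d(1, 3, 3, padding=1, rng=rng),
            nn.BatchNorm2d(3),
            nn.ReLU(),
            nn.MaxPool2d(2),
            nn.ResidualBlock(3, 4, stride=2, rng=rng),
            nn.GlobalAvgPool2d(),
            nn.Dense(4, 2, rng=rng),
        )
        x = rng.normal(size=(2, 1, 8, 8))
        w = rng.normal(size=(2, 2))

        def loss():
            return float((net.forward(x.copy(), train=True) * w).sum())

        net.forward(x.copy(), train=True)
        for p in net.parameters():
            p.grad[...] = 0.0
        gx = net.backward(w.copy())

        def num_grad(arr, eps=1e-6):
            g = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + eps
                fp = loss()
                arr[i] = old - eps
                fm = loss()
                arr[i] = old
                g[i] = (fp - fm) / (2 * eps)
            return g

        np.testing.assert_allclose(gx, num_grad(x), atol=1e-7)
        for p in net.parameters():
            ng = num_grad(p.value)
            scale = max(np.abs(ng).max(), 1e-3)  # conv biases before BN have ~0 gradient
            assert np.abs(p.grad - ng).max() / scale < 1e-5
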