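"""Slice classifier: architecture, focal loss, cosine schedule, training.

The classifier is a residual-style CNN over single-channel ROI patches with a
small fully connected head (one hidden layer) and sigmoid output nodes.  Two
output modes exist: ``two_node`` (one sigmoid node per class, as in the
original network description) and ``single_logit`` (one sigmoid node for the
positive class); both are trained with per-node focal loss.

Backbones:

* ``tiny`` — three conv/BN/ReLU/pool blocks; trains on one CPU in minutes and
  is the default for the bundled phantom experiments;
* ``resnet18`` / ``resnet50`` — five-stage residual networks (7x7/64 first
  stage, then 3x3 basic blocks; bottleneck 1x1-3x3-1x1 blocks from the third
  stage for resnet50).

ImageNet transfer learning is not available in this package (no weight
source is bundled); ``pretrained=True`` raises.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .preprocess import augment as _augment

BACKBONES = ("tiny", "resnet18", "resnet50")


@dataclasses.dataclass
class ClassifierConfig:
    backbone: str = "tiny"
    pretrained: bool = False
    input_size: tuple[int, int] = (224, 224)
    output_mode: str = "two_node"  # or "single_logit"
    hidden_units: int = 32
    batch_size: int = 32
    initial_lr: float = 0.03
    lr_min: float = 0.0
    momentum: float = 0.9
    epochs: int = 50
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    prob_epsilon: float = 1e-7
    augment: bool = True
    rotation_range: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if self.output_mode not in ("two_node", "single_logit"):
            raise ValueError("output_mode must be 'two_node' or 'single_logit'")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not 0 < self.focal_alpha <= 1:
            raise ValueError("focal_alpha must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def n_outputs(self) -> int:
        return 2 if self.output_mode == "two_node" else 1


def focal_loss(p, alpha: float = 0.25, gamma: float = 2.0, eps: float = 1e-7) -> float:
    """Focal loss -alpha (1-p)^gamma ln(p) of the true-class probability ``p``.

    ``p`` may be a scalar or array; the mean over entries is returned (the
    batch loss is the mean over samples).  With gamma=0 and alpha=1 this is
    the binary cross-entropy.
    """
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0)
    return float(np.mean(-alpha * (1.0 - p) ** gamma * np.log(p)))


def _focal_grad(p: np.ndarray, alpha: float, gamma: float, eps: float) -> np.ndarray:
    """d/dp of -alpha (1-p)^gamma ln(p), elementwise."""
    p = np.clip(p, eps, 1.0 - 1e-12)
    q = 1.0 - p
    if gamma == 0.0:
        return -alpha / p
    return alpha * gamma * q ** (gamma - 1.0) * np.log(p) - alpha * q**gamma / p


def cosine_lr(t: int, total: int, lr0: float, lr_min: float = 0.0) -> float:
    """Cosine-decay learning rate at epoch ``t`` of ``total``."""
    if total < 1:
        raise ValueError("total epochs must be >= 1")
    if not 0 <= t <= total:
        raise ValueError(f"epoch {t} outside [0, {total}]")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * t / total))


class Classifier:
    """A trainable slice classifier: conv ``features`` + dense ``head`` +
    sigmoid output, with the split exposed for Grad-CAM."""

    def __init__(self, config: ClassifierConfig, features: nn.Sequential, head: nn.Sequential):
        self.config = config
        self.features = features
        self.head = head
        self.out_act = nn.Sigmoid()
        # per-dataset standardization, fitted on the training set
        self.input_mean = 0.0
        self.input_std = 1.0

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.input_mean) / self.input_std

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.out_act.forward(self.head.forward(self.features.forward(x, train), train), train)

    def parameters(self) -> list[nn.Parameter]:
        return self.features.parameters() + self.head.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    @property
    def n_weighted_layers(self) -> int:
        """Main-path convolution count plus dense layers in the head."""
        n = 0
        stack = list(self.features.layers) + list(self.head.layers)
        while stack:
            layer = stack.pop()
            if isinstance(layer, (nn.Conv2d, nn.Dense)):
                n += 1
            elif isinstance(layer, nn.Sequential):
                stack.extend(layer.layers)
            elif isinstance(layer, (nn.ResidualBlock, nn.BottleneckBlock)):
                stack.extend(layer.main.layers)  # projection shortcuts not counted
        return n

    @property
    def backbone_depth(self) -> int:
        """Canonical depth: main-path convolutions plus the output layer."""
        return self.n_weighted_layers - 1  # hidden dense layer not counted

    # ------------------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[2:] != tuple(self.config.input_size):
            raise ValueError(
                f"patch size {x.shape[2:]} does not match configured input {self.config.input_size}"
            )
        return self.normalize(x)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Probability of the BME-positive class per patch."""
        out = self.forward(self._check_input(patches), train=False)
        return out[:, 1] if self.config.n_outputs == 2 else out[:, 0]

    def predict(self, patches: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(patches) > threshold).astype(int)


def predict_slice(classifier: Classifier, patch: np.ndarray) -> float:
    """Score one ROI patch; probability in [0, 1] of BME-positive."""
    return float(classifier.predict_proba(np.asarray(patch)[None])[0])


def build_classifier(config: ClassifierConfig) -> Classifier:
    """Instantiate the configured backbone with seeded initialization."""
    if config.pretrained:
        raise ValueError(
            "pretrained backbones are not available in this package: no weight "
            "source is bundled; train from random initialization instead"
        )
    rng = np.random.default_rng(config.seed)
    if config.backbone == "tiny":
        features = nn.Sequential(
            nn.Conv2d(1, 8, 3, padding=1, rng=rng),
            nn.BatchNorm2d(8),
            nn.ReLU(),
            nn.MaxPool2d(2),
            nn.Conv2d(8, 16, 3, padding=1, rng=rng),
            nn.BatchNorm2d(16),
            nn.ReLU(),
            nn.MaxPool2d(2),
            nn.Conv2d(16, 32, 3, padding=1, rng=rng),
            nn.BatchNorm2d(32),
            nn.ReLU(),
            nn.MaxPool2d(2),
        )
        head_entry: list[nn.Module] = [nn.Flatten()]
    elif config.backbone == "resnet18":
        features = nn.Sequential(
            nn.Conv2d(1, 64, 7, stride=2, padding=3, rng=rng),
            nn.BatchNorm2d(64),
            nn.ReLU(),
            nn.MaxPool2d(3, stride=2, padding=1),
            nn.ResidualBlock(64, 64, rng=rng),
            nn.ResidualBlock(64, 64, rng=rng),
            nn.ResidualBlock(64, 128, stride=2, rng=rng),
            nn.ResidualBlock(128, 128, rng=rng),
            nn.ResidualBlock(128, 256, stride=2, rng=rng),
            nn.ResidualBlock(256, 256, rng=rng),
            nn.ResidualBlock(256, 512, stride=2, rng=rng),
            nn.ResidualBlock(512, 512, rng=rng),
        )
        head_entry = [nn.GlobalAvgPool2d()]
    else:  # resnet50: basic blocks in stage 2, bottlenecks from stage 3
        layers: list[nn.Module] = [
            nn.Conv2d(1, 64, 7, stride=2, padding=3, rng=rng),
            nn.BatchNorm2d(64),
            nn.ReLU(),
            nn.MaxPool2d(3, stride=2, padding=1),
            nn.ResidualBlock(64, 64, rng=rng),
            nn.ResidualBlock(64, 64, rng=rng),
            nn.ResidualBlock(64, 64, rng=rng),
        ]
        cin = 64
        for mid, count, stride in ((128, 4, 2), (256, 6, 2), (512, 3, 2)):
            for i in range(count):
                layers.append(nn.BottleneckBlock(cin, mid, stride=stride if i == 0 else 1, rng=rng))
                cin = mid * nn.BottleneckBlock.expansion
        features = nn.Sequential(*layers)
        head_entry = [nn.GlobalAvgPool2d()]

    # probe the feature map to size the dense head
    probe = np.zeros((1, 1, *config.input_size))
    feat = features.forward(probe, train=False)
    entry = nn.Sequential(*head_entry)
    n_in = entry.forward(feat, train=False).shape[1]
    head = nn.Sequential(
        *head_entry,
        nn.Dense(n_in, config.hidden_units, rng=rng),
        nn.ReLU(),
        nn.Dense(config.hidden_units, config.n_outputs, rng=rng),
    )
    return Classifier(config, features, head)


def _targets(y: np.ndarray, n_outputs: int) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if n_outputs == 1:
        return y[:, None].astype(float)
    return np.stack([1 - y, y], axis=1).astype(float)


def _batch_loss_and_grad(out: np.ndarray, targets: np.ndarray, config: ClassifierConfig):
    """Mean per-node focal loss over a batch and its gradient w.r.t. the
    sigmoid outputs."""
    eps = config.prob_epsilon
    p_true = np.where(targets == 1.0, out, 1.0 - out)
    loss = focal_loss(p_true, config.focal_alpha, config.focal_gamma, eps)
    dldp = _focal_grad(p_true, config.focal_alpha, config.focal_gamma, eps)
    grad = np.where(targets == 1.0, dldp, -dldp) / p_true.size
    return loss, grad


def train(
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None,
    config: ClassifierConfig,
) -> tuple[Classifier, pd.DataFrame]:
    """Train a classifier; returns (classifier, per-epoch history).

    ``train_set`` / ``val_set`` are ``(X, y)`` with ``X`` of shape
    ``(n, H, W)`` or ``(n, 1, H, W)`` in [0,1] and binary ``y``.  Training is
    deterministic for a fixed config seed under single-threaded execution:
    shuffling, augmentation and initialization all derive from it.
    """
    x_train, y_train = train_set
    x_train = np.asarray(x_train, dtype=np.float64)
    if x_train.ndim == 3:
        x_train = x_train[:, None]
    y_train = np.asarray(y_train).astype(int)
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    if len(np.unique(y_train)) < 2:
        warnings.warn("training set contains a single class; proceeding (focal loss)")

    clf = build_classifier(config)
    clf.input_mean = float(x_train.mean())
    sd = float(x_train.std())
    clf.input_std = sd if sd > 1e-8 else 1.0
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.SGD(clf.parameters(), lr=config.initial_lr, momentum=config.momentum)

    history = []
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.initial_lr, config.lr_min)
        opt.lr = lr
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx]
            if config.augment:
                xb = np.stack(
                    [_augment(im[0], rng, rotation_range=config.rotation_range)[None] for im in xb]
                )
            tb = _targets(y_train[idx], config.n_outputs)
            out = clf.forward(clf.normalize(xb), train=True)
            loss, gout = _batch_loss_and_grad(out, tb, config)
            clf.zero_grad()
            gz = clf.out_act.backward(gout)
            clf.features.backward(clf.head.backward(gz))
            opt.step()
            losses.append(loss)
            p_pos = out[:, 1] if config.n_outputs == 2 else out[:, 0]
            correct += int(((p_pos > 0.5).astype(int) == y_train[idx]).sum())
        row = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": correct / n,
        }
        if val_set is not None and len(val_set[0]):
            xv = np.asarray(val_set[0], dtype=np.float64)
            if xv.ndim == 3:
                xv = xv[:, None]
            yv = np.asarray(val_set[1]).astype(int)
            row["val_accuracy"] = float((clf.predict(xv) == yv).mean())
        history.append(row)
    return clf, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(clf: Classifier, path: str | Path, history: pd.DataFrame | None = None) -> None:
    path = Path(path)
    arrays = {f"param_{i}": p.value for i, p in enumerate(clf.parameters())}
    bn_state = {}
    i = 0
    for layer in _iter_layers(clf):
        if isinstance(layer, nn.BatchNorm2d):
            bn_state[f"bn_{i}_mean"] = layer.running_mean
            bn_state[f"bn_{i}_var"] = layer.running_var
            i += 1
    meta = json.dumps(dataclasses.asdict(clf.config))
    np.savez(
        path,
        __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
        __norm__=np.array([clf.input_mean, clf.input_std]),
        **arrays,
        **bn_state,
    )
    if history is not None:
        history.to_csv(path.with_suffix(".history.csv"), index=False)


def load_checkpoint(path: str | Path) -> Classifier:
    data = np.load(Path(path) if str(path).endswith(".npz") else f"{path}")
    meta = json.loads(bytes(data["__config__"]).decode())
    meta["input_size"] = tuple(meta["input_size"])
    config = ClassifierConfig(**meta)
    clf = build_classifier(config)
    if "__norm__" in data:
        clf.input_mean, clf.input_std = (float(v) for v in data["__norm__"])
    for i, p in enumerate(clf.parameters()):
        p.value[...] = data[f"param_{i}"]
    i = 0
    for layer in _iter_layers(clf):
        if isinstance(layer, nn.BatchNorm2d):
            layer.running_mean[...] = data[f"bn_{i}_mean"]
            layer.running_var[...] = data[f"bn_{i}_var"]
            i += 1
    return clf


def _iter_layers(clf: Classifier):
    stack = list(clf.features.layers) + list(clf.head.layers)
    while stack:
        layer = stack.pop(0)
        yield layer
        if isinstance(layer, nn.Sequential):
            stack = list(layer.layers) + stack
        elif isinstance(layer, (nn.ResidualBlock, nn.BottleneckBlock)):
            inner = list(layer.main.layers)
            if layer.shortcut:
                inner += list(layer.shortcut.layers)
            stack = inner + stack
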