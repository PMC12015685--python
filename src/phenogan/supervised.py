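"""Fully supervised convolutional baselines.

Two models: (i) a custom 6-stage CNN trained from scratch with binary
cross-entropy, consuming the identical 72x72 [-1, 1] pipeline as the GAN
discriminator so the learning strategy is the only difference between them;
(ii) transfer learning with a deep residual ("bottleneck") network at
128x128 input whose new binary head plus top few backbone layers are
fine-tuned while all deeper layers stay frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .chipio import UNLABELED, ChipDataset
from .esgan import prepare_inputs

_EPS = 1e-7


@dataclass
class CnnSpec:
    """6 conv stages (widths 32,32,64,64,128,128), each conv+BN+ReLU+pool;
    40% dropout after stages 2, 4, 6; dense 128 + BN + 50% dropout; sigmoid."""

    input_size: int = 72
    channel_widths: tuple[int, ...] = (32, 32, 64, 64, 128, 128)
    dropout_stages: tuple[int, ...] = (2, 4, 6)       # 1-based stage indices
    conv_dropout: float = 0.4
    fc_width: int = 128
    fc_dropout: float = 0.5

    def feature_side(self) -> int:
        side = self.input_size
        for _ in self.channel_widths:
            side = max(side // 2, 1)
        return side


@dataclass
class TransferSpec:
    """Residual backbone + new binary head; ``n_trainable_layers`` counts the
    top weight-bearing backbone layers that stay trainable (default 5)."""

    input_size: int = 128
    stage_blocks: tuple[int, ...] = (3, 4, 6, 3)      # 50-layer bottleneck net
    base_width: int = 64
    n_trainable_layers: int = 5


@dataclass
class SupervisedTrainConfig:
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 20
    seed: int = 0


class BinaryConvNet:
    """A Sequential ending in a scalar sigmoid, plus its Adam state."""

    def __init__(self, net: nn.Sequential, input_size: int, seed: int,
                 lr: float = 1e-4) -> None:
        self.net = net
        self.input_size = input_size
        self.opt = nn.Adam(net, lr=lr)
        self.seed = seed

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValueError(
                f"expected (N, {self.input_size}, {self.input_size}, 3) input")
        return self.net.forward(x, train, rng)[:, 0]

    def predict_scores(self, chips: ChipDataset | np.ndarray) -> np.ndarray:
        if isinstance(chips, ChipDataset):
            x, _ = prepare_inputs(chips, self.input_size)
        else:
            x = np.asarray(chips, dtype=np.float32)
        out = [self.forward(x[i:i + 256]) for i in range(0, len(x), 256)]
        return np.concatenate(out)


def build_custom_cnn(spec: CnnSpec | None = None, seed: int = 0,
                     lr: float = 1e-3) -> BinaryConvNet:
    spec = spec or CnnSpec()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = 3
    for stage, c_out in enumerate(spec.channel_widths, start=1):
        layers += [nn.Conv2D(c_in, c_out, rng=rng), nn.BatchNorm(c_out),
                   nn.ReLU(), nn.MaxPool2()]
        if stage in spec.dropout_stages:
            layers.append(nn.Dropout(spec.conv_dropout))
        c_in = c_out
    flat = spec.feature_side() ** 2 * spec.channel_widths[-1]
    layers += [nn.Flatten(),
               nn.Dense(flat, spec.fc_width, rng=rng), nn.BatchNorm(spec.fc_width),
               nn.ReLU(), nn.Dropout(spec.fc_dropout),
               nn.Dense(spec.fc_width, 1, rng=rng, init="glorot"), nn.Sigmoid()]
    return BinaryConvNet(nn.Sequential(layers), spec.input_size, seed, lr)


def build_residual_backbone(spec: TransferSpec, rng: np.random.Generator
                            ) -> tuple[list[nn.Layer], int]:
    """Stem + bottleneck stages + global average pool; returns (layers,
    feature width)."""
    w = spec.base_width
    layers: list[nn.Layer] = [nn.Conv2D(3, w, kernel=7, stride=2, rng=rng),
                              nn.BatchNorm(w), nn.ReLU(), nn.MaxPool2()]
    c_in = w
    for stage, blocks in enumerate(spec.stage_blocks):
        c_mid = w * 2 ** stage
        c_out = c_mid * 4
        for b in range(blocks):
            stride = 2 if (b == 0 and stage > 0) else 1
            layers.append(nn.ResidualBlock(c_in, c_mid, c_out, stride, rng=rng))
            c_in = c_out
    layers.append(nn.GlobalAvgPool())
    return layers, c_in


def build_transfer_model(spec: TransferSpec | None = None, seed: int = 0,
                         lr: float = 1e-3,
                         backbone_weights: str | None = None) -> BinaryConvNet:
    """Residual classifier with frozen lower backbone.

    ``backbone_weights`` may name an ``.npz`` of pretrained parameters in
    ``nn.get_state`` layout; without it the backbone starts from random
    initialisation (no natural-image pretraining is bundled), which keeps
    the freezing/fine-tuning mechanics exercisable.
    """
    spec = spec or TransferSpec()
    rng = np.random.default_rng(seed)
    backbone, feat = build_residual_backbone(spec, rng)
    backbone_net = nn.Sequential(backbone)
    if backbone_weights is not None:
        nn.set_state(backbone_net, dict(np.load(backbone_weights)))
    # freeze everything except the top n weight-bearing backbone layers
    weighted = [l for l in nn.walk_layers(backbone_net) if l.params]
    keep = set(id(l) for l in weighted[-spec.n_trainable_layers:]) \
        if spec.n_trainable_layers > 0 else set()
    for layer in nn.walk_layers(backbone_net):
        if id(layer) not in keep:
            layer.trainable = False
            if isinstance(layer, nn.BatchNorm):
                layer.frozen = True        # frozen BN uses running statistics
    head: list[nn.Layer] = [nn.Dense(feat, 1, rng=rng, init="glorot"),
                            nn.Sigmoid()]
    return BinaryConvNet(nn.Sequential(backbone + head), spec.input_size, seed, lr)


def finetune_pretrained(spec: TransferSpec, train_ds: ChipDataset,
                        val: ChipDataset, cfg: SupervisedTrainConfig,
                        backbone_weights: str | None = None
                        ) -> tuple[BinaryConvNet, pd.DataFrame]:
    model = build_transfer_model(spec, seed=cfg.seed, backbone_weights=backbone_weights)
    return train_supervised(model, train_ds, val, cfg)


def _bce(scores: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(scores.astype(np.float64), _EPS, 1.0 - _EPS)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


def train_supervised(model: BinaryConvNet, labeled_train: ChipDataset,
                     val: ChipDataset, cfg: SupervisedTrainConfig | None = None
                     ) -> tuple[BinaryConvNet, pd.DataFrame]:
    """Binary cross-entropy minimisation with Adam and early stopping on
    validation OA; returns the best model and per-epoch history."""
    cfg = cfg or SupervisedTrainConfig()
    if len(labeled_train) == 0:
        raise ValueError("training set is empty")
    if np.any(labeled_train.labels == UNLABELED):
        raise ValueError("supervised training refuses chips with masked labels")
    if len(np.unique(labeled_train.labels)) < 2:
        raise ValueError("training set contains a single class; "
                         "a binary classifier cannot be fit")
    if len(val) == 0 or not val.all_labeled:
        raise ValueError("validation set must be non-empty and fully labeled")
    x, y = prepare_inputs(labeled_train, model.input_size)
    vx, vy = prepare_inputs(val, model.input_size)
    stream = np.random.default_rng(cfg.seed)
    n = len(x)
    history: list[dict] = []
    best_oa, best_epoch, best_state = -1.0, -1, None
    for epoch in range(cfg.max_epochs):
        order = stream.permutation(n)
        total = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            scores = model.forward(x[idx], train=True, rng=stream)
            yb = y[idx].astype(np.float64)
            total += _bce(scores, yb)
            n_batches += 1
            p = np.clip(scores.astype(np.float64), _EPS, 1.0 - _EPS)
            dscore = ((p - yb) / (p * (1 - p)) / len(idx)).astype(np.float32)
            model.net.backward(dscore[:, None])
            model.opt.step()
            model.opt.zero_grad()
        val_scores = model.predict_scores(vx)
        val_oa = float(np.mean((val_scores > 0.5).astype(int) == vy))
        history.append({"epoch": epoch, "loss": total / n_batches,
                        "val_oa": val_oa})
        if val_oa >= best_oa:
            # snapshot the most recent equally-good model; only strict
            # improvement resets the early-stopping clock
            if val_oa > best_oa:
                best_epoch = epoch
            best_oa = val_oa
            best_state = nn.get_state(model.net)
        if epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        nn.set_state(model.net, best_state)
    return model, pd.DataFrame(history)
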