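"""Semi-supervised GAN for heading classification (the ESGAN strategy).

One convolutional backbone feeds two discriminator heads that share every
backbone weight: a supervised 2-class softmax head (heading / not heading)
and an unsupervised real-vs-fake head obtained *from the same logits* via
the normalised-sum-of-exponentials activation D(x) = Z/(Z+1) with
Z = sum_k exp(l_k) — i.e. sigmoid(logsumexp(l)).  A generated image plays
the implicit K+1-th ("fake") class.  Because both heads literally read the
same parameters, every update through either objective moves the shared
representation, which is how tens of labels plus thousands of unlabeled
chips suffice.

Each training step runs, in order:
  1a. supervised cross-entropy update on the labeled half-batch;
  1b. unsupervised update pushing D(x) -> 1 on real unlabeled chips;
  1c. unsupervised update pushing D(G(z)) -> 0 on freshly generated fakes;
  2.  generator update (discriminator frozen) minimising the feature-matching
      loss || mean f(real) - mean f(fake) ||^2 over post-flatten, pre-dropout
      backbone features.  A non-saturating adversarial generator loss is
      available behind ``TrainConfig.generator_loss``.

Both submodels use Adam at learning rate 1e-4.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp, softmax

from . import nn
from .chipio import (UNLABELED, ChipDataset, ImageChip, normalize_for_gan,
                     resize_chip)

_EPS = 1e-7  # floor inside every log


class EsganTrainingError(RuntimeError):
    """Raised when a loss goes non-finite; carries the diagnostic state."""

    def __init__(self, message: str, losses: dict | None = None) -> None:
        super().__init__(message)
        self.losses = losses or {}


@dataclass
class GeneratorSpec:
    """Latent vector -> dense reshape -> 2 stride-2 transposed convolutions."""

    latent_dim: int = 100
    image_size: int = 72
    reshape_channels: int = 128
    mid_channels: int = 64

    def __post_init__(self) -> None:
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4 "
                             "(two 2x upscaling stages)")

    @property
    def reshape_side(self) -> int:
        return self.image_size // 4


@dataclass
class DiscriminatorSpec:
    """4 conv(3x3)+LeakyReLU+maxpool(2) stages, flatten, 40% dropout, then a
    2-class dense head; channel widths default to (32, 64, 128, 128)."""

    image_size: int = 72
    channel_widths: tuple[int, ...] = (32, 64, 128, 128)
    dropout: float = 0.4
    leaky_slope: float = 0.2
    n_classes: int = 2

    @property
    def feature_dim(self) -> int:
        side = self.image_size
        for _ in self.channel_widths:
            side = max(side // 2, 1)
        return side * side * self.channel_widths[-1]


@dataclass
class TrainConfig:
    batch_size: int = 64              # half labeled, half unlabeled
    max_epochs: int = 1000
    patience: int = 50                # epochs without val-OA improvement
    steps_per_epoch: int | None = None
    seed: int = 0
    use_unlabeled: bool = True        # False = ablation: phases 1b/1c/2 off
    generator_loss: str = "feature_matching"   # or "non_saturating"

    def __post_init__(self) -> None:
        if self.batch_size % 2 != 0:
            raise ValueError("batch_size must be even (balanced halves)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.generator_loss not in ("feature_matching", "non_saturating"):
            raise ValueError("unknown generator_loss")


class EsganModel:
    """Generator + shared-backbone dual-head discriminator + Adam states."""

    def __init__(self, gen_spec: GeneratorSpec | None = None,
                 disc_spec: DiscriminatorSpec | None = None,
                 seed: int = 0, lr: float = 1e-4) -> None:
        self.gen_spec = gen_spec or GeneratorSpec()
        self.disc_spec = disc_spec or DiscriminatorSpec(
            image_size=self.gen_spec.image_size)
        if self.gen_spec.image_size != self.disc_spec.image_size:
            raise ValueError("generator and discriminator image sizes differ")
        rng = np.random.default_rng(seed)
        gs, ds = self.gen_spec, self.disc_spec
        side = gs.reshape_side
        self.generator = nn.Sequential([
            nn.Dense(gs.latent_dim, side * side * gs.reshape_channels, rng=rng),
            nn.LeakyReLU(ds.leaky_slope),
            nn.Reshape((side, side, gs.reshape_channels)),
            nn.ConvTranspose2D(gs.reshape_channels, gs.mid_channels, rng=rng),
            nn.LeakyReLU(ds.leaky_slope),
            nn.ConvTranspose2D(gs.mid_channels, 3, rng=rng),
            nn.Tanh(),
        ])
        layers: list[nn.Layer] = []
        c_in = 3
        for c_out in ds.channel_widths:
            layers += [nn.Conv2D(c_in, c_out, rng=rng),
                       nn.LeakyReLU(ds.leaky_slope), nn.MaxPool2()]
            c_in = c_out
        layers.append(nn.Flatten())
        self._backbone_end = len(layers)          # features = output of Flatten
        layers += [nn.Dropout(ds.dropout),
                   nn.Dense(ds.feature_dim, ds.n_classes, rng=rng, init="glorot")]
        self.discriminator = nn.Sequential(layers)
        self.lr = lr
        self.opt_g = nn.Adam(self.generator, lr=lr)
        self.opt_d = nn.Adam(self.discriminator, lr=lr)
        self.step_count = 0

    # -- forward passes ----------------------------------------------------
    @property
    def image_size(self) -> int:
        return self.gen_spec.image_size

    def disc_logits(self, x: np.ndarray, train: bool = False,
                    rng: np.random.Generator | None = None) -> np.ndarray:
        return self.discriminator.forward(x.astype(np.float32), train, rng)

    def features(self, x: np.ndarray) -> np.ndarray:
        """Backbone features: post-flatten, pre-dropout."""
        h = x.astype(np.float32)
        for layer in self.discriminator.layers[:self._backbone_end]:
            h = layer.forward(h, False, None)
        return h

    def _backbone_backward(self, dfeat: np.ndarray) -> np.ndarray:
        dy = dfeat
        for layer in reversed(self.discriminator.layers[:self._backbone_end]):
            dy = layer.backward(dy)
        return dy

    def generate(self, z: np.ndarray) -> np.ndarray:
        return self.generator.forward(z.astype(np.float32), True, None)

    def zero_grads(self) -> None:
        self.opt_d.zero_grad()
        self.opt_g.zero_grad()

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        blob = {f"g__{k}": v for k, v in nn.get_state(self.generator).items()}
        blob |= {f"d__{k}": v for k, v in nn.get_state(self.discriminator).items()}
        for tag, opt in (("og", self.opt_g), ("od", self.opt_d)):
            st = opt.state()
            blob |= {f"{tag}_m__{k}": v for k, v in st["m"].items()}
            blob |= {f"{tag}_v__{k}": v for k, v in st["v"].items()}
            blob[f"{tag}_t"] = np.array(st["t"])
        blob["step_count"] = np.array(self.step_count)
        blob["spec_json"] = np.frombuffer(json.dumps(
            {"gen": asdict(self.gen_spec),
             "disc": asdict(self.disc_spec), "lr": self.lr}).encode(), dtype=np.uint8)
        np.savez(path, **blob)

    @classmethod
    def load(cls, path: str | Path) -> "EsganModel":
        data = np.load(path)
        spec = json.loads(bytes(data["spec_json"]).decode())
        spec["gen"]["latent_dim"] = int(spec["gen"]["latent_dim"])
        model = cls(GeneratorSpec(**spec["gen"]),
                    DiscriminatorSpec(**{**spec["disc"],
                                         "channel_widths": tuple(spec["disc"]["channel_widths"])}),
                    lr=spec["lr"])
        nn.set_state(model.generator,
                     {k[3:]: data[k] for k in data.files if k.startswith("g__")})
        nn.set_state(model.discriminator,
                     {k[3:]: data[k] for k in data.files if k.startswith("d__")})
        for tag, opt in (("og", model.opt_g), ("od", model.opt_d)):
            opt.load_state({
                "t": int(data[f"{tag}_t"]),
                "m": {k[len(tag) + 4:]: data[k] for k in data.files
                      if k.startswith(f"{tag}_m__")},
                "v": {k[len(tag) + 4:]: data[k] for k in data.files
                      if k.startswith(f"{tag}_v__")}})
        model.step_count = int(data["step_count"])
        return model


# ---------------------------------------------------------------------------
# Losses and activations


def unsupervised_activation(logits: np.ndarray) -> np.ndarray:
    """Real-vs-fake probability from supervised-head logits.

    D(x) = Z/(Z+1) with Z = sum_k exp(logit_k); computed stably as
    sigmoid(logsumexp(logits)).  p(fake) = 1 - D(x).
    """
    logits = np.asarray(logits, dtype=np.float64)
    return expit(logsumexp(logits, axis=-1))


def supervised_loss(class_probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log probability of the true class."""
    probs = np.asarray(class_probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if np.any((labels < 0) | (labels >= probs.shape[-1])):
        raise ValueError("labels out of range for supervised loss")
    p_true = probs[np.arange(len(labels)), labels]
    return float(np.mean(-np.log(np.maximum(p_true, _EPS))))


def unsupervised_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """-E log D(x_real) - E log(1 - D(G(z))), with D the real-probability."""
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    real_term = float(np.mean(-np.log(np.maximum(d_real, _EPS))))
    fake_term = float(np.mean(-np.log(np.maximum(1.0 - d_fake, _EPS))))
    return real_term + fake_term


# ---------------------------------------------------------------------------
# Batch construction


def _draw_half(n_pool: int, half: int, stream: np.random.Generator) -> np.ndarray:
    """Indices for one half-batch: without replacement when the pool is large
    enough, with replacement otherwise (the tiny-labeled-pool case)."""
    if n_pool == 0:
        raise ValueError("cannot sample from an empty pool")
    if n_pool >= half:
        return stream.choice(n_pool, size=half, replace=False)
    return stream.integers(0, n_pool, size=half)


def _multiset_subset(ds: ChipDataset, indices: np.ndarray) -> ChipDataset:
    """Subset that tolerates repeated indices (with-replacement draws);
    repeat occurrences get '@k' suffixed ids to stay unique."""
    seen: dict[str, int] = {}
    ids = []
    for i in indices:
        base = ds.ids[int(i)]
        k = seen.get(base, 0)
        seen[base] = k + 1
        ids.append(base if k == 0 else f"{base}@{k}")
    prov = [ds.provenance[int(i)] for i in indices] if ds.provenance else None
    return ChipDataset(chips=[ds.chips[int(i)] for i in indices],
                       labels=ds.labels[np.asarray(indices, dtype=int)],
                       ids=ids, provenance=prov)


def sample_balanced_batch(labeled: ChipDataset, unlabeled: ChipDataset,
                          batch_size: int, stream: np.random.Generator
                          ) -> tuple[ChipDataset, ChipDataset]:
    """Exactly batch_size/2 labeled + batch_size/2 unlabeled chips."""
    if batch_size % 2 != 0:
        raise ValueError("batch_size must be even")
    half = batch_size // 2
    li = _draw_half(len(labeled), half, stream)
    ui = _draw_half(len(unlabeled), half, stream)
    return _multiset_subset(labeled, li), _multiset_subset(unlabeled, ui)


def prepare_inputs(ds: ChipDataset, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Resize chips to the network input size and map to [-1, 1]."""
    xs = []
    for chip in ds.chips:
        if chip.value_range == (0.0, 1.0):
            chip = normalize_for_gan(resize_chip(chip, size))
        elif chip.size != size:
            raise ValueError("chips already in [-1, 1] must match the input size")
        xs.append(chip.pixels)
    return np.stack(xs).astype(np.float32), ds.labels.copy()


# ---------------------------------------------------------------------------
# Training


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    return softmax(logits.astype(np.float64), axis=-1)


def generator_update(model: EsganModel, latents: np.ndarray,
                     real_batch: np.ndarray,
                     generator_loss: str = "feature_matching",
                     stream: np.random.Generator | None = None) -> float:
    """One generator Adam step with the discriminator frozen.

    The default loss is feature matching: the squared L2 distance between
    the batch-mean backbone features (post-flatten, pre-dropout) of the real
    and generated batches.  Discriminator parameters are bit-identical
    before and after (gradients flow through D but no D step is taken).
    """
    if len(latents) == 0 or len(real_batch) == 0:
        raise ValueError("generator update needs non-empty batches")
    D, G = model.discriminator, model.generator
    f_real = model.features(real_batch)             # before fake pass: caches
    fake = model.generate(latents)
    if generator_loss == "feature_matching":
        f_fake = model.features(fake)
        mu_r = f_real.mean(axis=0, dtype=np.float64)
        mu_f = f_fake.mean(axis=0, dtype=np.float64)
        loss = float(np.sum((mu_r - mu_f) ** 2))
        dfeat = np.broadcast_to(2.0 * (mu_f - mu_r) / len(f_fake),
                                f_fake.shape).astype(np.float32)
        dfake = model._backbone_backward(dfeat)
    elif generator_loss == "non_saturating":        # maximise log D(G(z))
        logits = D.forward(fake, True, stream)
        lse = logsumexp(logits.astype(np.float64), axis=-1)
        loss = float(np.mean(np.logaddexp(0.0, -lse)))
        dlse = -expit(-lse) / len(lse)
        dfake = D.backward((dlse[:, None] * _softmax_rows(logits)
                            ).astype(np.float32))
    else:
        raise ValueError(f"unknown generator loss {generator_loss!r}")
    G.backward(dfake)
    model.opt_g.step()                              # D untouched: no opt_d.step
    model.zero_grads()
    return loss


def train_step(model: EsganModel, labeled_x: np.ndarray, labeled_y: np.ndarray,
               unlabeled_x: np.ndarray | None, stream: np.random.Generator,
               generator_loss: str = "feature_matching") -> dict[str, float]:
    """One balanced adversarial step; returns the four loss values.

    ``labeled_x``/``unlabeled_x`` are (B/2, S, S, 3) arrays in [-1, 1].
    Pass ``unlabeled_x=None`` for the supervised-only ablation.  Generator
    parameters are untouched by phases 1a-1c and discriminator parameters
    are untouched by phase 2 (no optimiser step is taken for them).
    """
    if len(labeled_x) == 0:
        raise ValueError("empty labeled batch")
    if np.any(labeled_y == UNLABELED):
        raise ValueError("masked labels reached supervised training")
    D, G = model.discriminator, model.generator
    losses: dict[str, float] = {}

    # 1a) supervised head on labeled chips
    logits = D.forward(labeled_x, True, stream)
    probs = _softmax_rows(logits)
    losses["loss_sup"] = supervised_loss(probs, labeled_y)
    grad = probs.copy()
    grad[np.arange(len(labeled_y)), labeled_y.astype(int)] -= 1.0
    D.backward((grad / len(labeled_y)).astype(np.float32))
    model.opt_d.step()
    model.zero_grads()

    if unlabeled_x is not None:
        half_fake = len(unlabeled_x)
        # 1b) unsupervised head on real unlabeled chips: push D(x) -> 1
        logits = D.forward(unlabeled_x, True, stream)
        lse = logsumexp(logits.astype(np.float64), axis=-1)
        losses["loss_unsup_real"] = float(np.mean(np.logaddexp(0.0, -lse)))
        dlse = -expit(-lse) / len(lse)
        D.backward((dlse[:, None] * _softmax_rows(logits)).astype(np.float32))
        model.opt_d.step()
        model.zero_grads()

        # 1c) unsupervised head on fakes: push D(G(z)) -> 0
        z = stream.normal(size=(half_fake, model.gen_spec.latent_dim))
        fake = model.generate(z)                    # G params frozen: no G step
        logits = D.forward(fake, True, stream)
        lse = logsumexp(logits.astype(np.float64), axis=-1)
        losses["loss_unsup_fake"] = float(np.mean(np.logaddexp(0.0, lse)))
        dlse = expit(lse) / len(lse)
        D.backward((dlse[:, None] * _softmax_rows(logits)).astype(np.float32))
        model.opt_d.step()
        model.zero_grads()

        # 2) generator update with D frozen
        z = stream.normal(size=(half_fake, model.gen_spec.latent_dim))
        losses["loss_gen"] = generator_update(model, z, unlabeled_x,
                                              generator_loss, stream)
    else:
        losses["loss_unsup_real"] = math.nan
        losses["loss_unsup_fake"] = math.nan
        losses["loss_gen"] = math.nan

    finite = [v for v in losses.values() if not math.isnan(v)]
    if not all(math.isfinite(v) for v in finite):
        raise EsganTrainingError(
            f"non-finite loss at step {model.step_count}: {losses}", losses)
    model.step_count += 1
    return losses


def predict_heading(model: EsganModel, chips: ChipDataset | np.ndarray
                    ) -> np.ndarray:
    """Class probabilities (N, 2) from the supervised head, dropout-free.

    Input chips must be resized to the model's input size and lie in
    [-1, 1] (``prepare_inputs`` does both).  Hard labels follow by argmax,
    ties resolved toward class 0.
    """
    if isinstance(chips, ChipDataset):
        x, _ = prepare_inputs(chips, model.image_size)
    else:
        x = np.asarray(chips, dtype=np.float32)
    if x.ndim != 4 or x.shape[1] != model.image_size or x.shape[2] != model.image_size:
        raise ValueError(f"expected (N, {model.image_size}, {model.image_size}, 3) input")
    if x.min() < -1.0 - 1e-5 or x.max() > 1.0 + 1e-5:
        raise ValueError("inputs must be normalised to [-1, 1]")
    probs = []
    for start in range(0, len(x), 256):
        logits = model.disc_logits(x[start:start + 256], train=False)
        probs.append(_softmax_rows(logits))
    return np.concatenate(probs, axis=0)


def generate_samples(model: EsganModel, n: int, stream: np.random.Generator
                     ) -> list[ImageChip]:
    """Draw n fake chips (72x72x3 by default, values in [-1, 1])."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z = stream.normal(size=(n, model.gen_spec.latent_dim))
    out = model.generate(z)
    return [ImageChip(np.clip(img, -1.0, 1.0), (-1.0, 1.0)) for img in out]


def train(model: EsganModel, labeled: ChipDataset, unlabeled: ChipDataset,
          val: ChipDataset, cfg: TrainConfig | None = None
          ) -> tuple[EsganModel, pd.DataFrame]:
    """Epoch loop with balanced batches and early stopping on validation OA.

    Returns the model restored to its best-validation-OA parameters and a
    per-epoch history of the four losses plus validation OA.
    """
    cfg = cfg or TrainConfig()
    if len(val) == 0:
        raise ValueError("validation set must not be empty")
    if not val.all_labeled:
        raise ValueError("validation set must be fully labeled")
    lx, ly = prepare_inputs(labeled, model.image_size)
    if np.any(ly == UNLABELED):
        raise ValueError("labeled pool contains masked labels")
    use_unl = cfg.use_unlabeled and len(unlabeled) > 0
    ux = prepare_inputs(unlabeled, model.image_size)[0] if use_unl else None
    vx, vy = prepare_inputs(val, model.image_size)
    half = cfg.batch_size // 2
    n_pool = len(lx) + (len(ux) if use_unl else 0)
    steps = cfg.steps_per_epoch or max(1, math.ceil(n_pool / cfg.batch_size))
    stream = np.random.default_rng(cfg.seed)

    history: list[dict] = []
    best_oa, best_epoch = -1.0, -1
    best_state = None
    for epoch in range(cfg.max_epochs):
        sums = {"loss_sup": 0.0, "loss_unsup_real": 0.0,
                "loss_unsup_fake": 0.0, "loss_gen": 0.0}
        for _ in range(steps):
            li = _draw_half(len(lx), half, stream)
            ub = ux[_draw_half(len(ux), half, stream)] if use_unl else None
            losses = train_step(model, lx[li], ly[li], ub, stream,
                                cfg.generator_loss)
            for k in sums:
                sums[k] += losses[k]
        probs = predict_heading(model, vx)
        val_oa = float(np.mean(np.argmax(probs, axis=1) == vy))
        history.append({"epoch": epoch, **{k: v / steps for k, v in sums.items()},
                        "val_oa": val_oa})
        if val_oa >= best_oa:
            # snapshot the most recent equally-good model; only strict
            # improvement resets the early-stopping clock
            if val_oa > best_oa:
                best_epoch = epoch
            best_oa = val_oa
            best_state = (nn.get_state(model.generator),
                          nn.get_state(model.discriminator))
        if epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        nn.set_state(model.generator, best_state[0])
        nn.set_state(model.discriminator, best_state[1])
    return model, pd.DataFrame(history)
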