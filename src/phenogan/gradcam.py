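"""Gradient-weighted class activation maps over the supervised head.

For a query chip, the gradient of the target-class logit is taken with
respect to the activations of the last convolution stage; each feature
channel is weighted by the spatial mean of its gradient, channels are
summed, rectified, min-max scaled to 0-255 and bilinearly upsampled to the
chip size.  High values mark the regions driving the class decision (for
heading plants: the panicle speckles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .chipio import bilinear_resize
from .esgan import EsganModel


@dataclass
class ActivationMap:
    """0-255 integer activation grid at the query chip's spatial size."""

    values: np.ndarray
    target_class: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.min() < 0 or v.max() > 255:
            raise ValueError("activation map must be a 2-D grid in [0, 255]")
        self.values = v.astype(np.uint8)


def _conv_activation_index(layers: list[nn.Layer]) -> int:
    """Index of the activation following the last convolution layer (the
    'last convolutional feature maps' of the method)."""
    conv_idx = None
    for i, layer in enumerate(layers):
        if isinstance(layer, nn.Conv2D):
            conv_idx = i
    if conv_idx is None:
        raise ValueError("model has no convolution layer to map")
    idx = conv_idx
    while idx + 1 < len(layers) and isinstance(
            layers[idx + 1], (nn.ReLU, nn.LeakyReLU, nn.BatchNorm)):
        idx += 1
    return idx


def activation_map_from_layers(layers: list[nn.Layer], chip_pixels: np.ndarray,
                               target_class: int, n_outputs: int) -> ActivationMap:
    """Grad-CAM over an explicit layer chain ending in class logits."""
    act_idx = _conv_activation_index(layers)
    x = np.asarray(chip_pixels, dtype=np.float32)[None]
    h = x
    acts = None
    for i, layer in enumerate(layers):
        h = layer.forward(h, False, None)
        if i == act_idx:
            acts = h.copy()
    logits = h
    seed = np.zeros_like(logits, dtype=np.float32)
    if n_outputs == 1:
        # scalar-sigmoid heads: the pre-sigmoid score already is the log-odds
        seed[...] = 1.0 if target_class == 1 else -1.0
    else:
        # softmax heads: differentiate the target-class log-odds
        # l_t - mean(l_other); the raw logit carries a class-agnostic
        # common mode whose gradient swamps the class-discriminative signal
        seed[0, :] = -1.0 / (n_outputs - 1)
        seed[0, target_class] = 1.0
    dy = seed
    for i in range(len(layers) - 1, act_idx, -1):
        dy = layers[i].backward(dy)
    grads = dy[0]                              # (h, w, c) at the conv stage
    weights = grads.mean(axis=(0, 1))          # channel importance
    cam = np.maximum((acts[0] * weights).sum(axis=-1), 0.0)
    lo, hi = float(cam.min()), float(cam.max())
    if hi - lo < 1e-12:
        scaled = np.zeros_like(cam)            # constant map -> all zeros
    else:
        scaled = (cam - lo) / (hi - lo) * 255.0
    size = chip_pixels.shape[0]
    up = bilinear_resize(scaled.astype(np.float32), size, size)
    return ActivationMap(np.clip(np.round(up), 0, 255), target_class)


def activation_map(model: EsganModel, chip_pixels: np.ndarray,
                   target_class: int) -> ActivationMap:
    """Grad-CAM for the GAN's supervised head.

    ``chip_pixels`` must be preprocessed exactly as for prediction
    (model input size, [-1, 1]).
    """
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 or 1")
    if chip_pixels.shape[:2] != (model.image_size, model.image_size):
        raise ValueError("chip must be resized to the model input size")
    return activation_map_from_layers(model.discriminator.layers, chip_pixels,
                                      target_class, model.disc_spec.n_classes)


def save_panels(chips_01: list[np.ndarray], maps: list[ActivationMap],
                path) -> None:
    """Side-by-side panels: chip | activation map | overlay."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(chips_01)
    fig, axes = plt.subplots(n, 3, figsize=(7, 2.4 * n), squeeze=False)
    for i, (chip, amap) in enumerate(zip(chips_01, maps)):
        axes[i][0].imshow(chip)
        axes[i][1].imshow(amap.values, cmap="viridis", vmin=0, vmax=255)
        axes[i][2].imshow(chip)
        axes[i][2].imshow(amap.values, cmap="viridis", alpha=0.45,
                          vmin=0, vmax=255)
        for ax in axes[i]:
            ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
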