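"""Sequential container, composite residual block, parameter utilities."""

from __future__ import annotations

import hashlib

import numpy as np

from .layers import BatchNorm, Conv2D, Layer, ReLU

F32 = np.float32


class Sequential(Layer):
    """Ordered chain of layers with whole-network forward/backward.

    ``forward`` threads a single rng stream through stochastic layers
    (dropout); ``backward`` returns the gradient with respect to the input,
    optionally stopping early so callers can read the gradient arriving at an
    intermediate layer's output (used by Grad-CAM).
    """

    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def sublayers(self) -> list[Layer]:
        return self.layers

    def forward(self, x, train: bool, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy, stop_at: int | None = None):
        """Backpropagate; if ``stop_at`` is given, return the gradient flowing
        into the *output* of ``self.layers[stop_at]`` without entering it."""
        for i in range(len(self.layers) - 1, -1, -1):
            if stop_at is not None and i == stop_at:
                return dy
            dy = self.layers[i].backward(dy)
        return dy


class ResidualBlock(Layer):
    """Bottleneck residual unit: 1x1 -> 3x3(stride s) -> 1x1 conv, each with
    batch normalisation, ReLU between, identity (or 1x1-projected) shortcut
    added before the final ReLU."""

    def __init__(self, c_in: int, c_mid: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.stride = stride
        self.conv1 = Conv2D(c_in, c_mid, kernel=1, rng=rng)
        self.bn1 = BatchNorm(c_mid)
        self.conv2 = Conv2D(c_mid, c_mid, kernel=3, stride=stride, rng=rng)
        self.bn2 = BatchNorm(c_mid)
        self.conv3 = Conv2D(c_mid, c_out, kernel=1, rng=rng)
        self.bn3 = BatchNorm(c_out)
        self.relu1, self.relu2, self.relu_out = ReLU(), ReLU(), ReLU()
        if stride != 1 or c_in != c_out:
            self.proj: Conv2D | None = Conv2D(c_in, c_out, kernel=1, stride=stride, rng=rng)
            self.bn_proj: BatchNorm | None = BatchNorm(c_out)
        else:
            self.proj = None
            self.bn_proj = None

    def sublayers(self) -> list[Layer]:
        subs = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2,
                self.relu2, self.conv3, self.bn3, self.relu_out]
        if self.proj is not None:
            subs += [self.proj, self.bn_proj]
        return subs

    def forward(self, x, train, rng=None):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.relu2.forward(self.bn2.forward(self.conv2.forward(y, train, rng), train), train)
        y = self.bn3.forward(self.conv3.forward(y, train), train)
        if self.proj is not None:
            sc = self.bn_proj.forward(self.proj.forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(y + sc, train)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self.relu2.backward(
                self.conv3.backward(self.bn3.backward(dy))))))))
        if self.proj is not None:
            dsc = self.proj.backward(self.bn_proj.backward(dy))
        else:
            dsc = dy
        return dmain + dsc


def walk_layers(layer: Layer):
    """Yield every primitive (parameter-holding or not) layer, depth-first."""
    subs = layer.sublayers() if hasattr(layer, "sublayers") else []
    if subs:
        for sub in subs:
            yield from walk_layers(sub)
    else:
        yield layer


def named_params(root: Layer, trainable_only: bool = True):
    """Yield ((layer_index, param_name), layer, name) for optimiser slots."""
    for i, layer in enumerate(walk_layers(root)):
        if trainable_only and not layer.trainable:
            continue
        for name in layer.params:
            yield (i, name), layer, name


def param_hash(root: Layer, trainable_only: bool = False) -> str:
    """SHA-1 over all parameter bytes, in traversal order (bitwise identity)."""
    h = hashlib.sha1()
    for _, layer, name in named_params(root, trainable_only):
        h.update(np.ascontiguousarray(layer.params[name]).tobytes())
    return h.hexdigest()


def get_state(root: Layer) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    for i, layer in enumerate(walk_layers(root)):
        for name, p in layer.params.items():
            state[f"{i}.{name}"] = p.copy()
        if isinstance(layer, BatchNorm):
            state[f"{i}.running_mean"] = layer.running_mean.copy()
            state[f"{i}.running_var"] = layer.running_var.copy()
    return state


def set_state(root: Layer, state: dict[str, np.ndarray]) -> None:
    for i, layer in enumerate(walk_layers(root)):
        for name in layer.params:
            layer.params[name][...] = state[f"{i}.{name}"]
        if isinstance(layer, BatchNorm):
            layer.running_mean[...] = state[f"{i}.running_mean"]
            layer.running_var[...] = state[f"{i}.running_var"]


def count_params(root: Layer, trainable_only: bool = False) -> int:
    return sum(layer.params[name].size
               for _, layer, name in named_params(root, trainable_only))
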