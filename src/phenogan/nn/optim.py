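"""Adam optimiser over the parameter tree of a layer graph."""

from __future__ import annotations

import numpy as np

from .network import Layer, named_params

F32 = np.float32


class Adam:
    """Standard Adam with bias correction (Kingma & Ba defaults for betas).

    Slots are keyed by (layer traversal index, parameter name) so the
    optimiser state survives checkpointing and frozen layers simply never
    receive a step.
    """

    def __init__(self, model: Layer, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        """Apply one update using gradients currently stored on the layers.

        Layers whose ``grads`` dict is empty (e.g. untouched by the last
        backward pass, or frozen) are skipped.
        """
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for key, layer, name in named_params(self.model, trainable_only=True):
            if name not in layer.grads:
                continue
            g = layer.grads[name].astype(F32)
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / bc1
            vhat = self.v[key] / bc2
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)

    def zero_grad(self) -> None:
        for _, layer, _ in named_params(self.model, trainable_only=False):
            layer.grads.clear()

    def state(self) -> dict:
        return {"t": self.t,
                "m": {f"{k[0]}.{k[1]}": v.copy() for k, v in self.m.items()},
                "v": {f"{k[0]}.{k[1]}": v.copy() for k, v in self.v.items()}}

    def load_state(self, state: dict) -> None:
        self.t = state["t"]
        def unkey(s: str) -> tuple[int, str]:
            i, name = s.split(".", 1)
            return int(i), name
        self.m = {unkey(k): v.copy() for k, v in state["m"].items()}
        self.v = {unkey(k): v.copy() for k, v in state["v"].items()}
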