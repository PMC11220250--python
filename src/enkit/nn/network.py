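"""Sequential network container with softmax/cross-entropy head."""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np

from .layers import Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, None)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


class Network:
    """Ordered layer stack producing class logits.

    ``forward`` returns logits; ``predict_proba`` applies the softmax
    head so rows sum to one.  ``train_step_grads`` runs the fused
    softmax + cross-entropy backward.  In inference mode (training=False,
    dropout off, batch-norm running statistics) the forward map is
    deterministic.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int, int]):
        self.layers = layers
        self.input_shape = input_shape  # (maps, channels, samples), batch-free

    # -- structure ---------------------------------------------------------
    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init(rng)

    def shapes(self, batch: int = 1) -> list[tuple[str, tuple[int, ...]]]:
        shape: tuple[int, ...] = (batch, *self.input_shape)
        out = []
        for layer in self.layers:
            shape = layer.output_shape(shape)
            out.append((layer.name, shape))
        return out

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def find(self, name: str) -> int:
        for i, layer in enumerate(self.layers):
            if layer.name == name:
                return i
        raise KeyError(f"no layer named {name!r}; have "
                       f"{[la.name for la in self.layers]}")

    # -- computation -------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def backward(self, gy: np.ndarray, stop_at: int = -1) -> np.ndarray:
        """Backpropagate ``gy`` from the top; returns the gradient flowing
        out of layer ``stop_at`` (i.e. d loss / d output of that layer).
        With the default ``stop_at=-1`` the gradient w.r.t. the network
        input is returned."""
        for layer in reversed(self.layers[stop_at + 1 :]):
            gy = layer.backward(gy)
        return gy

    def loss_and_grads(self, x: np.ndarray, onehot: np.ndarray,
                       training: bool = True,
                       rng: Optional[np.random.Generator] = None) -> float:
        """Cross-entropy loss with fused softmax gradient; fills layer grads."""
        logits = self.forward(x, training=training, rng=rng)
        probs = softmax(logits)
        loss = cross_entropy(probs, onehot)
        self.zero_grad()
        self.backward((probs - onehot) / x.shape[0])
        return loss

    # -- state -------------------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.params.items():
                state[f"{i}:{layer.name}:{key}"] = val.copy()
            for key in ("running_mean", "running_var"):
                if hasattr(layer, key):
                    state[f"{i}:{layer.name}:{key}"] = getattr(layer, key).copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for key in layer.params:
                layer.params[key] = state[f"{i}:{layer.name}:{key}"].copy()
            for key in ("running_mean", "running_var"):
                if hasattr(layer, key):
                    setattr(layer, key, state[f"{i}:{layer.name}:{key}"].copy())
            layer.zero_grad()

    def clone_state(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.get_state())
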