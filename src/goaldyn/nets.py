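"""Feed-forward networks (Glorot-uniform init, ReLU hidden layers).

Used both for the state-dependent Gaussian-mixture potential of the goal
model and for the recognition (approximate posterior) networks.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, astensor

__all__ = ["MLP"]


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class MLP:
    """Multi-layer perceptron.

    Parameters
    ----------
    sizes : sequence of int
        Layer widths, ``[d_in, h1, ..., d_out]``.  ``len(sizes) == 2`` gives
        a plain affine map (the "linear" potential variant).
    rng : numpy Generator
        Source for the Glorot-uniform weight initialization; biases start
        at zero.
    out_weight_scale : float
        Extra multiplier on the final layer's initial weights (small values
        start the network near its bias).
    out_bias : array-like or None
        Initial value for the final bias vector.
    """

    def __init__(self, sizes, rng: np.random.Generator,
                 out_weight_scale: float = 1.0, out_bias=None):
        self.sizes = list(sizes)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        n_layers = len(sizes) - 1
        for i in range(n_layers):
            w = glorot_uniform(rng, sizes[i], sizes[i + 1])
            b = np.zeros(sizes[i + 1])
            if i == n_layers - 1:
                w = w * out_weight_scale
                if out_bias is not None:
                    b = np.asarray(out_bias, dtype=np.float64).copy()
                    if b.shape != (sizes[i + 1],):
                        raise ValueError("out_bias shape mismatch")
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(b, requires_grad=True))

    @property
    def params(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def __call__(self, x) -> Tensor:
        h = astensor(x)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = h.relu()
        return h

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        """Gradient-free forward pass on raw arrays."""
        h = np.asarray(x, dtype=np.float64)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w.data + b.data
            if i < last:
                h = np.maximum(h, 0.0)
        return h

    # -------------------------------------------------------- serialization
    def state_dict(self) -> dict:
        d = {"sizes": list(self.sizes)}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            d[f"W{i}"] = w.data
            d[f"b{i}"] = b.data
        return d

    @classmethod
    def from_state(cls, d: dict) -> "MLP":
        net = cls.__new__(cls)
        net.sizes = list(d["sizes"])
        net.weights, net.biases = [], []
        for i in range(len(net.sizes) - 1):
            net.weights.append(Tensor(np.asarray(d[f"W{i}"]), requires_grad=True))
            net.biases.append(Tensor(np.asarray(d[f"b{i}"]), requires_grad=True))
        return net


class Adam:
    """ADAM optimizer over a flat list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data + self.lr * mhat / (np.sqrt(vhat) + self.eps)
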