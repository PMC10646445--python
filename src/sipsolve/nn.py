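"""Minimal fully-connected network substrate with manual backpropagation.

Implements exactly what the generative solvers need: dense layers, tanh /
leaky-ReLU activations, Adam, optional spectral normalization on
discriminator weights (one power iteration per forward pass, with the
spectral scale treated as a constant in the backward pass), and the
numerically stable binary-cross-entropy pieces used by non-saturating GAN
losses.  Networks return gradients with respect to their *inputs* as well as
their weights, which is what lets a generator update flow through a
discriminator and through the forward model's Jacobian.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "sigmoid", "softplus", "d_softplus_neg"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def d_softplus_neg(z: np.ndarray) -> np.ndarray:
    """d/dz softplus(-z) = -sigmoid(-z) = sigmoid(z) - 1."""
    return sigmoid(z) - 1.0


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 spectral_norm: bool = False):
        # He-style init keeps early logits in a sane range for leaky ReLU
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.spectral_norm = spectral_norm
        if spectral_norm:
            u = rng.normal(size=n_out)
            self._u = u / np.linalg.norm(u)
        self._sigma = 1.0

    def effective_W(self) -> np.ndarray:
        if not self.spectral_norm:
            return self.W
        # one power iteration; sigma detached in backward
        v = self.W @ self._u
        v /= np.linalg.norm(v) + 1e-12
        u = self.W.T @ v
        nu = np.linalg.norm(u) + 1e-12
        self._u = u / nu
        self._sigma = float(v @ self.W @ self._u) + 1e-12
        return self.W / self._sigma

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._Weff = self.effective_W()
        return x @ self._Weff + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        gW_eff = self._x.T @ g
        self.gW += gW_eff / (self._sigma if self.spectral_norm else 1.0)
        self.gb += g.sum(axis=0)
        return g @ self._Weff.T


def _act(name: str):
    if name == "tanh":
        return np.tanh, lambda a: 1.0 - a**2
    if name == "lrelu":
        return (
            lambda z: np.where(z > 0, z, 0.2 * z),
            lambda a: np.where(a > 0, 1.0, 0.2),
        )
    raise ValueError(f"unknown activation {name!r}")


class MLP:
    """Fully connected net with a linear output layer.

    ``sizes`` gives (n_in, hidden..., n_out).  ``backward`` accumulates
    weight gradients and returns the gradient with respect to the input
    batch, enabling input-side chaining through other modules.
    """

    def __init__(self, sizes, rng: np.random.Generator, hidden_act: str = "lrelu",
                 spectral_norm: bool = False):
        self.layers = [
            _Dense(a, b, rng, spectral_norm=spectral_norm)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.f, self.df = _act(hidden_act)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._acts = []
        h = x
        for layer in self.layers[:-1]:
            h = self.f(layer.forward(h))
            self._acts.append(h)
        return self.layers[-1].forward(h)

    __call__ = forward

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        g = self.layers[-1].backward(g_out)
        for layer, a in zip(reversed(self.layers[:-1]), reversed(self._acts)):
            g = layer.backward(g * self.df(a))
        return g

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.gW[...] = 0.0
            layer.gb[...] = 0.0

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend([layer.W, layer.b])
        return out

    def gradients(self):
        out = []
        for layer in self.layers:
            out.extend([layer.gW, layer.gb])
        return out

    # -- (de)serialization --------------------------------------------------

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            state[f"W{i}"] = layer.W.copy()
            state[f"b{i}"] = layer.b.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            layer.W[...] = state[f"W{i}"]
            layer.b[...] = state[f"b{i}"]


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
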