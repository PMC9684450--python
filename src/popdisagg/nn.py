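"""Minimal fully-deterministic conv net in numpy.

The occupancy network is four convolutional layers (1x1 kernels by
default, so effectively a per-pixel MLP): three hidden layers of 128
filters with ReLU + dropout(0.4), and a single-filter output layer
whose pre-activation is returned (callers apply softplus). For kernel
sizes > 1 the same stack runs on the full grid via im2col with zero
padding.

Parameters, forward, backward and the Adam update are implemented
directly on numpy arrays; every source of randomness (init, dropout)
is an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ValidationError

__all__ = ["NetworkSpec", "ConvNet", "Adam", "count_params"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters of the occupancy / count network."""

    n_inputs: int
    depth: int = 4
    hidden_width: int = 128
    kernel_size: int = 1
    dropout_p: float = 0.4
    dropout_placement: str = "last"  # 'last': one dropout after the final
    # hidden layer; 'all': after every hidden layer. With few supervision
    # units, dropout at every layer injects enough gradient noise to drown
    # the covariate signal, so a single late dropout is the default.

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValidationError("depth must be >= 2")
        if self.kernel_size not in (1, 3, 5):
            raise ValidationError("kernel_size must be one of 1, 3, 5")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValidationError("dropout_p must be in [0, 1)")
        if self.n_inputs < 1:
            raise ValidationError("n_inputs must be >= 1")
        if self.dropout_placement not in ("last", "all"):
            raise ValidationError("dropout_placement must be 'last' or 'all'")

    @property
    def layer_widths(self) -> list[int]:
        return [self.n_inputs] + [self.hidden_width] * (self.depth - 1) + [1]


def count_params(spec: NetworkSpec) -> int:
    """Closed-form parameter count: sum over layers of k^2*n_in*n_out + n_out."""
    widths = spec.layer_widths
    k2 = spec.kernel_size**2
    return sum(k2 * a * b + b for a, b in zip(widths[:-1], widths[1:]))


class ConvNet:
    """Weights plus forward/backward passes; no optimizer state."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        k = spec.kernel_size
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        widths = spec.layer_widths
        for n_in, n_out in zip(widths[:-1], widths[1:]):
            fan_in = k * k * n_in
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k * k * n_in, n_out)))
            self.biases.append(np.zeros(n_out))

    # -- parameter bookkeeping -------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def get_flat_params(self) -> list[np.ndarray]:
        return [p for pair in zip(self.weights, self.biases) for p in pair]

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.get_flat_params()]

    def set_params_from(self, flat: list[np.ndarray]) -> None:
        for i in range(len(self.weights)):
            self.weights[i][...] = flat[2 * i]
            self.biases[i][...] = flat[2 * i + 1]

    def _dropout_here(self, hidden_layer_index: int) -> bool:
        if self.spec.dropout_p <= 0:
            return False
        if self.spec.dropout_placement == "all":
            return True
        return hidden_layer_index == self.spec.depth - 2

    # -- per-cell path (kernel_size == 1) --------------------------------
    def forward_cells(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Forward on a (n_cells, C) matrix; returns (z_out (n,), cache).

        Dropout is active iff ``dropout_rng`` is given (training mode).
        """
        if self.spec.kernel_size != 1:
            raise ValidationError("forward_cells requires kernel_size == 1")
        h = X
        cache = []
        for li, (w, b) in enumerate(zip(self.weights[:-1], self.biases[:-1])):
            z = h @ w + b
            a = np.maximum(z, 0.0)
            mask = None
            if dropout_rng is not None and self._dropout_here(li):
                mask = (dropout_rng.random(a.shape) >= self.spec.dropout_p) / (
                    1.0 - self.spec.dropout_p
                )
                a = a * mask
            cache.append((h, z, mask))
            h = a
        z_out = (h @ self.weights[-1] + self.biases[-1])[:, 0]
        cache.append((h, None, None))
        return z_out, cache

    def backward_cells(self, cache, dz_out: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(z_out); returns flat grad list."""
        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        h_last = cache[-1][0]
        d = dz_out[:, None]
        grads_w[-1] = h_last.T @ d
        grads_b[-1] = d.sum(axis=0)
        dh = d @ self.weights[-1].T
        for li in range(len(self.weights) - 2, -1, -1):
            h, z, mask = cache[li]
            if mask is not None:
                dh = dh * mask
            dz = dh * (z > 0)
            grads_w[li] = h.T @ dz
            grads_b[li] = dz.sum(axis=0)
            if li > 0:
                dh = dz @ self.weights[li].T
        return [g for pair in zip(grads_w, grads_b) for g in pair]

    # -- full-grid path (any kernel size) --------------------------------
    def _im2col(self, a: np.ndarray) -> np.ndarray:
        """(H, W, C) -> (H*W, k*k*C) patch matrix with zero padding."""
        k = self.spec.kernel_size
        if k == 1:
            return a.reshape(-1, a.shape[2])
        pad = k // 2
        padded = np.pad(a, ((pad, pad), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(padded, (k, k), axis=(0, 1))
        # win: (H, W, C, k, k) -> (H, W, k, k, C)
        win = win.transpose(0, 1, 3, 4, 2)
        return win.reshape(a.shape[0] * a.shape[1], k * k * a.shape[2])

    def _col2im_add(self, dcols: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
        k = self.spec.kernel_size
        H, W, C = shape
        if k == 1:
            return dcols.reshape(H, W, C)
        pad = k // 2
        dpadded = np.zeros((H + 2 * pad, W + 2 * pad, C))
        d = dcols.reshape(H, W, k, k, C)
        for ki in range(k):
            for kj in range(k):
                dpadded[ki : ki + H, kj : kj + W, :] += d[:, :, ki, kj, :]
        return dpadded[pad : pad + H, pad : pad + W, :]

    def forward_grid(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Forward on a (H, W, C) grid; returns (z_out (H*W,), cache)."""
        H, W, _ = X.shape
        h = X
        cache = []
        for li, (w, b) in enumerate(zip(self.weights[:-1], self.biases[:-1])):
            cols = self._im2col(h)
            z = cols @ w + b
            a = np.maximum(z, 0.0)
            mask = None
            if dropout_rng is not None and self._dropout_here(li):
                mask = (dropout_rng.random(a.shape) >= self.spec.dropout_p) / (
                    1.0 - self.spec.dropout_p
                )
                a = a * mask
            cache.append((h.shape, cols, z, mask))
            h = a.reshape(H, W, -1)
        cols = self._im2col(h)
        z_out = (cols @ self.weights[-1] + self.biases[-1])[:, 0]
        cache.append((h.shape, cols, None, None))
        return z_out, cache

    def backward_grid(self, cache, dz_out: np.ndarray):
        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        shape_last, cols_last, _, _ = cache[-1]
        d = dz_out[:, None]
        grads_w[-1] = cols_last.T @ d
        grads_b[-1] = d.sum(axis=0)
        dcols = d @ self.weights[-1].T
        dh = self._col2im_add(dcols, shape_last)
        for li in range(len(self.weights) - 2, -1, -1):
            shape, cols, z, mask = cache[li]
            da = dh.reshape(z.shape)
            if mask is not None:
                da = da * mask
            dz = da * (z > 0)
            grads_w[li] = cols.T @ dz
            grads_b[li] = dz.sum(axis=0)
            if li > 0:
                dcols = dz @ self.weights[li].T
                dh = self._col2im_add(dcols, shape)
        return [g for pair in zip(grads_w, grads_b) for g in pair]


class Adam:
    """Standard Adam with optional L2 weight decay added to the gradient."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
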