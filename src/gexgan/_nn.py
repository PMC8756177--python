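"""Minimal dense-network machinery for the conditional WGAN-GP.

Both players are multilayer perceptrons with ReLU hidden activations and a
linear output layer, operating on batches (rows = samples).  Everything is
plain numpy; gradients are computed by hand.

The one non-routine piece is the gradient penalty.  The critic is penalised
by lambda * mean_i (||grad_x D(x~_i)|| - 1)^2, which requires the gradient
of a gradient: the penalty's derivative with respect to the critic weights.
For a ReLU network the input-gradient is piecewise linear in the weights
with the ReLU masks locally constant (the second derivative of ReLU is zero
almost everywhere), so the second-order term can be accumulated with one
extra backward sweep that reuses the first sweep's deltas.  This matches
what reverse-mode autodiff computes for the same architecture.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "init_mlp",
    "mlp_forward",
    "mlp_backward",
    "input_gradient",
    "gradient_penalty_terms",
    "RMSProp",
]


def init_mlp(layer_sizes: list[int], rng: np.random.Generator):
    """He-initialised weights for a ReLU MLP.

    ``layer_sizes`` is ``[n_in, h1, ..., n_out]``.  Returns ``(Ws, bs)``
    with ``Ws[l]`` of shape (fan_out, fan_in) and zero biases.
    """
    Ws, bs = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        Ws.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_out, fan_in)))
        bs.append(np.zeros(fan_out))
    return Ws, bs


def mlp_forward(Ws, bs, V):
    """Forward pass. Returns (output, cache of layer inputs).

    ``cache[l]`` is the input to layer ``l`` (so ``cache[0]`` is the network
    input); hidden activations are ReLU, the last layer is linear.
    """
    V = np.asarray(V, dtype=float)
    cache = [V]
    h = V
    n_layers = len(Ws)
    for l, (W, b) in enumerate(zip(Ws, bs)):
        a = h @ W.T + b
        h = a if l == n_layers - 1 else np.maximum(a, 0.0)
        if l < n_layers - 1:
            cache.append(h)
    return h, cache


def mlp_backward(Ws, bs, cache, d_out):
    """Backward pass from ``d_out`` (batch, n_out).

    Returns ``(dWs, dbs, deltas)`` where ``deltas[l]`` is the gradient at
    the input of layer ``l`` (``deltas[0]`` is the input gradient).
    """
    n_layers = len(Ws)
    dWs = [None] * n_layers
    dbs = [None] * n_layers
    deltas = [None] * (n_layers + 1)
    deltas[n_layers] = np.asarray(d_out, dtype=float)
    d = deltas[n_layers]
    for l in range(n_layers - 1, -1, -1):
        h_in = cache[l]
        dWs[l] = d.T @ h_in
        dbs[l] = d.sum(axis=0)
        d = d @ Ws[l]
        if l > 0:
            d = d * (cache[l] > 0.0)  # ReLU mask of the layer below
        deltas[l] = d
    return dWs, dbs, deltas


def input_gradient(Ws, bs, cache):
    """Gradient of the scalar output w.r.t. the network input, per sample.

    Also returns the per-layer backward deltas, reused by the penalty's
    second-order sweep.
    """
    batch = cache[0].shape[0]
    ones = np.ones((batch, Ws[-1].shape[0]))
    _, _, deltas = mlp_backward(Ws, bs, cache, ones)
    return deltas[0], deltas


def gradient_penalty_terms(Ws, cache, deltas, x_width: int, lam: float, k: int):
    """Penalty value and its weight gradients at interpolated inputs.

    ``deltas`` must come from :func:`input_gradient` on the interpolated
    batch; the gradient norm is taken over the first ``x_width`` input
    components only (the expression slice; covariates are conditioning, not
    penalised).  Returns ``(penalty, dWs)``; bias gradients vanish.
    """
    g_full = deltas[0]
    g_x = g_full[:, :x_width]
    norms = np.sqrt((g_x**2).sum(axis=1))
    penalty = (lam / k) * ((norms - 1.0) ** 2).sum()

    # dp/d(input-gradient), zero outside the expression slice
    safe = np.maximum(norms, 1e-12)
    c = np.zeros_like(g_full)
    c[:, :x_width] = (2.0 * lam / k) * ((norms - 1.0) / safe)[:, None] * g_x

    n_layers = len(Ws)
    dWs = [np.zeros_like(W) for W in Ws]
    t = c
    for l in range(n_layers):
        # backward delta at the input of layer l+1 == ReLU-masked u-chain
        if l < n_layers - 1:
            u = deltas[l + 1]
        else:
            u = np.ones((t.shape[0], 1))
        dWs[l] = u.T @ t
        if l < n_layers - 1:
            t = (t @ Ws[l].T) * (cache[l + 1] > 0.0)
    return penalty, dWs


class RMSProp:
    """RMSProp with decay ``rho`` and stabiliser ``eps`` over a flat list of
    parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 5e-4,
                 rho: float = 0.9, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, c in zip(self.params, grads, self.cache):
            if g is None:
                continue
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)
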