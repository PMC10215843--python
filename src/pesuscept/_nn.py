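"""Minimal NumPy neural-network primitives (explicit forward/backward).

Only what the two classifiers need: dense layers, ReLU, size-2 1-D max
pooling along the node axis, softmax cross-entropy, Chebyshev graph
convolution against precomputed polynomial bases, and Adam. Everything is
deterministic given the seed used to initialize parameters and shuffle
batches.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "chebyshev_filter",
    "cheb_basis",
    "glorot_uniform",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def chebyshev_filter(x: np.ndarray, Ls: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Apply a Chebyshev polynomial filter via the three-term recurrence.

    ``y = sum_k theta_k T_k(Ls) x`` with ``T_0 = I``, ``T_1 = Ls`` and
    ``T_k = 2 Ls T_{k-1} - T_{k-2}``; the recurrence acts on the signal, so
    no matrix power is ever materialized per sample.

    Parameters
    ----------
    x : (n_nodes,), (n_nodes, f_in) or (batch, n_nodes, f_in)
    Ls : (n_nodes, n_nodes) rescaled Laplacian, spectrum in [-1, 1]
    theta : (K,) for scalar channels or (K, f_in, f_out)
    """
    x = np.asarray(x, dtype=float)
    Ls = np.asarray(Ls, dtype=float)
    theta = np.asarray(theta, dtype=float)
    squeeze_feat = x.ndim == 1
    if squeeze_feat:
        x = x[:, None]
    squeeze_batch = x.ndim == 2
    if squeeze_batch:
        x = x[None]
    if x.shape[1] != Ls.shape[0]:
        raise ValueError(
            f"signal has {x.shape[1]} nodes but Laplacian is {Ls.shape[0]}x{Ls.shape[1]}"
        )
    K = theta.shape[0]
    scalar_theta = theta.ndim == 1
    t_prev = x  # T_0 x
    acc = _apply_theta(t_prev, theta, 0, scalar_theta)
    if K > 1:
        t_curr = np.matmul(Ls, x)  # T_1 x, applied along the node axis
        acc = acc + _apply_theta(t_curr, theta, 1, scalar_theta)
        for k in range(2, K):
            t_next = 2.0 * np.matmul(Ls, t_curr) - t_prev
            t_prev, t_curr = t_curr, t_next
            acc = acc + _apply_theta(t_curr, theta, k, scalar_theta)
    if squeeze_batch:
        acc = acc[0]
    if squeeze_feat:
        acc = acc[..., 0]
    return acc


def _apply_theta(tx, theta, k, scalar_theta):
    if scalar_theta:
        return theta[k] * tx
    return tx @ theta[k]


def cheb_basis(Ls: np.ndarray, K: int) -> np.ndarray:
    """Stack of Chebyshev matrices ``T_k(Ls)`` for k=0..K-1, shape (K, n, n).

    Precomputed once per graph level (the graph is fixed during training),
    never per sample.
    """
    n = Ls.shape[0]
    out = np.empty((K, n, n))
    out[0] = np.eye(n)
    if K > 1:
        out[1] = Ls
        for k in range(2, K):
            out[k] = 2.0 * Ls @ out[k - 1] - out[k - 2]
    return out


def cheb_layer_forward(T: np.ndarray, H: np.ndarray, theta: np.ndarray, bias: np.ndarray):
    """Graph-convolution layer: ``out = sum_k T_k H theta_k + bias``.

    T: (K, n, n) precomputed basis; H: (batch, n, f_in); theta: (K, f_in,
    f_out). Returns ``(out, Z)`` where ``Z`` (batch, n, K, f_in) is cached
    for the backward pass. Uses batched matmul throughout.
    """
    K, n, _ = T.shape
    b, _, f_in = H.shape
    H2 = H.transpose(1, 0, 2).reshape(n, b * f_in)
    Z = np.matmul(T, H2)  # (K, n, b*f_in)
    Z = Z.reshape(K, n, b, f_in).transpose(2, 1, 0, 3)  # (b, n, K, f_in)
    out = Z.reshape(b, n, K * f_in) @ theta.reshape(K * f_in, -1) + bias
    return out, Z


def cheb_layer_backward(T: np.ndarray, Z: np.ndarray, theta: np.ndarray,
                        dout: np.ndarray, need_dinput: bool = True):
    """Gradients of :func:`cheb_layer_forward`.

    Returns ``(dtheta, dbias, dH)`` with ``dH`` None when ``need_dinput`` is
    False (the first layer's input is data).
    """
    b, n, K, f_in = Z.shape
    f_out = dout.shape[-1]
    Zm = Z.reshape(b * n, K * f_in)
    dm = dout.reshape(b * n, f_out)
    dtheta = (Zm.T @ dm).reshape(K, f_in, f_out)
    dbias = dout.sum(axis=(0, 1))
    dH = None
    if need_dinput:
        dZ = (dm @ theta.reshape(K * f_in, f_out).T).reshape(b, n, K, f_in)
        dZr = dZ.transpose(2, 1, 0, 3).reshape(K, n, b * f_in)
        # T_k is a polynomial of a symmetric matrix, hence symmetric
        acc = np.matmul(T, dZr).sum(axis=0)  # (n, b*f_in)
        dH = acc.reshape(n, b, f_in).transpose(1, 0, 2)
    return dtheta, dbias, dH


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y_onehot: np.ndarray, sample_weight=None):
    """Mean cross-entropy and the gradient w.r.t. the logits."""
    p = softmax(logits)
    eps = 1e-12
    losses = -np.sum(y_onehot * np.log(p + eps), axis=1)
    if sample_weight is None:
        loss = losses.mean()
        grad = (p - y_onehot) / logits.shape[0]
    else:
        w = sample_weight / sample_weight.sum()
        loss = float(np.sum(w * losses))
        grad = (p - y_onehot) * w[:, None]
    return float(loss), grad


class Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
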