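"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's networks (bidirectional GRU encoders with two attention
levels) need gradients of a user-level cross-entropy loss with respect to
every weight.  Rather than hand-deriving the full backward pass of the
composed model, each building block here is a differentiable primitive on a
small tape: generic array ops (matmul, add, mul, tanh, sigmoid, softmax,
concat, reshape), an embedding lookup, a masked softmax for attention over
padded sequences, an attention-weighted sum, a fused GRU layer whose
backward-through-time is derived by hand, and a fused softmax
cross-entropy.  Every primitive is checked against central finite
differences in the test suite.

Tensors are float64 throughout; problem sizes in this package are small
enough that exactness is worth more than the float32 speedup.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "mul",
    "matmul",
    "dense",
    "tanh",
    "sigmoid",
    "softmax",
    "masked_softmax",
    "concat",
    "reshape",
    "lookup",
    "attend",
    "gru_layer",
    "nll_from_logits",
]


class Tensor:
    """A node in the computation graph: an ndarray plus backward plumbing."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Accumulate gradients into every reachable parent tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order; graphs can be ~100s of nodes deep
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad += pgrad


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out._backward = lambda g: (
        _unbroadcast(g, a.data.shape),
        _unbroadcast(g, b.data.shape),
    )
    return out


def mul(a: Tensor, b) -> Tensor:
    """Elementwise product; `b` may be a Tensor or a constant ndarray."""
    if isinstance(b, Tensor):
        out = Tensor(a.data * b.data, (a, b))
        out._backward = lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )
        return out
    barr = np.asarray(b, dtype=np.float64)
    out = Tensor(a.data * barr, (a,))
    out._backward = lambda g: (_unbroadcast(g * barr, a.data.shape),)
    return out


def matmul(a: Tensor, w: Tensor) -> Tensor:
    """`a @ w` where a is (..., I) and w is (I, O)."""
    lead = a.data.shape[:-1]
    a2 = a.data.reshape(-1, a.data.shape[-1])
    out = Tensor((a2 @ w.data).reshape(*lead, w.data.shape[1]), (a, w))

    def _bw(g):
        g2 = g.reshape(-1, w.data.shape[1])
        return (g2 @ w.data.T).reshape(a.data.shape), a2.T @ g2

    out._backward = _bw
    return out


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return add(matmul(x, w), b)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: (g * (1.0 - y * y),)
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, (x,))
    out._backward = lambda g: (g * y * (1.0 - y),)
    return out


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    p = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(p, (x,))
    out._backward = lambda g: (p * (g - (g * p).sum(axis=-1, keepdims=True)),)
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to positions where mask == 1.

    Masked positions get probability 0.  Rows with no valid position at all
    (fully padded posts/bags) yield an all-zero row rather than an error;
    callers zero out everything downstream of such rows.
    """
    m = np.asarray(mask, dtype=np.float64)
    neg = np.where(m > 0, scores.data, -np.inf)
    rowmax = neg.max(axis=-1, keepdims=True)
    alive = np.isfinite(rowmax)
    rowmax = np.where(alive, rowmax, 0.0)
    e = np.exp(np.where(m > 0, scores.data - rowmax, -np.inf)) * m
    denom = e.sum(axis=-1, keepdims=True)
    p = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
    out = Tensor(p, (scores,))
    out._backward = lambda g: (p * (g - (g * p).sum(axis=-1, keepdims=True)),)
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.data.reshape(shape), (x,))
    out._backward = lambda g: (g.reshape(x.data.shape),)
    return out


def lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """Embedding lookup: rows of `table` gathered by integer `ids`."""
    ids = np.asarray(ids)
    out = Tensor(table.data[ids], (table,))

    def _bw(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, ids.reshape(-1), g.reshape(-1, table.data.shape[1]))
        return (gt,)

    out._backward = _bw
    return out


def attend(weights: Tensor, seq: Tensor) -> Tensor:
    """Weighted sum over time: (N,T) x (N,T,D) -> (N,D)."""
    a, h = weights.data, seq.data
    out = Tensor(np.einsum("nt,ntd->nd", a, h), (weights, seq))
    out._backward = lambda g: (
        np.einsum("nd,ntd->nt", g, h),
        a[:, :, None] * g[:, None, :],
    )
    return out


def nll_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of `labels` under softmax(logits)."""
    labels = np.asarray(labels, dtype=int)
    shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    logp = shifted - logz
    n = labels.shape[0]
    out = Tensor(-logp[np.arange(n), labels].mean(), (logits,))

    def _bw(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        return (float(g) * p / n,)

    out._backward = _bw
    return out


def gru_layer(
    x: Tensor,
    mask: np.ndarray,
    w: Tensor,
    u: Tensor,
    b: Tensor,
    reverse: bool = False,
) -> Tensor:
    """One direction of a GRU over a padded batch of sequences.

    x: (N, T, I); mask: (N, T) with 1 on real steps.  Gate order in the
    packed weight matrices is [update z | reset r | candidate n] and the
    candidate applies the reset gate to the recurrent term,
    n = tanh(W_n x + b_n + r * (U_n h)).  Masked steps carry the previous
    hidden state unchanged, so trailing padding never perturbs the states
    of real steps (in either direction).  Returns the hidden-state
    sequence (N, T, H); the backward pass is hand-derived
    backpropagation-through-time over the stored per-step gates.
    """
    n_seq, t_len, _ = x.data.shape
    hid = u.data.shape[0]
    m_all = np.asarray(mask, dtype=np.float64)
    xd = x.data
    if reverse:
        xd = xd[:, ::-1]
        m_all = m_all[:, ::-1]

    gx = xd.reshape(-1, xd.shape[-1]) @ w.data + b.data
    gx = gx.reshape(n_seq, t_len, 3 * hid)

    h = np.zeros((n_seq, hid))
    hs_prev = np.empty((n_seq, t_len, hid))
    zs = np.empty_like(hs_prev)
    rs = np.empty_like(hs_prev)
    ns = np.empty_like(hs_prev)
    ghn_s = np.empty_like(hs_prev)
    out_seq = np.empty_like(hs_prev)
    for t in range(t_len):
        gh = h @ u.data
        z = 1.0 / (1.0 + np.exp(-(gx[:, t, :hid] + gh[:, :hid])))
        r = 1.0 / (1.0 + np.exp(-(gx[:, t, hid : 2 * hid] + gh[:, hid : 2 * hid])))
        ghn = gh[:, 2 * hid :]
        n_cand = np.tanh(gx[:, t, 2 * hid :] + r * ghn)
        h_new = (1.0 - z) * n_cand + z * h
        m = m_all[:, t : t + 1]
        hs_prev[:, t] = h
        zs[:, t], rs[:, t], ns[:, t], ghn_s[:, t] = z, r, n_cand, ghn
        h = m * h_new + (1.0 - m) * h
        out_seq[:, t] = h

    if reverse:
        out = Tensor(out_seq[:, ::-1], (x, w, u, b))
    else:
        out = Tensor(out_seq, (x, w, u, b))

    def _bw(grad):
        g_seq = grad[:, ::-1] if reverse else grad
        dgx = np.zeros_like(gx)
        du = np.zeros_like(u.data)
        carry = np.zeros((n_seq, hid))
        for t in range(t_len - 1, -1, -1):
            dh = g_seq[:, t] + carry
            m = m_all[:, t : t + 1]
            dh_new = dh * m
            carry = dh * (1.0 - m)
            z, r, n_cand = zs[:, t], rs[:, t], ns[:, t]
            h_prev, ghn = hs_prev[:, t], ghn_s[:, t]
            dn = dh_new * (1.0 - z)
            dz = dh_new * (h_prev - n_cand)
            dh_prev = dh_new * z
            dan = dn * (1.0 - n_cand * n_cand)
            dr = dan * ghn
            dghn = dan * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            dgh = np.concatenate([daz, dar, dghn], axis=1)
            dh_prev = dh_prev + dgh @ u.data.T
            du += h_prev.T @ dgh
            dgx[:, t, :hid] = daz
            dgx[:, t, hid : 2 * hid] = dar
            dgx[:, t, 2 * hid :] = dan
            carry = carry + dh_prev
        dgx2 = dgx.reshape(-1, 3 * hid)
        dx = (dgx2 @ w.data.T).reshape(n_seq, t_len, -1)
        if reverse:
            dx = dx[:, ::-1]
        dw = xd.reshape(-1, xd.shape[-1]).T @ dgx2
        db = dgx2.sum(axis=0)
        return dx, dw, du, db

    out._backward = _bw
    return out
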