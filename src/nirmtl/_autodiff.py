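"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the spectral feature extractors need:
broadcast arithmetic, (batched) matmul, activations, softmax, dropout,
same-padded 1-D convolution via im2col, and fused LSTM and scaled
dot-product attention nodes whose backward passes are implemented in closed
form (much faster than composing them from elementwise nodes at 228
sequence positions).  All arithmetic is float32.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "name")

    def __init__(self, data, parents=(), backward=None, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the same gradient array may be routed to several parents
            self.grad = np.array(np.broadcast_to(grad, self.data.shape),
                                 dtype=DTYPE)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Reverse-topological accumulation from this (scalar) node."""
        topo, seen = [], set()

        def visit(node: "Tensor") -> None:
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            a.accumulate(_unbroadcast(g, a.shape))
            b.accumulate(_unbroadcast(g, b.shape))

        return Tensor(a.data + b.data, (a, b), backward)

    def __mul__(self, other):
        if np.isscalar(other):
            a, s = self, float(other)
            return Tensor(a.data * s, (a,), lambda g: a.accumulate(g * s))
        a, b = self, other

        def backward(g):
            a.accumulate(_unbroadcast(g * b.data, a.shape))
            b.accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        """Matrix product; batched over leading dimensions when present."""
        a, b = self, other

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a.accumulate(_unbroadcast(ga, a.shape))
            b.accumulate(_unbroadcast(gb, b.shape))

        return Tensor(a.data @ b.data, (a, b), backward)

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        a = self
        return Tensor(a.data.reshape(*shape), (a,),
                      lambda g: a.accumulate(g.reshape(a.shape)))

    def transpose(self, *axes) -> "Tensor":
        a = self
        inverse = np.argsort(axes)
        return Tensor(a.data.transpose(axes), (a,),
                      lambda g: a.accumulate(g.transpose(inverse)))

    # -- activations -----------------------------------------------------
    def tanh(self) -> "Tensor":
        a = self
        out = np.tanh(a.data)
        return Tensor(out, (a,), lambda g: a.accumulate(g * (1 - out ** 2)))

    def sigmoid(self) -> "Tensor":
        a = self
        out = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor(out, (a,), lambda g: a.accumulate(g * out * (1 - out)))

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0
        return Tensor(a.data * mask, (a,), lambda g: a.accumulate(g * mask))

    def softmax_last(self) -> "Tensor":
        """Numerically stable softmax along the last axis."""
        a = self
        z = a.data - a.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * out).sum(axis=-1, keepdims=True)
            a.accumulate((g - dot) * out)

        return Tensor(out, (a,), backward)

    def dropout(self, p: float, rng: np.random.Generator | None) -> "Tensor":
        """Inverted dropout; identity when ``rng`` is None (inference)."""
        if rng is None or p <= 0:
            return self
        a = self
        mask = ((rng.random(a.shape) >= p) / (1.0 - p)).astype(DTYPE)
        return Tensor(a.data * mask, (a,), lambda g: a.accumulate(g * mask))

    def mean(self) -> "Tensor":
        a = self
        scale = 1.0 / a.data.size
        return Tensor(a.data.mean(), (a,),
                      lambda g: a.accumulate(np.full(a.shape, g * scale)))


def concat(tensors, axis: int = -1) -> Tensor:
    parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in parents]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(parents, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate(g[tuple(idx)])

    return Tensor(np.concatenate([t.data for t in parents], axis=axis),
                  parents, backward)


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 1-D convolution.

    ``x``: (batch, length, c_in); ``weight``: (kernel, c_in, c_out);
    ``bias``: (c_out,).  Output: (batch, length, c_out).
    """
    B, L, Cin = x.data.shape
    K, _, Cout = weight.data.shape
    pad_l, pad_r = (K - 1) // 2, K // 2
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
    # (B, L, K, Cin) gather of sliding windows
    cols = np.stack([xp[:, t:t + L, :] for t in range(K)], axis=2)
    cols2 = cols.reshape(B * L, K * Cin)
    W2 = weight.data.reshape(K * Cin, Cout)
    out = (cols2 @ W2).reshape(B, L, Cout) + bias.data

    def backward(g):
        g2 = g.reshape(B * L, Cout)
        weight.accumulate((cols2.T @ g2).reshape(weight.shape))
        bias.accumulate(g2.sum(axis=0))
        dcols = (g2 @ W2.T).reshape(B, L, K, Cin)
        dxp = np.zeros_like(xp)
        for t in range(K):
            dxp[:, t:t + L, :] += dcols[:, :, t, :]
        x.accumulate(dxp[:, pad_l:pad_l + L, :])

    return Tensor(out, (x, weight, bias), backward)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """Fused softmax(q k' / sqrt(dh)) v for (batch, heads, T, dh) inputs."""
    dh = q.data.shape[-1]
    scale = DTYPE(1.0 / np.sqrt(dh))
    probs = (q.data @ np.swapaxes(k.data, -1, -2)) * scale
    probs -= probs.max(axis=-1, keepdims=True)
    np.exp(probs, out=probs)
    probs /= probs.sum(axis=-1, keepdims=True)
    out = probs @ v.data

    def backward(g):
        v.accumulate(np.swapaxes(probs, -1, -2) @ g)
        dprobs = g @ np.swapaxes(v.data, -1, -2)
        ds = (dprobs - (dprobs * probs).sum(axis=-1, keepdims=True)) * probs
        ds *= scale
        q.accumulate(ds @ k.data)
        k.accumulate(np.swapaxes(ds, -1, -2) @ q.data)

    return Tensor(out, (q, k, v), backward)


def lstm(x: Tensor, W: Tensor, U: Tensor, b: Tensor) -> Tensor:
    """Fused LSTM layer returning the full hidden-state sequence.

    ``x``: (batch, steps, d_in); ``W``: (d_in, 4*hidden); ``U``:
    (hidden, 4*hidden); ``b``: (4*hidden,).  Gate order: input, forget,
    candidate, output; forget-gate bias should be pre-set to 1.
    """
    B, T, _ = x.data.shape
    H = U.data.shape[0]
    h = np.zeros((B, H), dtype=DTYPE)
    c = np.zeros((B, H), dtype=DTYPE)
    gates = np.empty((T, B, 4 * H), dtype=DTYPE)
    cs = np.empty((T, B, H), dtype=DTYPE)       # c_t
    hs = np.empty((T, B, H), dtype=DTYPE)       # h_{t-1}
    cs_prev = np.empty((T, B, H), dtype=DTYPE)  # c_{t-1}
    out = np.empty((B, T, H), dtype=DTYPE)
    xW = x.data @ W.data  # (B, T, 4H), hoisted out of the loop
    for t in range(T):
        hs[t], cs_prev[t] = h, c
        a = xW[:, t, :] + h @ U.data + b.data
        i = 1.0 / (1.0 + np.exp(-a[:, :H]))
        f = 1.0 / (1.0 + np.exp(-a[:, H:2 * H]))
        g_ = np.tanh(a[:, 2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-a[:, 3 * H:]))
        c = f * cs_prev[t] + i * g_
        h = o * np.tanh(c)
        gates[t] = np.concatenate([i, f, g_, o], axis=1)
        cs[t] = c
        out[:, t, :] = h

    def backward(gout):
        dU = np.zeros_like(U.data)
        db = np.zeros_like(b.data)
        dx = np.empty_like(x.data)
        da_all = np.empty((B, T, 4 * H), dtype=DTYPE)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i, f = gates[t, :, :H], gates[t, :, H:2 * H]
            g_, o = gates[t, :, 2 * H:3 * H], gates[t, :, 3 * H:]
            tc = np.tanh(cs[t])
            dh = gout[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc ** 2) + dc_next
            di, dg = dc * g_, dc * i
            df = dc * cs_prev[t]
            dc_next = dc * f
            da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g_ ** 2), do * o * (1 - o)],
                                axis=1)
            da_all[:, t, :] = da
            dx[:, t, :] = da @ W.data.T
            dh_next = da @ U.data.T
            dU += hs[t].T @ da
            db += da.sum(axis=0)
        x.accumulate(dx)
        W.accumulate(np.einsum("btd,btg->dg", x.data, da_all))
        U.accumulate(dU)
        b.accumulate(db)

    return Tensor(out, (x, W, U, b), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - np.asarray(target, float).reshape(pred.shape)
    n = diff.size

    def backward(g):
        pred.accumulate(g * 2.0 * diff / n)

    return Tensor(np.mean(diff ** 2), (pred,), backward)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean cross-entropy with fused softmax backward."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    n = logits.data.shape[0]
    loss = -np.sum(onehot * np.log(probs + 1e-30)) / n

    def backward(g):
        logits.accumulate(g * (probs - onehot) / n)

    return Tensor(loss, (logits,), backward)


class Adam:
    """Adam with coupled L2 (grad += l2 * param) and global-norm clipping."""

    def __init__(self, params, lr: float = 1e-3, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, clip_norm: float = 1.0):
        self.params = list(params)
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        scale = 1.0
        if self.clip_norm:
            total = np.sqrt(sum(float(np.sum(p.grad ** 2))
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = scale * p.grad + self.l2 * p.data
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g ** 2
            m_hat = m / (1 - self.beta1 ** self.t)
            v_hat = v / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
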