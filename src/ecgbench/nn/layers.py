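"""Layer objects composing the autodiff primitives.

Layers hold :class:`~ecgbench.nn.autodiff.Tensor` parameters and build graph
nodes in ``__call__``.  The recurrent (GRU) and additive-attention layers
implement forward and backward inside a single graph node each, so a 5000
time-step sequence does not expand into thousands of graph nodes; their
hand-written backward passes are finite-difference checked in the tests.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .autodiff import Tensor, conv1d_same, matmul, maxpool1d


class Layer:
    train_mode: bool = True

    def params(self) -> list[Tensor]:
        return []

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def glorot_init(rng, shape, fan_in, fan_out) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Conv1d(Layer):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.w = Tensor(he_init(rng, (cout, cin, k), cin * k), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.k = k

    def params(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.w, self.b)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.w = Tensor(glorot_init(rng, (nin, nout), nin, nout), requires_grad=True)
        self.b = Tensor(np.zeros(nout), requires_grad=True)

    def params(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.w) + self.b


class BatchNorm1d(Layer):
    """Batch normalization over (batch, time) per channel, with running
    statistics for evaluation mode."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor) -> Tensor:
        if self.train_mode:
            mu = x.data.mean(axis=(0, 2))
            var = x.data.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var

        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None]) * inv[None, :, None]
        out_data = self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]
        out = Tensor(out_data, _prev=(x, self.gamma, self.beta))
        train = self.train_mode
        gamma, beta = self.gamma, self.beta

        def bwd():
            g = out.grad
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                gi = g * gamma.data[None, :, None] * inv[None, :, None]
                if train:
                    m = x.data.shape[0] * x.data.shape[2]
                    mean_g = gi.mean(axis=(0, 2), keepdims=True)
                    mean_gx = (gi * xhat).mean(axis=(0, 2), keepdims=True)
                    x._accum(gi - mean_g - xhat * mean_gx)
                    del m
                else:
                    x._accum(gi)

        out._backward = bwd
        return out


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.train_mode or self.p == 0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.3):
        self.alpha = alpha

    def __call__(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.alpha)


class MaxPool(Layer):
    def __init__(self, size: int = 2, stride: int = 2):
        self.size, self.stride = size, stride

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.size, self.stride)


class GRU(Layer):
    """Unidirectional GRU returning all hidden states, as one graph node.

    Update gate z, reset gate r, candidate h~; h_t = (1-z) h_{t-1} + z h~_t.
    Input (N, T, I), output (N, T, H).  ``reverse=True`` processes the
    sequence right-to-left (for the backward half of a bidirectional layer).
    """

    def __init__(self, nin: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        def wi():
            return glorot_init(rng, (nin, hidden), nin, hidden)

        def wh():
            return glorot_init(rng, (hidden, hidden), hidden, hidden)

        self.Wz, self.Wr, self.Wh = (Tensor(wi(), requires_grad=True) for _ in range(3))
        self.Uz, self.Ur, self.Uh = (Tensor(wh(), requires_grad=True) for _ in range(3))
        self.bz, self.br, self.bh = (
            Tensor(np.zeros(hidden), requires_grad=True) for _ in range(3)
        )
        self.hidden = hidden
        self.reverse = reverse

    def params(self):
        return [self.Wz, self.Wr, self.Wh, self.Uz, self.Ur, self.Uh,
                self.bz, self.br, self.bh]

    def __call__(self, x: Tensor) -> Tensor:
        N, T, _ = x.data.shape
        H = self.hidden
        xs = x.data[:, ::-1, :] if self.reverse else x.data
        # precompute input projections for all steps at once
        xz = xs @ self.Wz.data + self.bz.data
        xr = xs @ self.Wr.data + self.br.data
        xh = xs @ self.Wh.data + self.bh.data
        hs = np.zeros((T + 1, N, H))
        zs = np.zeros((T, N, H))
        rs = np.zeros((T, N, H))
        cs = np.zeros((T, N, H))  # candidates
        for t in range(T):
            hp = hs[t]
            z = _sig(xz[:, t] + hp @ self.Uz.data)
            r = _sig(xr[:, t] + hp @ self.Ur.data)
            c = np.tanh(xh[:, t] + (r * hp) @ self.Uh.data)
            hs[t + 1] = (1 - z) * hp + z * c
            zs[t], rs[t], cs[t] = z, r, c
        out_seq = hs[1:].transpose(1, 0, 2)  # (N, T, H)
        if self.reverse:
            out_seq = out_seq[:, ::-1, :]
        out = Tensor(out_seq, _prev=(x, *self.params()))
        layer = self

        def bwd():
            gseq = out.grad  # (N, T, H)
            if layer.reverse:
                gseq = gseq[:, ::-1, :]
            dWz = np.zeros_like(layer.Wz.data); dWr = np.zeros_like(layer.Wr.data)
            dWh = np.zeros_like(layer.Wh.data); dUz = np.zeros_like(layer.Uz.data)
            dUr = np.zeros_like(layer.Ur.data); dUh = np.zeros_like(layer.Uh.data)
            dbz = np.zeros(H); dbr = np.zeros(H); dbh = np.zeros(H)
            dx = np.zeros_like(xs)
            dh = np.zeros((N, H))
            for t in range(T - 1, -1, -1):
                dh = dh + gseq[:, t]
                hp, z, r, c = hs[t], zs[t], rs[t], cs[t]
                dz = dh * (c - hp)
                dc = dh * z
                dhp = dh * (1 - z)
                dac = dc * (1 - c * c)
                dWh += xs[:, t].T @ dac
                dUh += (r * hp).T @ dac
                dbh += dac.sum(0)
                duh = dac @ layer.Uh.data.T
                dr = duh * hp
                dhp += duh * r
                daz = dz * z * (1 - z)
                dar = dr * r * (1 - r)
                dWz += xs[:, t].T @ daz
                dWr += xs[:, t].T @ dar
                dUz += hp.T @ daz
                dUr += hp.T @ dar
                dbz += daz.sum(0)
                dbr += dar.sum(0)
                dx[:, t] = daz @ layer.Wz.data.T + dar @ layer.Wr.data.T + dac @ layer.Wh.data.T
                dh = dhp + daz @ layer.Uz.data.T + dar @ layer.Ur.data.T
            for p, g in zip(
                layer.params(), (dWz, dWr, dWh, dUz, dUr, dUh, dbz, dbr, dbh)
            ):
                if p.requires_grad:
                    p._accum(g)
            if x.requires_grad:
                x._accum(dx[:, ::-1, :] if layer.reverse else dx)

        out._backward = bwd
        return out


def _sig(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60)))


class BiGRU(Layer):
    """Bidirectional GRU: forward and reverse passes concatenated on the
    feature axis, sequence output (N, T, 2H)."""

    def __init__(self, nin: int, hidden: int, rng: np.random.Generator):
        self.fwd = GRU(nin, hidden, rng)
        self.bwd_ = GRU(nin, hidden, rng, reverse=True)

    def params(self):
        return self.fwd.params() + self.bwd_.params()

    def __call__(self, x: Tensor) -> Tensor:
        a, b = self.fwd(x), self.bwd_(x)
        out = Tensor(np.concatenate([a.data, b.data], axis=2), _prev=(a, b))
        H = a.data.shape[2]

        def bwd():
            if a.requires_grad:
                a._accum(out.grad[:, :, :H])
            if b.requires_grad:
                b._accum(out.grad[:, :, H:])

        out._backward = bwd
        return out


class AttentionPool(Layer):
    """Additive attention with a learned context vector.

    Scores s_t = v . tanh(W h_t + b) are softmax-normalized over time and
    the output is the attention-weighted sum of hidden states.  The
    normalized weights of the latest forward pass are kept on
    ``last_weights`` for inspection.
    """

    def __init__(self, dim: int, attn_dim: int, rng: np.random.Generator):
        self.W = Tensor(glorot_init(rng, (dim, attn_dim), dim, attn_dim),
                        requires_grad=True)
        self.b = Tensor(np.zeros(attn_dim), requires_grad=True)
        self.v = Tensor(glorot_init(rng, (attn_dim,), attn_dim, 1),
                        requires_grad=True)
        self.last_weights: Optional[np.ndarray] = None

    def params(self):
        return [self.W, self.b, self.v]

    def __call__(self, h: Tensor) -> Tensor:
        u = np.tanh(h.data @ self.W.data + self.b.data)  # (N, T, A)
        s = u @ self.v.data  # (N, T)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        alpha = e / e.sum(axis=1, keepdims=True)
        self.last_weights = alpha
        c = np.einsum("nt,ntd->nd", alpha, h.data)
        out = Tensor(c, _prev=(h, self.W, self.b, self.v))
        W, b, v = self.W, self.b, self.v

        def bwd():
            dc = out.grad  # (N, D)
            dalpha = np.einsum("nd,ntd->nt", dc, h.data)
            dh = alpha[:, :, None] * dc[:, None, :]
            ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
            if v.requires_grad:
                v._accum(np.einsum("nta,nt->a", u, ds))
            du = ds[:, :, None] * v.data
            da = du * (1 - u * u)
            if W.requires_grad:
                W._accum(np.einsum("ntd,nta->da", h.data, da))
            if b.requires_grad:
                b._accum(da.sum(axis=(0, 1)))
            dh += np.einsum("nta,da->ntd", da, W.data)
            if h.requires_grad:
                h._accum(dh)

        out._backward = bwd
        return out
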