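"""Neural-network building blocks with explicit forward/backward passes.

Everything is plain NumPy.  Each layer caches what its backward pass needs;
parameters are (value, grad) pairs collected by the optimizer.  Shapes follow
the 1-D-convolution convention (batch, channels, time).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1D",
    "BatchNorm1D",
    "ReLU",
    "GlobalAvgPool",
    "LSTMLast",
    "Dense",
    "Adam",
    "softmax",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray, dtype=np.float32):
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Conv1D:
    """Same-padded 1-D convolution (cross-correlation), He-initialised."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = Param(rng.standard_normal((c_out, c_in, kernel)) * scale, dtype)
        self.b = Param(np.zeros(c_out), dtype)
        self.kernel = kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left
        self._xp: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True,
                mask: np.ndarray | None = None) -> np.ndarray:
        """``mask`` (N, T) marks valid positions of right-padded batches;
        padded positions are zeroed so they behave exactly like the zero
        same-padding beyond a series' true end."""
        n, c, t = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        out = np.empty((n, self.W.value.shape[0], t), dtype=self.W.value.dtype)
        out[:] = self.b.value[None, :, None]
        for j in range(self.kernel):
            out += np.einsum("nct,oc->not", xp[:, :, j : j + t], self.W.value[:, :, j], optimize=True)
        if mask is not None:
            out *= mask[:, None, :]
        self._xp = xp if train else None
        self._t = t
        self._mask = mask
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, t = self._xp, self._t
        if self._mask is not None:
            grad = grad * self._mask[:, None, :]
        dxp = np.zeros_like(xp)
        for j in range(self.kernel):
            self.W.grad[:, :, j] += np.einsum("not,nct->oc", grad, xp[:, :, j : j + t], optimize=True)
            dxp[:, :, j : j + t] += np.einsum("not,oc->nct", grad, self.W.value[:, :, j], optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        dx = dxp[:, :, self.pad_left : self.pad_left + t]
        if self._mask is not None:
            dx *= self._mask[:, None, :]
        return dx


class BatchNorm1D:
    """Per-channel batch normalisation over (batch, time)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels), dtype)
        self.beta = Param(np.zeros(channels), dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True,
                mask: np.ndarray | None = None) -> np.ndarray:
        """Masked positions are excluded from the batch statistics."""
        if train:
            if mask is None:
                m = x.shape[0] * x.shape[2]
                mu = x.mean(axis=(0, 2))
                var = x.var(axis=(0, 2))
            else:
                m = float(mask.sum())
                mu = np.einsum("nct,nt->c", x, mask) / m
                cen = (x - mu[None, :, None]) * mask[:, None, :]
                var = np.einsum("nct,nct->c", cen, cen) / m
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(self.running_mean.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv_std[None, :, None]
        if mask is not None:
            xhat *= mask[:, None, :]
        if train:
            self._xhat, self._inv_std = xhat, inv_std
            self._m = (x.shape[0] * x.shape[2]) if mask is None else float(mask.sum())
            self._mask = mask
        out = self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]
        if mask is not None:
            out *= mask[:, None, :]  # keep padded positions exactly zero
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        if self._mask is not None:
            grad = grad * self._mask[:, None, :]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma.value[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dx = (inv_std[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)
        if self._mask is not None:
            dx *= self._mask[:, None, :]
        return dx


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class GlobalAvgPool:
    """Mean over the time axis: (N, D, T) -> (N, D); length-invariant.

    With a mask, each series is averaged over its own true length."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True,
                mask: np.ndarray | None = None) -> np.ndarray:
        self._t = x.shape[2]
        self._mask = mask
        if mask is None:
            return x.mean(axis=2)
        self._len = mask.sum(axis=1)  # (N,)
        return np.einsum("ndt,nt->nd", x, mask) / self._len[:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return np.repeat(grad[:, :, None], self._t, axis=2) / self._t
        g = grad[:, :, None] / self._len[:, None, None]
        return g * self._mask[:, None, :]


class LSTMLast:
    """Single-layer LSTM over scalar inputs, returning the final hidden state.

    Gate order in the stacked weight matrices is (input, forget, output,
    cell-candidate) so the three sigmoid gates form one contiguous slab;
    forget-gate bias initialised to 1; initial hidden and cell states zero.
    """

    def __init__(self, hidden: int, rng: np.random.Generator, dtype=np.float32):
        h = hidden
        self.Wx = Param(rng.standard_normal((1, 4 * h)) / np.sqrt(1 + h), dtype)
        self.Wh = Param(rng.standard_normal((h, 4 * h)) / np.sqrt(1 + h), dtype)
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0
        self.b = Param(b, dtype)
        self.hidden = h
        self.dtype = dtype

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool = True,
                lengths: np.ndarray | None = None) -> np.ndarray:
        """x: (N, T) scalar sequence -> (N, H) hidden state at each series'
        final valid step (``lengths`` for right-padded ragged batches)."""
        n, t = x.shape
        h_dim = self.hidden
        dt = self.dtype
        hs = np.zeros((t + 1, n, h_dim), dtype=dt)
        cs = np.zeros((t + 1, n, h_dim), dtype=dt)
        gates = np.empty((t, n, 4 * h_dim), dtype=dt)
        tc = np.empty((t, n, h_dim), dtype=dt)
        # input contribution for every step at once (non-recurrent)
        xw = x.T[:, :, None] * self.Wx.value[0] + self.b.value  # (T, N, 4H)
        for step in range(t):
            z = xw[step] + hs[step] @ self.Wh.value
            z[:, : 3 * h_dim] = _sigmoid(z[:, : 3 * h_dim])
            np.tanh(z[:, 3 * h_dim :], out=z[:, 3 * h_dim :])
            i = z[:, :h_dim]
            f = z[:, h_dim : 2 * h_dim]
            o = z[:, 2 * h_dim : 3 * h_dim]
            g = z[:, 3 * h_dim :]
            cs[step + 1] = f * cs[step] + i * g
            np.tanh(cs[step + 1], out=tc[step])
            hs[step + 1] = o * tc[step]
            gates[step] = z
        if train:
            self._cache = (x, hs, cs, gates, tc, lengths)
        if lengths is None:
            return hs[t]
        return hs[lengths, np.arange(n)]

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        x, hs, cs, gates, tc, lengths = self._cache
        t_len = x.shape[1]
        h_dim = self.hidden
        if lengths is None:
            dh = grad.copy()
            inject = None
        else:
            # route each series' gradient to its own final step; rows of
            # dh/dc stay zero beyond a series' true length
            dh = np.zeros_like(grad)
            inject = (np.asarray(lengths) - 1, np.arange(grad.shape[0]))
        dc = np.zeros_like(dh)
        dzs = np.empty_like(gates)  # (T, N, 4H) pre-activation grads
        wh_t = self.Wh.value.T
        for step in range(t_len - 1, -1, -1):
            if inject is not None:
                sel = inject[0] == step
                if np.any(sel):
                    dh[inject[1][sel]] += grad[inject[1][sel]]
            z = gates[step]
            i = z[:, :h_dim]
            f = z[:, h_dim : 2 * h_dim]
            o = z[:, 2 * h_dim : 3 * h_dim]
            g = z[:, 3 * h_dim :]
            tcs = tc[step]
            do = dh * tcs
            dc += dh * o * (1.0 - tcs * tcs)
            dz = dzs[step]
            dz[:, :h_dim] = dc * g * i * (1 - i)
            dz[:, h_dim : 2 * h_dim] = dc * cs[step] * f * (1 - f)
            dz[:, 2 * h_dim : 3 * h_dim] = do * o * (1 - o)
            dz[:, 3 * h_dim :] = dc * i * (1 - g * g)
            dh = dz @ wh_t
            dc *= f
        # parameter gradients accumulated over all steps at once
        self.Wx.grad += np.einsum("nt,tng->g", x, dzs, optimize=True)[None, :]
        self.Wh.grad += np.einsum("tnh,tng->hg", hs[:-1], dzs, optimize=True)
        self.b.grad += dzs.sum(axis=(0, 1))
        return None  # input gradient unused (inputs are data)


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Param(rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in), dtype)
        self.b = Param(np.zeros(d_out), dtype)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


def _sigmoid(z: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(z)


class Adam:
    """Adaptive-moment optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
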