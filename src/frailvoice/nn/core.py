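"""Layers with explicit forward/backward passes and an Adam optimizer.

Conventions: activations carry shape (..., D) with matmuls on the last axis;
every module exposes ``parameters()``/``grads()`` as flat name->array dicts
(arrays are live references, so an optimizer can update them in place),
``zero_grad()``, and ``backward(dout)`` returning the gradient with respect to
the module input.  Caches from the last ``forward`` are kept on the module, so
a module instance must not be reused concurrently.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "softmax",
    "sinusoidal_positions",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerLayer",
    "TransformerEncoder",
    "MLPHead",
    "Adam",
]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def sinusoidal_positions(n_pos: int, dim: int) -> np.ndarray:
    """Classic fixed sin/cos positional table of shape (n_pos, dim)."""
    pos = np.arange(n_pos)[:, None].astype(float)
    i = np.arange(dim // 2)[None, :].astype(float)
    angles = pos / np.power(10000.0, 2 * i / dim)
    table = np.zeros((n_pos, dim))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return table


class Module:
    """Base class: recursive parameter/grad collection over ``_children``."""

    _children: list[tuple[str, "Module"]]

    def __init__(self) -> None:
        self._children = []
        self._params: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        self._params[name] = value
        self._grads[name] = np.zeros_like(value)
        return value

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children.append((name, child))
        return child

    def parameters(self) -> dict[str, np.ndarray]:
        out = dict(self._params)
        for cname, child in self._children:
            for pname, p in child.parameters().items():
                out[f"{cname}.{pname}"] = p
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = dict(self._grads)
        for cname, child in self._children:
            for pname, g in child.grads().items():
                out[f"{cname}.{pname}"] = g
        return out

    def zero_grad(self) -> None:
        for g in self._grads.values():
            g[...] = 0.0
        for _, child in self._children:
            child.zero_grad()

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(values)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in params.items():
            p[...] = values[name]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters().values()))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = self.add_param("W", rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = self.add_param("b", np.zeros(d_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self._grads["W"] += x2.T @ d2
        self._grads["b"] += d2.sum(axis=0)
        return dout @ self.W.T


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.g = self.add_param("g", np.ones(dim))
        self.beta = self.add_param("beta", np.zeros(dim))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.g * self._xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        d2 = dout.reshape(-1, dout.shape[-1])
        x2 = xhat.reshape(-1, xhat.shape[-1])
        self._grads["g"] += (d2 * x2).sum(axis=0)
        self._grads["beta"] += d2.sum(axis=0)
        dxhat = dout * self.g
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator) -> None:
        super().__init__()
        if dim % n_heads:
            raise ValueError("model dim must be divisible by n_heads")
        self.dim, self.h = dim, n_heads
        self.dh = dim // n_heads
        self.wq = self.add_child("wq", Linear(dim, dim, rng))
        self.wk = self.add_child("wk", Linear(dim, dim, rng))
        self.wv = self.add_child("wv", Linear(dim, dim, rng))
        self.wo = self.add_child("wo", Linear(dim, dim, rng))

    def _split(self, x: np.ndarray) -> np.ndarray:  # (B,T,D) -> (B,h,T,dh)
        b, t, _ = x.shape
        return x.reshape(b, t, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:  # (B,h,T,dh) -> (B,T,D)
        b, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scale = 1.0 / np.sqrt(self.dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = softmax(scores, axis=-1)
        ctx = attn @ v
        self._cache = (q, k, v, attn, scale)
        return self.wo.forward(self._merge(ctx))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, attn, scale = self._cache
        dctx = self._split(self.wo.backward(dout))
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        dscores = attn * (dattn - np.sum(dattn * attn, axis=-1, keepdims=True))
        dscores *= scale
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = self.wq.backward(self._merge(dq))
        dx += self.wk.backward(self._merge(dk))
        dx += self.wv.backward(self._merge(dv))
        return dx


class TransformerLayer(Module):
    """Post-norm encoder layer: LN(x + MHA(x)) then LN(u + FFN(u)), ReLU FFN."""

    def __init__(self, dim: int, n_heads: int, ffn_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.attn = self.add_child("attn", MultiHeadSelfAttention(dim, n_heads, rng))
        self.ln1 = self.add_child("ln1", LayerNorm(dim))
        self.ff1 = self.add_child("ff1", Linear(dim, ffn_dim, rng))
        self.ff2 = self.add_child("ff2", Linear(ffn_dim, dim, rng))
        self.ln2 = self.add_child("ln2", LayerNorm(dim))

    def forward(self, x: np.ndarray) -> np.ndarray:
        u = self.ln1.forward(x + self.attn.forward(x))
        h = self.ff1.forward(u)
        self._relu_mask = h > 0
        f = self.ff2.forward(h * self._relu_mask)
        return self.ln2.forward(u + f)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dg = self.ln2.backward(dout)
        dh = self.ff2.backward(dg) * self._relu_mask
        du = dg + self.ff1.backward(dh)
        da = self.ln1.backward(du)
        return da + self.attn.backward(da)


class TransformerEncoder(Module):
    """Input projection + sinusoidal positions + stacked encoder layers."""

    def __init__(
        self,
        input_dim: int,
        model_dim: int,
        n_heads: int,
        ffn_dim: int,
        n_layers: int,
        seed: int = 0,
    ) -> None:
        super().__init__()
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.model_dim = model_dim
        self.proj = self.add_child("proj", Linear(input_dim, model_dim, rng))
        self.layers = [
            self.add_child(f"layer{i}", TransformerLayer(model_dim, n_heads, ffn_dim, rng))
            for i in range(n_layers)
        ]
        self._pos_cache: np.ndarray | None = None

    def _positions(self, t: int) -> np.ndarray:
        if self._pos_cache is None or self._pos_cache.shape[0] < t:
            self._pos_cache = sinusoidal_positions(max(t, 16), self.model_dim)
        return self._pos_cache[:t]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, input_dim) -> (B, T, model_dim)."""
        if x.shape[-1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} feature columns, got {x.shape[-1]}"
            )
        h = self.proj.forward(x) + self._positions(x.shape[1])[None]
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return self.proj.backward(d)


class MLPHead(Module):
    """One-hidden-layer ReLU head (the classifier and the SSL decoder shape)."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.fc1 = self.add_child("fc1", Linear(d_in, d_hidden, rng))
        self.fc2 = self.add_child("fc2", Linear(d_hidden, d_out, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.fc1.forward(x)
        self._mask = h > 0
        return self.fc2.forward(h * self._mask)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.fc2.backward(dout) * self._mask
        return self.fc1.backward(dh)


class Adam:
    """Adam over a module's live parameter dict; state keyed by name."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
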