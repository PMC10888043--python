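"""Transformer building blocks on the package autodiff engine.

Layers follow the pre-LayerNorm transformer convention. Every module owns its
parameters as :class:`~petctsurv.autodiff.Tensor` objects with
``requires_grad=True`` and exposes them through :meth:`Module.parameters`;
initialization draws from an explicit ``numpy.random.Generator`` so that a
model is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, softmax

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadAttention",
    "FeedForward",
    "TransformerBlock",
    "MLP",
    "sinusoidal_embedding",
]


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        """All Tensor-valued state, trainable or frozen (buffers included)."""
        out: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value.data
            elif isinstance(value, Module):
                out.update(value.state_dict(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.state_dict(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                value.data = np.asarray(state[key], dtype=np.float64).reshape(value.shape)
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        item.data = np.asarray(state[f"{key}.{i}"]).reshape(item.shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init_scale: float | None = None, bias: bool = True):
        scale = init_scale if init_scale is not None else 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps) ** 0.5 * self.gain + self.shift


class MultiHeadAttention(Module):
    """Attention with separate query/key and value sources.

    ``__call__(q_src, k_src, v_src)`` computes
    ``softmax(QK^T / sqrt(d_head)) V`` per head followed by the output
    projection; self-attention is the ``q_src is k_src is v_src`` case and
    cross-modal attention passes different streams.
    """

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator,
                 zero_out_proj: bool = False):
        if d_model % heads:
            raise ValueError(f"d_model {d_model} not divisible by heads {heads}")
        self.heads = heads
        self.d_head = d_model // heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng, init_scale=0.0 if zero_out_proj else None)

    def _split(self, x: Tensor) -> Tensor:
        # (..., L, d_model) -> (..., H, L, d_head)
        *batch, L, _ = x.shape
        x = x.reshape(*batch, L, self.heads, self.d_head)
        return x.swapaxes(-2, -3)

    def __call__(self, q_src: Tensor, k_src: Tensor, v_src: Tensor) -> Tensor:
        q = self._split(self.wq(q_src))
        k = self._split(self.wk(k_src))
        v = self._split(self.wv(v_src))
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite attention logits")
        attn = softmax(logits, axis=-1)
        out = attn @ v
        out = out.swapaxes(-2, -3)
        *batch, L, _, _ = out.shape
        out = out.reshape(*batch, L, self.heads * self.d_head)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, d_model: int, d_hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerBlock(Module):
    """Pre-LN residual block: x + MHA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 4.0):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadAttention(d_model, heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, int(d_model * mlp_ratio), rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, h)
        return x + self.ffn(self.ln2(x))


class MLP(Module):
    def __init__(self, d_in: int, widths: list[int], rng: np.random.Generator,
                 d_out: int = 1):
        dims = [d_in, *widths]
        self.hidden = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.head = Linear(dims[-1], d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.hidden:
            x = layer(x).gelu()
        return self.head(x)


def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 100.0) -> np.ndarray:
    """Sin/cos positional features of a (normalized) scalar, shape (..., dim)."""
    if dim % 2:
        raise ValueError("embedding dim must be even")
    t = np.asarray(t, dtype=np.float64)[..., None]
    freqs = max_period ** (-np.arange(dim // 2) / (dim // 2))
    ang = t * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=-1)
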