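"""Neural layers built on the autograd engine.

Initialization follows the common truncated-normal(sigma=0.02) convention for
lookup tables and projection weights; every layer takes an explicit
``numpy.random.Generator`` so whole models are reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d_valid, softmax

__all__ = [
    "Module",
    "Linear",
    "EmbeddingTable",
    "LayerNorm",
    "Dropout",
    "MultiheadSelfAttention",
    "TransformerEncoderLayer",
    "TransformerEncoder",
    "Conv2d",
]

NEG_INF = -1e9  # additive attention mask for PAD keys


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


class Module:
    """Tiny nn.Module analogue: parameter discovery, train/eval, state dict."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            for p in _collect(obj):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for obj in self.__dict__.values():
            mods.extend(_collect_modules(obj))
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _collect(obj) -> list[Tensor]:
    if isinstance(obj, Tensor):
        return [obj] if obj.requires_grad else []
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out = []
        for o in obj:
            out.extend(_collect(o))
        return out
    return []


def _collect_modules(obj) -> list[Module]:
    if isinstance(obj, Module):
        return obj.modules()
    if isinstance(obj, (list, tuple)):
        out = []
        for o in obj:
            out.extend(_collect_modules(o))
        return out
    return []


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(trunc_normal(rng, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class EmbeddingTable(Module):
    """Learnable dictionary lookup (content or positional)."""

    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            trunc_normal(rng, (num_embeddings, dim)), requires_grad=True
        )

    def __call__(self, indices: np.ndarray) -> Tensor:
        from .autograd import embedding

        idx = np.asarray(indices)
        if idx.size and idx.max() >= self.weight.shape[0]:
            raise IndexError(
                f"index {int(idx.max())} out of range for table of "
                f"{self.weight.shape[0]} embeddings"
            )
        return embedding(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """x: (B, L, D); mask: (B, L) with 1 for real tokens, 0 for PAD."""
        B, L, D = x.shape
        H, Dh = self.n_heads, self.head_dim

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, Dh).transpose(0, 2, 1, 3)  # (B,H,L,Dh)

        q = split_heads(self.wq(x))
        k = split_heads(self.wk(x))
        v = split_heads(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(Dh))  # (B,H,L,L)
        # PAD keys are excluded from every query's attention
        bias = np.where(mask[:, None, None, :] > 0, 0.0, NEG_INF)
        attn = softmax(scores + Tensor(bias), axis=-1)
        ctx = attn @ v  # (B,H,L,Dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: LN(x + Drop(Attn(x))), LN(x + Drop(FFN(x)))."""

    def __init__(
        self,
        dim: int,
        n_heads: int,
        ffn_dim: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.attn = MultiheadSelfAttention(dim, n_heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ffn_dim, rng)
        self.ff2 = Linear(ffn_dim, dim, rng)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.drop1(self.attn(x, mask)))
        x = self.ln2(x + self.drop2(self.ff2(self.ff1(x).relu())))
        return x


class TransformerEncoder(Module):
    def __init__(
        self,
        n_layers: int,
        dim: int,
        n_heads: int,
        ffn_dim: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.layers = [
            TransformerEncoderLayer(dim, n_heads, ffn_dim, dropout, rng)
            for _ in range(n_layers)
        ]

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        for layer in self.layers:
            x = layer(x, mask)
        return x


class Conv2d(Module):
    """Stride-1, valid-padding 2-D convolution."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d_valid(x, self.weight, self.bias)
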