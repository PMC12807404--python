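"""Neural-network building blocks on top of the autograd engine.

Conventions follow the familiar deep-learning APIs: modules hold
``Parameter`` tensors, expose ``parameters()``, and carry a train/eval flag
(batch norm and dropout behave differently between the two).  All random
initialisation is driven by an explicit ``numpy.random.Generator`` so that
model construction is reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv1d",
    "MaxPool1d",
    "BatchNorm1d",
    "LayerNorm",
    "Embedding",
    "Dropout",
    "MultiheadAttention",
    "Sequential",
    "ReLU",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            for m in _collect_modules(value):
                mods.extend(m.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def _buffers(self) -> list[tuple["Module", str]]:
        """(module, attribute) pairs for non-learned state (BN running stats)."""
        out = []
        for m in self.modules():
            for name in getattr(m, "buffer_names", ()):
                out.append((m, name))
        return out

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        state += [np.array(getattr(m, name), copy=True) for m, name in self._buffers()]
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        buffers = self._buffers()
        if len(params) + len(buffers) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = s.copy()
        for (m, name), s in zip(buffers, state[len(params) :]):
            setattr(m, name, s.copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value) -> list[Parameter]:
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Parameter] = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_modules(value) -> list[Module]:
    if isinstance(value, Module):
        return [value]
    if isinstance(value, (list, tuple)):
        out: list[Module] = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    return []


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv1d(Module):
    """1-D convolution, stride 1, 'same' zero padding for odd kernel sizes."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        padding: str = "same",
    ):
        super().__init__()
        if padding != "same" or kernel_size % 2 == 0:
            raise ValueError("only odd-kernel 'same' convolution is supported")
        self.kernel_size = kernel_size
        bound = 1.0 / math.sqrt(in_channels * kernel_size)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (out_channels, in_channels, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, C_in, L) -> (B, C_out, L)
        k = self.kernel_size
        pad = k // 2
        weight, bias = self.weight, self.bias
        xd = x.data
        B, C, L = xd.shape
        padded = np.zeros((B, C, L + 2 * pad))
        padded[:, :, pad : pad + L] = xd
        out_data = np.einsum(
            "bclk,ock->bol",
            np.lib.stride_tricks.sliding_window_view(padded, k, axis=2),
            weight.data,
        ) + bias.data[None, :, None]

        def backward(g):
            # g: (B, C_out, L)
            gpad = np.zeros((B, C, L + 2 * pad))
            dw = np.zeros_like(weight.data)
            win = np.lib.stride_tricks.sliding_window_view(padded, k, axis=2)
            for j in range(k):
                gpad[:, :, j : j + L] += np.einsum("oc,bol->bcl", weight.data[:, :, j], g)
                dw[:, :, j] = np.einsum("bol,bcl->oc", g, win[:, :, :, j])
            x._accum(gpad[:, :, pad : pad + L])
            weight._accum(dw)
            bias._accum(g.sum(axis=(0, 2)))

        return Tensor._make(out_data, (x, weight, bias), backward)


class MaxPool1d(Module):
    """Non-overlapping max pooling (kernel = stride); trailing remainder dropped."""

    def __init__(self, kernel_size: int = 2):
        super().__init__()
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel_size
        B, C, L = x.data.shape
        Lout = L // k
        if Lout < 1:
            raise ValueError(f"sequence length {L} shorter than pool size {k}")
        view = x.data[:, :, : Lout * k].reshape(B, C, Lout, k)
        out_data = view.max(axis=3)
        arg = view.argmax(axis=3)

        def backward(g):
            full = np.zeros_like(x.data)
            b_idx, c_idx, l_idx = np.meshgrid(
                np.arange(B), np.arange(C), np.arange(Lout), indexing="ij"
            )
            full[b_idx, c_idx, l_idx * k + arg] += g
            x._accum(full)

        return Tensor._make(out_data, (x,), backward)


class BatchNorm1d(Module):
    """Batch normalisation over (B,) for 2-D input or (B, L) for 3-D input.

    Training mode normalises with batch statistics (biased variance) and
    updates exponential running statistics; eval mode uses the running ones.
    """

    buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            axes, shape = (0,), (1, -1)
        elif x.ndim == 3:
            axes, shape = (0, 2), (1, -1, 1)
        else:
            raise ValueError("BatchNorm1d expects 2-D or 3-D input")
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean = (
                1 - self.momentum
            ) * self.running_mean + self.momentum * mean.data.reshape(-1)
            self.running_var = (
                1 - self.momentum
            ) * self.running_var + self.momentum * var.data.reshape(-1)
            xhat = (x - mean) / (var + self.eps).sqrt()
        else:
            mean = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mean) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) / (var + self.eps).sqrt() * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, (num_embeddings, dim)))

    def forward(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=np.intp)
        return self.weight[ids]


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiheadAttention(Module):
    """Standard scaled dot-product multi-head attention.

    Inputs are (B, T, D); ``forward(q, k, v)`` supports cross-attention by
    passing distinct key/value sources.  ``attn_mask`` is an additive mask
    broadcastable to (B, heads, Tq, Tk).
    """

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        rng: np.random.Generator,
        dropout: float = 0.0,
    ):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.w_q = Linear(d_model, d_model, rng)
        self.w_k = Linear(d_model, d_model, rng)
        self.w_v = Linear(d_model, d_model, rng)
        self.w_o = Linear(d_model, d_model, rng)
        self.drop = Dropout(dropout, rng)

    def set_identity(self) -> None:
        """Set all four projections to the identity map (used in tests and
        to realise degenerate/ablation configurations exactly)."""
        eye = np.eye(self.d_model)
        for lin in (self.w_q, self.w_k, self.w_v, self.w_o):
            lin.weight.data = eye.copy()
            lin.bias.data[:] = 0.0

    def _split(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_model // self.n_heads).transpose(
            0, 2, 1, 3
        )

    def forward(
        self,
        query: Tensor,
        key: Tensor,
        value: Tensor,
        attn_mask: np.ndarray | None = None,
    ) -> Tensor:
        B, Tq, _ = query.shape
        dh = self.d_model // self.n_heads
        q = self._split(self.w_q(query)) / math.sqrt(dh)
        k = self._split(self.w_k(key))
        v = self._split(self.w_v(value))
        scores = q @ k.swapaxes(-1, -2)  # (B, H, Tq, Tk)
        if attn_mask is not None:
            scores = scores + Tensor(attn_mask)
        attn = self.drop(scores.softmax(axis=-1))
        out = attn @ v  # (B, H, Tq, dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, Tq, self.d_model)
        return self.w_o(out)
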