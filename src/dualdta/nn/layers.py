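"""Neural-network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Embedding",
    "LSTM",
    "BiLSTM",
    "BatchNorm1d",
    "Dropout",
    "MLP",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: parameter registry, train/eval mode,
    state-dict (de)serialization."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, m in self._modules.items():
            yield from m.named_modules(prefix + name + ".")

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for path, m in self.named_modules():
            m._collect_buffers(out, path)
        return out

    def _collect_buffers(self, out: dict, path: str) -> None:
        pass  # overridden by modules with non-parameter state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float64).copy()
        for path, m in self.named_modules():
            m._load_buffers(state, path)

    def _load_buffers(self, state: dict, path: str) -> None:
        pass

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _uniform(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        s = 1.0 / np.sqrt(in_dim)
        self.weight = Parameter(_uniform(rng, (in_dim, out_dim), s))
        self.bias = Parameter(np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 1.0, size=(vocab_size, dim)))
        self.vocab_size = vocab_size
        self.dim = dim

    def forward(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=np.intp)
        if ids.size and (ids.min() < 0 or ids.max() >= self.vocab_size):
            raise ValueError("token id outside embedding vocabulary")
        flat = self.weight[ids.reshape(-1)]
        return flat.reshape(*ids.shape, self.dim)


class LSTM(Module):
    """Single-direction LSTM over padded batches.

    Masked (padding) time steps carry the previous hidden and cell state
    forward unchanged, so padding never enters the recurrence.
    """

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        s = 1.0 / np.sqrt(hidden_dim)
        self.w_x = Parameter(_uniform(rng, (in_dim, 4 * hidden_dim), s))
        self.w_h = Parameter(_uniform(rng, (hidden_dim, 4 * hidden_dim), s))
        self.bias = Parameter(np.zeros(4 * hidden_dim))
        self.hidden_dim = hidden_dim

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        b, t, _ = x.shape
        h_dim = self.hidden_dim
        xw = x @ self.w_x + self.bias  # (B, T, 4H)
        h = Tensor(np.zeros((b, h_dim)))
        c = Tensor(np.zeros((b, h_dim)))
        outs = []
        for step in range(t):
            gates = xw[:, step] + h @ self.w_h
            i = gates[:, 0:h_dim].sigmoid()
            f = gates[:, h_dim : 2 * h_dim].sigmoid()
            g = gates[:, 2 * h_dim : 3 * h_dim].tanh()
            o = gates[:, 3 * h_dim : 4 * h_dim].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = mask[:, step : step + 1].astype(np.float64)
            if m.all():
                h, c = h_new, c_new
            else:
                h = Tensor(m) * h_new + Tensor(1.0 - m) * h
                c = Tensor(m) * c_new + Tensor(1.0 - m) * c
            outs.append(h.reshape(b, 1, h_dim))
        return concat(outs, axis=1)


class BiLSTM(Module):
    """Bidirectional LSTM: each direction has width ``out_dim // 2`` and the
    two output streams are concatenated per position."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        if out_dim % 2:
            raise ValueError("BiLSTM output width must be even")
        self.fwd = LSTM(in_dim, out_dim // 2, rng)
        self.bwd = LSTM(in_dim, out_dim // 2, rng)

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        out_f = self.fwd(x, mask)
        # Reverse time for the backward direction.  Padding sits at the end of
        # each sequence, so in the reversed array it leads; masked leading
        # steps leave the state at zero, which is the correct initial state.
        x_rev = x[:, ::-1]
        out_b = self.bwd(x_rev, mask[:, ::-1])[:, ::-1]
        return concat([out_f, out_b], axis=2)


class BatchNorm1d(Module):
    """Batch normalization over axis 0 (rows = nodes/samples).

    Training mode normalizes with batch statistics (differentiably) and
    updates running statistics; eval mode uses the running statistics, making
    single-graph inference deterministic.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbiased = var.data[0] * (n / max(n - 1, 1))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            xn = xc * ((var + self.eps) ** -0.5)
        else:
            xn = (x - self.running_mean) * (
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xn * self.gamma + self.beta

    def _collect_buffers(self, out: dict, path: str) -> None:
        out[path + "running_mean"] = self.running_mean.copy()
        out[path + "running_var"] = self.running_var.copy()

    def _load_buffers(self, state: dict, path: str) -> None:
        if path + "running_mean" in state:
            self.running_mean = state[path + "running_mean"].copy()
            self.running_var = state[path + "running_var"].copy()


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MLP(Module):
    """Stack of Linear layers with ReLU between them."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        super().__init__()
        self.n_layers = len(dims) - 1
        for i in range(self.n_layers):
            setattr(self, f"lin{i}", Linear(dims[i], dims[i + 1], rng))

    def forward(self, x: Tensor) -> Tensor:
        for i in range(self.n_layers):
            x = getattr(self, f"lin{i}")(x)
            if i < self.n_layers - 1:
                x = x.relu()
        return x
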