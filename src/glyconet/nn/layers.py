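"""Neural-network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter/buffer discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, val in sorted(vars(self).items()):
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in sorted(vars(self).items()):
            full = f"{prefix}{name}"
            if isinstance(val, Module):
                yield from val.named_buffers(prefix=full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{full}.{i}.")
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                yield full, val

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({f"buffer:{name}": b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data[...] = d[name]
        for name, b in self.named_buffers():
            b[...] = d[f"buffer:{name}"]


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (in_dim + out_dim))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.1, size=(n_tokens, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.int64)]


class BatchNorm1d(Module):
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu.data.ravel()
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var.data.ravel()
            xn = xc * (var + self.eps) ** -0.5
        else:
            xn = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class LSTM(Module):
    """Single-layer unidirectional LSTM; returns the final hidden state.

    Input is a padded integer matrix (batch, T) plus per-sequence lengths;
    padded steps leave the state untouched, so the "final" state is the
    state after each sequence's true last residue.
    """

    def __init__(self, n_tokens: int, embed_dim: int, hidden_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.embed = Embedding(n_tokens, embed_dim, rng)
        self.wx = Linear(embed_dim, 4 * hidden_dim, rng)
        self.wh = Linear(hidden_dim, 4 * hidden_dim, rng)
        self.hidden_dim = hidden_dim

    def __call__(self, tokens: np.ndarray, lengths: np.ndarray) -> Tensor:
        b, t_max = tokens.shape
        h = Tensor(np.zeros((b, self.hidden_dim)))
        c = Tensor(np.zeros((b, self.hidden_dim)))
        d = self.hidden_dim
        for t in range(t_max):
            x_t = self.embed(tokens[:, t])
            gates = self.wx(x_t) + self.wh(h)
            i = gates[:, 0:d].sigmoid()
            f = gates[:, d:2 * d].sigmoid()
            g = gates[:, 2 * d:3 * d].tanh()
            o = gates[:, 3 * d:4 * d].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            active = Tensor((lengths > t).astype(np.float64)[:, None])
            c = active * c_new + (1.0 - active) * c
            h = active * h_new + (1.0 - active) * h
        return h


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    return x.leaky_relu(slope)


def init_sparse(model: Module, sparsity: float = 0.10,
                seed: int | np.random.Generator = 0) -> Module:
    """Sparse initialization: per output unit of every 2-D weight matrix,
    a fraction `sparsity` of incoming entries is nonzero Gaussian (scaled
    to keep unit output variance), the rest exactly 0.  Bias vectors,
    embeddings and batch-norm parameters are untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for name, p in model.named_parameters():
        if p.data.ndim != 2 or "embed" in name:
            continue
        fan_in, fan_out = p.data.shape
        k = max(1, int(round(sparsity * fan_in)))
        w = np.zeros((fan_in, fan_out))
        std = 1.0 / np.sqrt(k)
        for j in range(fan_out):
            rows = rng.choice(fan_in, size=k, replace=False)
            w[rows, j] = rng.normal(0.0, std, size=k)
        p.data[...] = w
    return model
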