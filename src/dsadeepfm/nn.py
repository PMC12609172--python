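"""Neural-network building blocks and the Adam optimizer on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Dense", "Embedding", "BatchNorm1d", "Dropout", "Adam"]


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: tracks parameters, train/eval mode, named state."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        super().__setattr__(name, value)

    def add_param(self, name: str, data: np.ndarray, trainable: bool = True) -> Tensor:
        t = Tensor(np.asarray(data, dtype=np.float64), requires_grad=trainable)
        self._params[name] = t
        setattr(self, name, t)
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix="") -> dict[str, np.ndarray]:
        state = {prefix + k: v.data for k, v in self._params.items()}
        for name, m in self._modules.items():
            state.update(m.named_state(prefix + name + "."))
        for k, v in getattr(self, "_buffers", {}).items():
            state[prefix + k] = v
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix=""):
        for k, t in self._params.items():
            t.data = np.array(state[prefix + k], dtype=np.float64)
        for name, m in self._modules.items():
            m.load_state(state, prefix + name + ".")
        for k in getattr(self, "_buffers", {}):
            self._buffers[k] = np.array(state[prefix + k], dtype=np.float64)

    def set_training(self, flag: bool):
        self.training = flag
        for m in self._modules.values():
            m.set_training(flag)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Dense(Module):
    def __init__(self, rng, d_in: int, d_out: int):
        super().__init__()
        self.add_param("W", glorot_uniform(rng, d_in, d_out))
        self.add_param("b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.W) + self.b


class Embedding(Module):
    """Trainable lookup table; rows can be frozen for leave-out regimes."""

    def __init__(self, rng, n_rows: int, dim: int, scale: float = 0.05, trainable=True):
        super().__init__()
        self.add_param("table", rng.normal(0.0, scale, size=(n_rows, dim)), trainable)

    def __call__(self, indices: np.ndarray) -> Tensor:
        idx = np.asarray(indices)
        n = self.table.data.shape[0]
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            bad = idx[(idx < 0) | (idx >= n)]
            raise IndexError(
                f"categorical index out of range: entity index {int(bad.flat[0])} "
                f"not in [0, {n})"
            )
        return self.table.take_rows(idx)


class BatchNorm1d(Module):
    """Per-feature batch normalization with running statistics for eval mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.add_param("gamma", np.ones(dim))
        self.add_param("beta", np.zeros(dim))
        self.eps = eps
        self.momentum = momentum
        self._buffers = {
            "running_mean": np.zeros(dim),
            "running_var": np.ones(dim),
        }

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = centered.square().mean(axis=0, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel()
            )
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel()
            )
            inv = (var + self.eps) ** 0.5
            xhat = centered / inv
        else:
            mu = self._buffers["running_mean"]
            sd = np.sqrt(self._buffers["running_var"] + self.eps)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma + self.beta


# Tensor lacks __pow__; give BatchNorm the sqrt it needs via a helper.
def _tensor_sqrt(t: Tensor) -> Tensor:
    # sqrt via exp(0.5 log) would lose precision at 0; use dedicated op
    out = Tensor(np.sqrt(t.data))
    if t.requires_grad:
        out.requires_grad = True
        out._parents = (t,)

        def backward(g, o):
            t._accum(g * 0.5 / o.data)

        out._backward = backward
    return out


def _pow_half(self, p):
    if p != 0.5:
        raise NotImplementedError
    return _tensor_sqrt(self)


Tensor.__pow__ = _pow_half


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * mask


class Adam:
    """Adam with optional multiplicative step decay of the learning rate."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 decay_rate=1.0, decay_every=0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.decay_rate = decay_rate
        self.decay_every = decay_every
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self, epoch: int) -> float:
        if self.decay_every and self.decay_rate != 1.0:
            return self.lr * self.decay_rate ** (epoch // self.decay_every)
        return self.lr

    def step(self, epoch: int = 0):
        self.t += 1
        lr = self.current_lr(epoch)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
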