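"""Layer/module abstractions over the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d, maxpool2d, relu

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "Linear", "MaxPool2d"]


class Module:
    """Base class: parameter discovery by attribute walk."""

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                out.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        out.extend(v.modules())
        return out

    def set_training(self, training: bool) -> None:
        for m in self.modules():
            if hasattr(m, "training"):
                m.training = training

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Tensor], seen: set[int]) -> None:
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                if id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
            elif isinstance(value, Module):
                value._collect(params, seen)
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        v._collect(params, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    # -- flat state dict for checkpointing ---------------------------------

    def buffers(self) -> list[tuple["Module", str]]:
        """Non-parameter state (e.g. batch-norm running statistics)."""
        out = []
        for m in self.modules():
            for name in getattr(m, "buffer_names", ()):
                out.append((m, name))
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()] + [
            getattr(m, n) for m, n in self.buffers()
        ]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        bufs = self.buffers()
        if len(arrays) != len(params) + len(bufs):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects "
                f"{len(params) + len(bufs)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)
        for (m, n), a in zip(bufs, arrays[len(params):]):
            setattr(m, n, np.asarray(a, dtype=np.float64))


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, padding: int,
                 rng: np.random.Generator, bias: bool = True):
        fan_in = cin * kernel * kernel
        self.weight = Tensor(
            _he_init(rng, (cout, cin, kernel, kernel), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2d(Module):
    """2x2-kernel, stride-2 learned upsampling."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.weight = Tensor(_he_init(rng, (cin, cout, 2, 2), cin), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Tensor(_he_init(rng, (cout, cin), cin), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = _matmul_t(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


def _matmul_t(x: Tensor, w: Tensor) -> Tensor:
    """x @ w.T with gradient support (w is (out, in))."""

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data)
        if w.requires_grad:
            w._accumulate(g.T @ x.data)

    return Tensor._make(x.data @ w.data.T, (x, w), backward)


class BatchNorm2d(Module):
    """Per-channel batch normalization for NCHW tensors.

    In training mode the batch statistics normalize the activations and
    update exponential running estimates; in eval mode the running
    estimates are used, so inference is deterministic and batch-size
    independent.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.training = True
        # running stats are state, not parameters (kept out of the optimizer)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.buffer_names = ("running_mean", "running_var")
        self._acc: tuple[float, np.ndarray, np.ndarray] | None = None

    def start_stats_accumulation(self) -> None:
        """Begin exact-statistics accumulation (precise recalibration)."""
        self._acc = (0, np.zeros_like(self.running_mean),
                     np.zeros_like(self.running_var))

    def finish_stats_accumulation(self) -> None:
        """Replace the running statistics with the exact moments gathered
        since :meth:`start_stats_accumulation`."""
        n, s, ss = self._acc
        self._acc = None
        if n <= 1:
            return
        mean = s / n
        var = (ss / n - mean**2) * n / (n - 1)
        self.running_mean = mean
        self.running_var = np.maximum(var, 0.0)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            if self._acc is not None:
                n, s, ss = self._acc
                self._acc = (n + m, s + x.data.sum(axis=(0, 2, 3)),
                             ss + (x.data**2).sum(axis=(0, 2, 3)))
            self.running_mean += self.momentum * (mu - self.running_mean)
            unbiased = var * m / max(m - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mu = self.running_mean
            var = self.running_var
        gamma, beta, eps = self.gamma, self.beta, self.eps
        ivstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu[None, :, None, None]) * ivstd[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if not x.requires_grad:
                return
            iv = ivstd[None, :, None, None]
            if not training:
                x._accumulate(g * gamma.data[None, :, None, None] * iv)
                return
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            dxhat = g * gamma.data[None, :, None, None]
            sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = iv / m * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
            x._accumulate(gx)

        return Tensor._make(out, (x, gamma, beta), backward)


class MaxPool2d(Module):
    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.k)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)
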