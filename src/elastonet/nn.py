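"""Neural-network building blocks used by the displacement networks.

Layers are thin containers of :class:`~elastonet._autodiff.Tensor`
parameters with a ``__call__`` forward. Weight layout conventions:

* ``Conv2d``: weight ``(out_ch, in_ch, k, k)``, same padding, stride 1.
* ``ConvTranspose2x2``: weight ``(in_ch, out_ch, 2, 2)``, stride 2.
* ``ConvLSTMCell``: the four gate convolutions are stacked along the
  output-channel axis in (input, forget, output, cell) order.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and a train/eval flag."""

    def __init__(self):
        self.training = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{path}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield path, value

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                params[name].data = np.asarray(arr, dtype=DTYPE).reshape(
                    params[name].shape)
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected weight {name!r}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing weights: {sorted(missing)}")


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None, zero_init=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel))
        else:
            w = _he_init(rng, (out_ch, in_ch, kernel, kernel),
                         in_ch * kernel * kernel)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)


class ConvTranspose2x2(Module):
    """Stride-2 learned upsampling (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            with np.errstate(all="ignore"):
                m = self.momentum
                self.running_mean *= (1 - m)
                self.running_mean += m * mu.data.reshape(c)
                self.running_var *= (1 - m)
                self.running_var += m * var.data.reshape(c)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            xc = x - mu
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        inv = (var + self.eps) ** -0.5
        xhat = xc * inv
        return xhat * self.gamma.reshape(1, c, 1, 1) \
            + self.beta.reshape(1, c, 1, 1)


class ResNetBlock(Module):
    """Two conv-BN-leakyReLU layers with a (projected) residual addition."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 leaky_slope: float = 0.1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.slope = leaky_slope
        self.conv1 = Conv2d(in_ch, out_ch, kernel, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, kernel, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        if in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, rng=rng)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.leaky_relu(self.bn1(self.conv1(x)), self.slope)
        y = ad.leaky_relu(self.bn2(self.conv2(y)), self.slope)
        res = x if self.proj is None else self.proj(x)
        return y + res


class ConvLSTMCell(Module):
    """Convolutional LSTM cell.

    The gate pre-activations are convolutions of the input and of the
    previous hidden state; the cell state is updated as
    ``c_t = c_{t-1} * f + i * c_tilde`` and the hidden state as
    ``h_t = o * tanh(c_t)``, with logistic gates and tanh cell activation.
    """

    def __init__(self, in_ch: int, hidden_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_ch = in_ch
        self.hidden_ch = hidden_ch
        rng = rng or np.random.default_rng(0)
        self.w_x = Parameter(_he_init(rng, (4 * hidden_ch, in_ch, kernel,
                                            kernel), in_ch * kernel * kernel))
        self.w_h = Parameter(_he_init(rng, (4 * hidden_ch, hidden_ch, kernel,
                                            kernel),
                                      hidden_ch * kernel * kernel))
        self.bias = Parameter(np.zeros(4 * hidden_ch))

    def init_state(self, spatial: tuple[int, int]):
        h, w = spatial
        z = Tensor(np.zeros((1, self.hidden_ch, h, w), dtype=DTYPE))
        return z, Tensor(np.zeros((1, self.hidden_ch, h, w), dtype=DTYPE))

    def __call__(self, x: Tensor, h_prev: Tensor, c_prev: Tensor):
        if h_prev.shape != c_prev.shape:
            raise ValueError("hidden and cell state shapes differ")
        if h_prev.shape[1] != self.hidden_ch or x.shape[1] != self.in_ch:
            raise ValueError("state/input channel mismatch")
        if x.shape[-2:] != h_prev.shape[-2:]:
            raise ValueError("state/input spatial mismatch")
        gates = ad.conv2d(x, self.w_x, self.bias) + ad.conv2d(h_prev, self.w_h)
        hc = self.hidden_ch
        i = ad.sigmoid(gates[:, 0 * hc:1 * hc])
        f = ad.sigmoid(gates[:, 1 * hc:2 * hc])
        o = ad.sigmoid(gates[:, 2 * hc:3 * hc])
        c_tilde = ad.tanh(gates[:, 3 * hc:4 * hc])
        c_t = c_prev * f + i * c_tilde
        h_t = o * ad.tanh(c_t)
        return h_t, c_t


def group_average_channels(x: Tensor, out_ch: int) -> Tensor:
    """Reduce channels by averaging contiguous groups (in_ch % out_ch == 0)."""
    n, c, h, w = x.shape
    if c == out_ch:
        return x
    if c % out_ch:
        raise ValueError(f"cannot group-average {c} channels to {out_ch}")
    return x.reshape(n, out_ch, c // out_ch, h, w).mean(axis=2)


class Adam:
    """Adam optimiser with the standard default moment coefficients."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params, lr: float = 1e-3, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
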