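"""Neural-network layers on top of the autodiff engine.

Weight layout conventions: ``Conv2d`` is (Cout, Cin, kh, kw), transposed
convolution is (Cin, Cout, kh, kw).  Spectral normalization follows the
power-iteration scheme: one iteration per training forward pass, the spectral
norm estimate treated as a constant in the backward pass.  Modules support a
``frozen`` context in which their parameters are detached from the graph (used
when a network acts as a fixed feature extractor inside another network's
objective) — buffers (running statistics, power-iteration vectors) are not
updated while frozen.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

from .autodiff import Tensor, conv2d, conv_transpose2d, softmax

__all__ = [
    "Module", "Parameter", "frozen", "Conv2d", "ConvTranspose2d",
    "BatchNorm2d", "LeakyReLU", "ReLU", "Tanh", "Sigmoid", "Identity",
    "Sequential", "SelfAttention", "ResidualBlock",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True
        self._frozen = False
        self._buffer_names: list[str] = []

    # ------------------------------------------------------------ traversal
    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(prefix=path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_buffers(prefix=path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{path}.{i}.")
            elif name in self._buffer_names:
                yield path, v

    def register_buffer(self, name: str, value: np.ndarray):
        setattr(self, name, value)
        self._buffer_names.append(name)

    # ---------------------------------------------------------------- modes
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def p(self, name: str) -> Tensor:
        """Fetch a parameter, detached when the module is frozen."""
        t = getattr(self, name)
        return t.detach() if self._frozen else t

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ------------------------------------------------------------- state io
    def state_dict(self) -> dict:
        d = {f"param.{k}": v.data for k, v in self.named_parameters()}
        d.update({f"buffer.{k}": np.asarray(v) for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict):
        params = dict(self.named_parameters())
        for key, value in d.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                params[name].data = np.asarray(value, dtype=np.float32).reshape(params[name].data.shape)
            elif kind == "buffer":
                obj = self
                parts = name.split(".")
                for part in parts[:-1]:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                setattr(obj, parts[-1], np.asarray(value))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


@contextmanager
def frozen(*mods: Module):
    """Treat the given modules' parameters as constants inside the block."""
    all_mods = [m for mod in mods for m in mod.modules()]
    prev = [m._frozen for m in all_mods]
    for m in all_mods:
        m._frozen = True
    try:
        yield
    finally:
        for m, state in zip(all_mods, prev):
            m._frozen = state


# ---------------------------------------------------------------- conv layers
def _power_iteration(wm: np.ndarray, u: np.ndarray):
    v = wm.T @ u
    v = v / (np.linalg.norm(v) + 1e-12)
    u_new = wm @ v
    u_new = u_new / (np.linalg.norm(u_new) + 1e-12)
    sigma = float(u_new @ wm @ v)
    return u_new, sigma


class _ConvBase(Module):
    def __init__(self, spectral_norm: bool, rows: int, rng: np.random.Generator):
        super().__init__()
        self.spectral_norm = spectral_norm
        if spectral_norm:
            u = rng.standard_normal(rows)
            self.register_buffer("u", (u / np.linalg.norm(u)).astype(np.float32))

    def _sn_weight(self) -> Tensor:
        w = self.p("weight")
        if not self.spectral_norm:
            return w
        wm = w.data.reshape(w.data.shape[0], -1).astype(np.float64)
        u_new, sigma = _power_iteration(wm, self.u.astype(np.float64))
        if self.training and not self._frozen:
            self.u = u_new.astype(np.float32)
        return w * float(1.0 / max(sigma, 1e-12))

    def power_iterate(self, n: int = 50):
        """Run extra power iterations to converge the spectral-norm estimate."""
        if self.spectral_norm:
            wm = self.weight.data.reshape(self.weight.data.shape[0], -1).astype(np.float64)
            u = self.u.astype(np.float64)
            for _ in range(n):
                u, _ = _power_iteration(wm, u)
            self.u = u.astype(np.float32)
        return self

    def sigma(self) -> float:
        wm = self.weight.data.reshape(self.weight.data.shape[0], -1).astype(np.float64)
        _, s = _power_iteration(wm, self.u.astype(np.float64))
        return s


class Conv2d(_ConvBase):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 bias: bool = True, spectral_norm: bool = False,
                 pad_mode: str = "zero", rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        super().__init__(spectral_norm, cout, rng)
        self.stride, self.pad, self.pad_mode = stride, pad, pad_mode
        self.weight = Parameter(rng.normal(0.0, 0.02, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        b = self.p("bias") if self.bias is not None else None
        return conv2d(x, self._sn_weight(), b, self.stride, self.pad, self.pad_mode)


class ConvTranspose2d(_ConvBase):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 bias: bool = True, spectral_norm: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        super().__init__(spectral_norm, cin, rng)
        self.stride = stride
        self.weight = Parameter(rng.normal(0.0, 0.02, (cin, cout, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        b = self.p("bias") if self.bias is not None else None
        return conv_transpose2d(x, self._sn_weight(), b, self.stride)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones((1, c, 1, 1)))
        self.beta = Parameter(np.zeros((1, c, 1, 1)))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import batch_norm_train

        if self.training:
            out, mu, var_unbiased = batch_norm_train(
                x, self.p("gamma"), self.p("beta"), self.eps)
            if not self._frozen:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
                self.running_var = ((1 - m) * self.running_var + m * var_unbiased).astype(np.float32)
            return out
        c = self.running_mean.shape[0]
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, c, 1, 1)
        scale = Tensor(inv)
        shift = Tensor((-self.running_mean.reshape(1, c, 1, 1) * inv))
        return self.p("gamma") * (x * scale + shift) + self.p("beta")


# ------------------------------------------------------------------ pointwise
class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


# --------------------------------------------------------------- composites
class SelfAttention(Module):
    """Query/key/value self-attention over spatial positions.

    Key/query channels are ``C//8`` (minimum 1); the attended output is added
    through a learned scalar gate initialized at zero, so the module starts as
    an identity and the attention pathway is grown during training.
    """

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        cq = max(c // 8, 1)
        self.query = Conv2d(c, cq, 1, rng=rng)
        self.key = Conv2d(c, cq, 1, rng=rng)
        self.value = Conv2d(c, c, 1, rng=rng)
        self.gate = Parameter(np.zeros(1))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        L = h * w
        q = self.query(x).reshape(n, -1, L).transpose(0, 2, 1)   # (N, L, Cq)
        k = self.key(x).reshape(n, -1, L)                        # (N, Cq, L)
        att = softmax(q @ k, axis=-1)                            # (N, Lout, Lin)
        v = self.value(x).reshape(n, c, L)                       # (N, C, Lin)
        o = (v @ att.transpose(0, 2, 1)).reshape(n, c, h, w)
        return x + self.p("gate").reshape(1, 1, 1, 1) * o


class ResidualBlock(Module):
    """Two 3x3 convolutions with a learned shortcut (1x1 when channels change)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, slope: float = 0.2):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, pad=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, pad=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.shortcut = Identity() if cin == cout else Conv2d(cin, cout, 1, bias=False, rng=rng)
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).leaky_relu(self.slope)
        h = self.bn2(self.conv2(h))
        return (h + self.shortcut(x)).leaky_relu(self.slope)
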