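"""Neural-network layers on the autograd core.

Layers hold their parameters as ``Tensor``s with ``requires_grad=True`` and
are initialized from an explicit ``numpy.random.Generator`` so that model
construction is fully reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from chickcall.nn.autograd import Tensor, concat, conv2d, maxpool2d


class Module:
    """Base class: parameter discovery, train/eval mode, (de)serialization."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.data.shape)

    def save_weights(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as z:
            self.load_state_dict({k: z[k] for k in z.files})


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Dense(Module):
    """Affine map on the trailing axis of 2-D input; He-scaled init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0):
        super().__init__()
        self.stride, self.pad = stride, pad
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class MaxPool2d(Module):
    def __init__(self, size: int = 3, stride: int | None = None, pad: int = 0):
        super().__init__()
        self.size, self.stride, self.pad = size, stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.size, self.stride, self.pad)


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics in training, running in eval."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones((1, n_channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n_channels, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, n_channels, 1, 1))
        self.running_var = np.ones((1, n_channels, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                (self.running_var + self.eps) ** -0.5
            )
        return xhat * self.gamma + self.beta


class GRU(Module):
    """Gated recurrent unit layer over (N, T, D) input.

    Update gate z, reset gate r, candidate n = tanh(x W_n + (r*h) U_n + b_n),
    h <- z*h + (1-z)*n.  Returns either the full hidden sequence (N, T, H)
    or the last hidden state (N, H).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        super().__init__()
        self.n_hidden = n_hidden
        self.return_sequences = return_sequences
        sx = np.sqrt(1.0 / n_in)
        sh = np.sqrt(1.0 / n_hidden)
        self.w_x = Tensor(rng.normal(0.0, sx, size=(n_in, 3 * n_hidden)), requires_grad=True)
        self.w_h = Tensor(rng.normal(0.0, sh, size=(n_hidden, 3 * n_hidden)), requires_grad=True)
        self.bias = Tensor(np.zeros(3 * n_hidden), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, t, _ = x.shape
        hsz = self.n_hidden
        h = Tensor(np.zeros((n, hsz)))
        outputs = []
        for step in range(t):
            xt = x[:, step, :]
            gx = xt @ self.w_x + self.bias
            gh = h @ self.w_h
            z = (gx[:, 0:hsz] + gh[:, 0:hsz]).sigmoid()
            r = (gx[:, hsz : 2 * hsz] + gh[:, hsz : 2 * hsz]).sigmoid()
            cand = (gx[:, 2 * hsz :] + r * gh[:, 2 * hsz :]).tanh()
            h = z * h + (1.0 - z) * cand
            if self.return_sequences:
                outputs.append(h.reshape(n, 1, hsz))
        return concat(outputs, axis=1) if self.return_sequences else h
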